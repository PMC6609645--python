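"""File parsing, identifier unification and phenotype assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metmap import ingest_annotate as ia
from metmap.errors import ConfigurationError, ParseError


class TestAssignPhenotype:
    @pytest.mark.parametrize("hba1c,expected", [
        (5.0, "control"),
        (5.6999, "control"),
        (5.7, "prediabetes"),     # inclusive lower bound of the band
        (6.0, "prediabetes"),
        (6.5, "prediabetes"),     # inclusive upper bound
        (6.5001, "T2D"),
        (9.0, "T2D"),
    ])
    def test_cutoffs(self, hba1c, expected):
        assert ia.assign_phenotype(hba1c) == expected

    def test_medical_record_flag_overrides(self):
        assert ia.assign_phenotype(5.2, medical_record_t2d=True) == "T2D"

    @pytest.mark.parametrize("bad", [0.0, -1.0, 26.0, float("nan")])
    def test_implausible_values_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ia.assign_phenotype(bad)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=25))
    def test_total_monotone_step_function(self, h):
        """Phenotype ordering is monotone in HbA1c everywhere in range."""
        rank = {"control": 0, "prediabetes": 1, "T2D": 2}
        a = rank[ia.assign_phenotype(h)]
        b = rank[ia.assign_phenotype(min(h + 0.3, 25))]
        assert a <= b

    def test_unit_conversion_round_trip(self):
        for mmol in (36.2, 40.8, 56.5):
            assert ia.percent_to_mmolmol(ia.mmolmol_to_percent(mmol)) == \
                pytest.approx(mmol)


class TestLoadIntensityTable:
    def test_parse_errors_name_the_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("metabolite_id\tS1\tS2\nM1\t1.0\t2.0\nM1\t3.0\t4.0\n")
        with pytest.raises(ParseError, match="duplicate"):
            ia.load_intensity_table(p, "liver", "GC-MS")
        p.write_text("metabolite_id\tS1\tS2\nM1\t1.0\tabc\n")
        with pytest.raises(ParseError, match="line 2"):
            ia.load_intensity_table(p, "liver", "GC-MS")
        p.write_text("metabolite_id\tS1\tS2\nM1\t1.0\n")
        with pytest.raises(ParseError, match="line 2"):
            ia.load_intensity_table(p, "liver", "GC-MS")

    def test_all_missing_metabolite_loads(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("metabolite_id\tS1\tS2\nM1\t\t\nM2\t1.5\t2.5\n")
        table = ia.load_intensity_table(p, "serum", "LC-MS")
        assert table.mask.loc["M1"].sum() == 0
        assert table.mask.loc["M2"].all()


def _write_source(path, rows, columns=("id", "name", "hmdb_id", "chebi_id",
                                       "kegg_id", "smpdb_ids", "curated_class")):
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "") or "") for c in columns))
    path.write_text("\n".join(lines) + "\n")


class TestBuildUnifiedDB:
    def test_shared_kegg_id_merges_with_provenance(self, tmp_path):
        h, k = tmp_path / "h.tsv", tmp_path / "k.tsv"
        _write_source(h, [{"name": "Glucose", "hmdb_id": "HMDB01", "kegg_id": "C1",
                           "curated_class": "carbohydrates"}])
        _write_source(k, [{"name": "D-Glucose", "kegg_id": "C1"}])
        db = ia.build_unified_db([("hmdb", h), ("kegg", k)])
        assert len(db.records) == 1
        rec = db.records[0]
        assert rec.name == "Glucose"  # HMDB wins the conflict
        prov = db.provenance[rec.local_id]
        assert "D-Glucose" in prov.get("alt_names", "")
        assert db.crossrefs["kegg:C1"] == rec.local_id

    def test_disjoint_sources_sum(self, tmp_path):
        h, c = tmp_path / "h.tsv", tmp_path / "c.tsv"
        _write_source(h, [{"name": f"A{i}", "hmdb_id": f"H{i}"} for i in range(3)])
        _write_source(c, [{"name": f"B{i}", "chebi_id": f"CH{i}"} for i in range(4)])
        db = ia.build_unified_db([("hmdb", h), ("chebi", c)])
        assert len(db.records) == 7

    def test_cyclic_crossrefs_collapse_to_one(self, tmp_path):
        """A<->B<->C chained ids union into a single record."""
        h = tmp_path / "h.tsv"
        _write_source(h, [
            {"name": "X", "hmdb_id": "H1", "chebi_id": "CB1"},
            {"name": "X", "chebi_id": "CB1", "kegg_id": "K1"},
            {"name": "X", "kegg_id": "K1", "hmdb_id": "H1"},
        ])
        db = ia.build_unified_db([("hmdb", h)])
        assert len(db.records) == 1
        lids = {db.crossrefs[t] for t in ("hmdb:H1", "chebi:CB1", "kegg:K1")}
        assert len(lids) == 1

    def test_conflicting_claim_keeps_records_split(self, tmp_path):
        h, k = tmp_path / "h.tsv", tmp_path / "k.tsv"
        _write_source(h, [{"name": "A", "hmdb_id": "H1", "kegg_id": "K1"},
                          {"name": "B", "hmdb_id": "H2"}])
        _write_source(k, [{"name": "C", "hmdb_id": "H2", "kegg_id": "K1"}])
        db = ia.build_unified_db([("hmdb", h), ("kegg", k)])
        assert db.conflicts
        assert len(db.records) == 2
        # crossrefs stays a function despite the contested id
        assert len({db.crossrefs[t] for t in db.crossrefs}) <= len(db.records)

    def test_idempotent_under_self_merge(self, tmp_path):
        h = tmp_path / "h.tsv"
        _write_source(h, [{"name": "A", "hmdb_id": "H1", "kegg_id": "K1"},
                          {"name": "B", "chebi_id": "CB9"}])
        once = ia.build_unified_db([("hmdb", h)])
        twice = ia.build_unified_db([("hmdb", h), ("hmdb", h)])
        assert [r.to_dict() | {"local_id": ""} for r in once.records] == \
               [r.to_dict() | {"local_id": ""} for r in twice.records]

    def test_order_invariance_of_crossref_function(self, tmp_path):
        files = {}
        for name, rows in (("hmdb", [{"name": "A", "hmdb_id": "H1", "kegg_id": "K1"}]),
                           ("chebi", [{"name": "A2", "chebi_id": "CB1", "kegg_id": "K1"}]),
                           ("kegg", [{"name": "A3", "kegg_id": "K1"}])):
            p = tmp_path / f"{name}.tsv"
            _write_source(p, rows)
            files[name] = p
        for perm in itertools.permutations(files):
            db = ia.build_unified_db([(n, files[n]) for n in perm])
            # every id maps to exactly one record and all ids agree
            assert len(db.records) == 1
            assert len({db.crossrefs[t] for t in db.crossrefs}) == 1

    def test_json_round_trip(self, tmp_path):
        h = tmp_path / "h.tsv"
        _write_source(h, [{"name": "A", "hmdb_id": "H1"}])
        db = ia.build_unified_db([("hmdb", h)])
        out = tmp_path / "db.json"
        db.to_json(out)
        back = ia.UnifiedDB.from_json(out)
        assert [r.to_dict() for r in back.records] == \
               [r.to_dict() for r in db.records]
        assert back.crossrefs == db.crossrefs


class TestAnnotateMetabolites:
    @pytest.fixture()
    def db(self, tmp_path):
        h = tmp_path / "h.tsv"
        _write_source(h, [{"name": "Glucose", "hmdb_id": "H1",
                           "curated_class": "carbohydrates"}])
        return ia.build_unified_db([("hmdb", h)])

    def test_resolution_paths(self, db, tmp_path):
        import pandas as pd
        values = pd.DataFrame([[1.0, 2.0]] * 3,
                              index=["hmdb:H1", "GLUCOSE", "mystery"],
                              columns=["S1", "S2"])
        table = ia.IntensityTable("liver", "GC-MS", values)
        with pytest.warns(UserWarning):
            records, report = ia.annotate_metabolites(
                table, db, unresolved_warn_fraction=0.2)
        assert records[0].curated_class == "carbohydrates"   # exact token
        assert records[1].curated_class == "carbohydrates"   # case-insensitive name
        assert records[2].curated_class == "unclassified"    # stub
        assert report["n_resolved"] == 2
        assert report["resolution_rate"] == pytest.approx(2 / 3)


class TestLoadSamples:
    def test_phenotype_derived_and_units_converted(self, tmp_path):
        p = tmp_path / "samples.tsv"
        p.write_text(
            "sample_id\thba1c_mmolmol\tgsis\tage_years\tbmi\tgender\tsample_weight\n"
            "S1\t36.2\t10\t60\t25\tF\t100\n"
            "S2\t56.5\t5\t65\t28\tM\t90\n")
        records = ia.load_samples(p)
        assert records[0].phenotype == "control"
        assert records[1].phenotype == "T2D"
        assert records[0].hba1c_percent == pytest.approx(
            0.09148 * 36.2 + 2.152)
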