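"""Input handling, metabolite identifier unification and phenotype assignment.

The analysis consumes three kinds of files: per-(tissue, platform) intensity
matrices (TSV, metabolites x samples, empty cell = missing), a sample
metadata table, and metabolite annotation sources.  Annotation sources are
simplified tab-separated renderings of the public HMDB / ChEBI / KEGG / SMPDB
schemas; they are unified into a single local collection by union-find over
shared cross-references, with field conflicts resolved by source priority
HMDB > ChEBI > KEGG > SMPDB.

Phenotype groups follow the clinical HbA1c convention: glycated haemoglobin
below 5.7 % is normoglycemic, 5.7-6.5 % (inclusive) is pre-diabetes, above
6.5 % is overt type-2 diabetes; an explicit medical-record T2D flag overrides
the HbA1c-derived group, because treated T2D can present controlled HbA1c.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)

TISSUES = ("VAT", "liver", "islets", "muscle", "serum")
PLATFORMS = ("GC-MS", "LC-MS")
PHENOTYPES = ("control", "prediabetes", "T2D")
COMPARISONS = ("T2D_vs_nonDM", "PD_vs_CTRL", "T2D_vs_PD")

#: NGSP/IFCC master equation coefficients: percent = A * mmol/mol + B
_NGSP_A = 0.09148
_NGSP_B = 2.152

#: Clinical cutoffs on the NGSP (%) scale.
HBA1C_CONTROL_MAX = 5.7   # strictly below -> control
HBA1C_PREDIAB_MAX = 6.5   # inclusive upper bound of the pre-diabetes band


def mmolmol_to_percent(mmolmol: float) -> float:
    """Convert IFCC HbA1c (mmol/mol) to NGSP percent."""
    return _NGSP_A * float(mmolmol) + _NGSP_B


def percent_to_mmolmol(percent: float) -> float:
    """Convert NGSP HbA1c (%) to IFCC mmol/mol."""
    return (float(percent) - _NGSP_B) / _NGSP_A


def assign_phenotype(hba1c_percent: float, medical_record_t2d: bool = False) -> str:
    """Assign the phenotype group from HbA1c on the % scale.

    Parameters
    ----------
    hba1c_percent
        Glycated haemoglobin fraction in NGSP percent.
    medical_record_t2d
        If True, the subject is classified T2D regardless of HbA1c.

    Returns
    -------
    One of ``"control"``, ``"prediabetes"``, ``"T2D"``.
    """
    h = float(hba1c_percent)
    if not np.isfinite(h) or h <= 0 or h > 25:
        raise ConfigurationError(f"implausible HbA1c value: {hba1c_percent!r} %")
    if medical_record_t2d:
        return "T2D"
    if h < HBA1C_CONTROL_MAX:
        return "control"
    if h <= HBA1C_PREDIAB_MAX:
        return "prediabetes"
    return "T2D"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """Donor metadata for one subject (identical across the five tissues)."""

    sample_id: str
    phenotype: str
    hba1c_percent: float
    hba1c_mmolmol: float
    gsis: float
    age_years: float
    bmi: float
    gender: str  # "F" or "M"
    sample_weight: float
    medical_record_t2d: bool = False

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ConfigurationError(f"unknown phenotype {self.phenotype!r}")
        if self.gender not in ("F", "M"):
            raise ConfigurationError(f"gender must be 'F' or 'M', got {self.gender!r}")
        for name in ("age_years", "bmi", "sample_weight"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0 for {self.sample_id}")

    @property
    def non_diabetes(self) -> bool:
        """Merged control + pre-diabetes group used in the primary comparison."""
        return self.phenotype in ("control", "prediabetes")


@dataclass
class MetaboliteRecord:
    """Unified annotation for one metabolite."""

    local_id: str
    name: str | None = None
    hmdb_id: str | None = None
    chebi_id: str | None = None
    kegg_id: str | None = None
    smpdb_ids: tuple[str, ...] = ()
    curated_class: str = "unclassified"
    sub_class: str | None = None
    acyl_chain: tuple[int, int] | None = None  # (carbons, double bonds)
    pathways: tuple[str, ...] = ()
    biological_roles: tuple[str, ...] = ()
    platform: str | None = None

    def __post_init__(self) -> None:
        if not (self.name or self.hmdb_id or self.chebi_id or self.kegg_id
                or self.smpdb_ids):
            raise ConfigurationError(
                f"record {self.local_id}: at least one of name/IDs is required")
        if self.acyl_chain is not None and self.sub_class not in (
                "LPC", "carnitine", "NEFA", "other_lipid"):
            raise ConfigurationError(
                f"record {self.local_id}: acyl_chain only valid for lipid sub-classes")

    def external_ids(self) -> list[str]:
        ids = []
        if self.hmdb_id:
            ids.append(f"hmdb:{self.hmdb_id}")
        if self.chebi_id:
            ids.append(f"chebi:{self.chebi_id}")
        if self.kegg_id:
            ids.append(f"kegg:{self.kegg_id}")
        ids.extend(f"smpdb:{s}" for s in self.smpdb_ids)
        return ids

    def to_dict(self) -> dict:
        d = asdict(self)
        d["smpdb_ids"] = list(self.smpdb_ids)
        d["pathways"] = list(self.pathways)
        d["biological_roles"] = list(self.biological_roles)
        d["acyl_chain"] = list(self.acyl_chain) if self.acyl_chain else None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetaboliteRecord":
        d = dict(d)
        d["smpdb_ids"] = tuple(d.get("smpdb_ids") or ())
        d["pathways"] = tuple(d.get("pathways") or ())
        d["biological_roles"] = tuple(d.get("biological_roles") or ())
        ac = d.get("acyl_chain")
        d["acyl_chain"] = tuple(ac) if ac else None
        return cls(**d)


@dataclass
class IntensityTable:
    """Raw intensity matrix for one (tissue, platform).

    ``values`` is a metabolites x samples DataFrame; missing measurements are
    NaN and are never silently zero-filled.
    """

    tissue: str
    platform: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].tolist()
            raise ParseError(f"duplicate metabolite ids: {dup}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].tolist()
            raise ParseError(f"duplicate sample ids: {dup}")
        vals = self.values.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if not np.isfinite(vals[present]).all():
            raise ParseError("non-finite intensity present")
        if (vals[present] < 0).any():
            raise ParseError("negative intensity present")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a measurement is present."""
        return self.values.notna()


# ---------------------------------------------------------------------------
# file loading
# ---------------------------------------------------------------------------

def load_intensity_table(path: str | Path, tissue: str, platform: str) -> IntensityTable:
    """Read an intensity TSV (metabolites x samples, empty cell = missing)."""
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise ParseError(f"{path}: empty file")
    width = len(rows[0])
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}")
    header = rows[0][1:]
    index, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        index.append(row[0])
        parsed = []
        for colname, cell in zip(header, row[1:]):
            if cell == "":
                parsed.append(np.nan)
            else:
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}, column {colname!r}: "
                        f"non-numeric cell {cell!r}") from None
        data.append(parsed)
    df = pd.DataFrame(data, index=index, columns=header, dtype=float)
    return IntensityTable(tissue=tissue, platform=platform, values=df)


def load_samples(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV into SampleRecord objects.

    The phenotype column is optional: when absent it is derived from HbA1c.
    HbA1c may be given in % and/or mmol/mol; one is derived from the other
    with the NGSP/IFCC master equation.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    records = []
    for _, row in df.iterrows():
        pct = row.get("hba1c_percent", np.nan)
        mmol = row.get("hba1c_mmolmol", np.nan)
        if pd.isna(pct) and pd.isna(mmol):
            raise ParseError(f"{path}: sample {row['sample_id']} has no HbA1c")
        if pd.isna(pct):
            pct = mmolmol_to_percent(mmol)
        if pd.isna(mmol):
            mmol = percent_to_mmolmol(pct)
        flag = bool(row.get("medical_record_t2d", False))
        phenotype = row.get("phenotype")
        if phenotype is None or (isinstance(phenotype, float) and pd.isna(phenotype)):
            phenotype = assign_phenotype(pct, medical_record_t2d=flag)
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            phenotype=str(phenotype),
            hba1c_percent=float(pct),
            hba1c_mmolmol=float(mmol),
            gsis=float(row.get("gsis", np.nan)),
            age_years=float(row["age_years"]),
            bmi=float(row["bmi"]),
            gender=str(row["gender"]),
            sample_weight=float(row["sample_weight"]),
            medical_record_t2d=flag,
        ))
    return records


def load_annotations(path: str | Path) -> list[MetaboliteRecord]:
    """Read an annotation JSON (list of record dicts) back into records."""
    with Path(path).open() as fh:
        data = json.load(fh)
    return [MetaboliteRecord.from_dict(d) for d in data]


# ---------------------------------------------------------------------------
# unified metabolite database
# ---------------------------------------------------------------------------

SOURCE_PRIORITY = {"hmdb": 0, "chebi": 1, "kegg": 2, "smpdb": 3}

_SCALAR_FIELDS = ("name", "hmdb_id", "chebi_id", "kegg_id",
                  "curated_class", "sub_class", "acyl_chain")


@dataclass
class UnifiedDB:
    """Local unified collection of metabolite annotations.

    ``crossrefs`` maps any known external id token (``hmdb:...``,
    ``chebi:...``, ``kegg:...``, ``smpdb:...``) and lower-cased names
    (``name:...``) to a local id; the map is a function by construction.
    """

    records: list[MetaboliteRecord] = field(default_factory=list)
    crossrefs: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)

    def record_by_local_id(self, local_id: str) -> MetaboliteRecord:
        for r in self.records:
            if r.local_id == local_id:
                return r
        raise KeyError(local_id)

    def resolve(self, token: str) -> MetaboliteRecord | None:
        lid = self.crossrefs.get(token)
        return self.record_by_local_id(lid) if lid else None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "records": [r.to_dict() for r in self.records],
            "crossrefs": self.crossrefs,
            "provenance": self.provenance,
            "conflicts": self.conflicts,
        }
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "UnifiedDB":
        with Path(path).open() as fh:
            payload = json.load(fh)
        return cls(
            records=[MetaboliteRecord.from_dict(d) for d in payload["records"]],
            crossrefs=dict(payload["crossrefs"]),
            provenance={k: dict(v) for k, v in payload["provenance"].items()},
            conflicts=list(payload.get("conflicts", [])),
        )


def _source_rows(source: str, path: str | Path) -> list[dict]:
    """Parse one simplified tabular annotation source."""
    df = pd.read_csv(path, sep="\t", dtype=str).replace({np.nan: None})
    rows = []
    for _, row in df.iterrows():
        d = row.to_dict()
        d["_source"] = source
        rows.append(d)
    return rows


def _row_to_fields(row: Mapping) -> dict:
    """Normalise a raw source row into MetaboliteRecord-style fields."""
    smpdb = tuple(s for s in (row.get("smpdb_ids") or "").split(";") if s)
    pathways = tuple(s for s in (row.get("pathways") or "").split(";") if s)
    roles = tuple(s for s in (row.get("biological_roles") or "").split(";") if s)
    acyl = None
    if row.get("acyl_carbons") not in (None, ""):
        acyl = (int(row["acyl_carbons"]), int(row.get("acyl_double_bonds") or 0))
    return {
        "name": row.get("name"),
        "hmdb_id": row.get("hmdb_id"),
        "chebi_id": row.get("chebi_id"),
        "kegg_id": row.get("kegg_id"),
        "smpdb_ids": smpdb,
        "curated_class": row.get("curated_class") or "unclassified",
        "sub_class": row.get("sub_class"),
        "acyl_chain": acyl,
        "pathways": pathways,
        "biological_roles": roles,
    }


def _fields_tokens(fields: Mapping) -> list[str]:
    tokens = []
    for ns, key in (("hmdb", "hmdb_id"), ("chebi", "chebi_id"), ("kegg", "kegg_id")):
        if fields.get(key):
            tokens.append(f"{ns}:{fields[key]}")
    tokens.extend(f"smpdb:{s}" for s in fields.get("smpdb_ids", ()))
    return tokens


def _mergeable(existing: dict, new: Mapping) -> bool:
    """Two field sets merge unless they claim different ids in one namespace."""
    for key in ("hmdb_id", "chebi_id", "kegg_id"):
        a, b = existing.get(key), new.get(key)
        if a and b and a != b:
            return False
    return True


def build_unified_db(sources: Sequence[tuple[str, str | Path]]) -> UnifiedDB:
    """Merge annotation sources into a unified collection.

    Parameters
    ----------
    sources
        Sequence of ``(source_name, path)`` with source_name one of
        ``hmdb``, ``chebi``, ``kegg``, ``smpdb``.  Rows sharing any external
        cross-reference are merged transitively (union-find closure);
        conflicting scalar fields are resolved by source priority
        HMDB > ChEBI > KEGG > SMPDB, with per-field provenance retained.

    Notes
    -----
    A single external id claimed by two records that cannot merge (they carry
    different ids in the same namespace) produces a conflict report; the
    records are kept split and the contested id keeps its first owner.
    """
    for name, _ in sources:
        if name not in SOURCE_PRIORITY:
            raise ConfigurationError(f"unknown annotation source {name!r}")
    all_rows: list[dict] = []
    for name, path in sorted(sources, key=lambda s: SOURCE_PRIORITY[s[0]]):
        all_rows.extend(_source_rows(name, path))

    db = UnifiedDB()
    # merged[i] holds the accumulated fields for local record i
    merged: list[dict] = []
    local_ids: list[str] = []
    token_owner: dict[str, int] = {}

    for row in all_rows:
        source = row["_source"]
        fields_new = _row_to_fields(row)
        tokens = _fields_tokens(fields_new)
        owners = sorted({token_owner[t] for t in tokens if t in token_owner})
        target = None
        conflict = False
        for o in owners:
            if _mergeable(merged[o], fields_new):
                if target is None:
                    target = o
                elif _mergeable(merged[o], merged[target]):
                    # transitive closure: fold record o into target
                    _merge_fields(merged[target], merged[o],
                                  db.provenance[local_ids[target]],
                                  db.provenance[local_ids[o]])
                    for t, own in token_owner.items():
                        if own == o:
                            token_owner[t] = target
                    merged[o] = {}
                else:
                    conflict = True
            else:
                conflict = True
        if target is None:
            idx = len(merged)
            lid = f"UDB{idx + 1:05d}"
            merged.append(dict(fields_new))
            local_ids.append(lid)
            db.provenance[lid] = {k: source for k, v in fields_new.items() if v}
        else:
            idx = target
            lid = local_ids[idx]
            prov_new = {k: source for k, v in fields_new.items() if v}
            _merge_fields(merged[idx], fields_new, db.provenance[lid], prov_new)
        if conflict:
            msg = (f"external id(s) {tokens} claimed by non-mergeable records; "
                   f"kept split (row from source {source!r})")
            db.conflicts.append(msg)
            logger.warning(msg)
        for t in tokens:
            token_owner.setdefault(t, idx)

    for idx, fields_m in enumerate(merged):
        if not fields_m:
            continue
        lid = local_ids[idx]
        db.records.append(MetaboliteRecord(local_id=lid, **fields_m))
    for t, own in token_owner.items():
        if merged[own]:
            db.crossrefs[t] = local_ids[own]
    for rec in db.records:
        if rec.name:
            db.crossrefs.setdefault(f"name:{rec.name.lower()}", rec.local_id)
    return db


def _merge_fields(base: dict, extra: Mapping, prov_base: dict, prov_extra: Mapping) -> None:
    """Fold ``extra`` into ``base``; base wins scalar conflicts (it was added
    earlier, i.e. from the higher-priority source)."""
    for key in _SCALAR_FIELDS:
        if not base.get(key) and extra.get(key):
            base[key] = extra[key]
            if key in prov_extra:
                prov_base[key] = prov_extra[key]
    for key in ("smpdb_ids", "pathways", "biological_roles"):
        combined = list(base.get(key, ()))
        for v in extra.get(key, ()):
            if v not in combined:
                combined.append(v)
        base[key] = tuple(combined)
        if combined and key not in prov_base and key in prov_extra:
            prov_base[key] = prov_extra[key]
    # keep the alternative name in provenance for transparency
    if extra.get("name") and base.get("name") and extra["name"] != base["name"]:
        prov_base.setdefault("alt_names", "")
        if extra["name"] not in prov_base["alt_names"]:
            prov_base["alt_names"] = (prov_base["alt_names"] + "|" + extra["name"]).strip("|")


def annotate_metabolites(
    table: IntensityTable,
    db: UnifiedDB,
    unresolved_warn_fraction: float = 0.5,
) -> tuple[list[MetaboliteRecord], dict]:
    """Attach unified annotation records to a table's metabolites.

    Resolution is exact id/token match first, then case-insensitive name
    match; anything else gets a stub record with class ``unclassified``.
    Returns the aligned record list and a resolution report.
    """
    records: list[MetaboliteRecord] = []
    n_resolved = 0
    for mid in table.metabolite_ids:
        rec = db.resolve(mid)
        if rec is None:
            rec = db.resolve(f"name:{mid.lower()}")
        if rec is None:
            records.append(MetaboliteRecord(local_id=mid, name=mid))
        else:
            n_resolved += 1
            records.append(rec)
    n = len(records)
    report = {
        "tissue": table.tissue,
        "platform": table.platform,
        "n_metabolites": n,
        "n_resolved": n_resolved,
        "n_unresolved": n - n_resolved,
        "resolution_rate": n_resolved / n if n else float("nan"),
    }
    if n and (n - n_resolved) / n > unresolved_warn_fraction:
        warnings.warn(
            f"{table.tissue}/{table.platform}: unresolved fraction "
            f"{(n - n_resolved) / n:.2f} exceeds {unresolved_warn_fraction}",
            stacklevel=2)
    return records, report
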