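"""Permutation tests, effect sizes and screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metmap import diffstats as ds
from metmap import preprocess as pp
from metmap import synthdata
from metmap.errors import MetmapError
from metmap.synthdata import CohortSpec, EffectSpec, MissingnessSpec

from conftest import make_intensity_frame


class TestMwuExact:
    def test_separated_groups_enumeration(self):
        u, p = ds.mwu_exact([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme

    def test_identical_multisets(self):
        _, p = ds.mwu_exact([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_all_ties(self):
        u, p = ds.mwu_exact([1, 1], [1, 1])
        assert u == 2.0  # E[U] = n1*n2/2
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(MetmapError):
            ds.mwu_exact([], [1.0])


class TestMwuPermutation:
    def test_matches_exact_on_small_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(0.8, size=6)
            _, p_exact = ds.mwu_exact(x, y)
            res = ds.mwu_permutation(x, y, n_perms=20_000, seed=1)
            se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
            assert abs(res["p_perm"] - p_exact) < 3 * se + 1e-4

    def test_minimum_attainable_p(self):
        x = np.arange(10.0)
        y = np.arange(100.0, 110.0)
        res = ds.mwu_permutation(x, y, n_perms=2000, seed=0)
        assert res["p_perm"] == pytest.approx(1 / 2001)

    def test_small_n_perms_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            ds.mwu_permutation([1, 2, 3.0], [4, 5, 6.0], n_perms=500, seed=0)

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=9)
        a = ds.mwu_permutation(x, y, n_perms=5000, seed=9)["p_perm"]
        b = ds.mwu_permutation(x, y, n_perms=5000, seed=9)["p_perm"]
        c = ds.mwu_permutation(x[::-1], y[::-1], n_perms=5000, seed=9)["p_perm"]
        assert a == b == c


class TestFoldChangeCI:
    def test_identical_groups_effect_zero(self):
        x = np.array([1.0, 2, 3, 4])
        effect, ci = ds.fold_change_ci(x, x, n_boot=2000, seed=0)
        assert effect == 0.0
        assert ci[0] <= 0 <= ci[1]

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(1, 1, size=10)
        e1, ci1 = ds.fold_change_ci(x, y, n_boot=4000, seed=5)
        e2, ci2 = ds.fold_change_ci(y, x, n_boot=4000, seed=5)
        assert e1 == pytest.approx(-e2)
        assert ci1[0] == pytest.approx(-ci2[1], abs=0.1)

    def test_tiny_group_suppresses_ci(self):
        effect, ci = ds.fold_change_ci([1.0, 2, 3], [5.0, 6], seed=0)
        assert ci is None and effect == pytest.approx(3.5)


def _scaled_from(matrix, tissue="muscle", samples=None):
    df = make_intensity_frame(matrix, samples=samples)
    return pp.ScaledTable(tissue, df)


def _samples_for(sample_ids, groups):
    from metmap.ingest_annotate import SampleRecord
    hb = {"control": 5.0, "prediabetes": 6.0, "T2D": 8.0}
    return [SampleRecord(sid, g, hb[g], 40.0, 10.0, 60.0, 25.0, "F", 100.0)
            for sid, g in zip(sample_ids, groups)]


class TestDifferentialScreen:
    def test_alpha_zero_nothing_significant(self, muscle_scaled, cohort):
        res = ds.differential_screen({"muscle": muscle_scaled}, cohort,
                                     alpha=0.0, n_perms=2000, n_boot=500, seed=0)
        assert not res["significant"].any()

    def test_single_group_tissue_skipped(self, muscle_scaled, cohort):
        controls = [s for s in cohort if s.phenotype == "control"]
        with pytest.warns(UserWarning, match="skipped"):
            res = ds.differential_screen({"muscle": muscle_scaled}, controls,
                                         n_perms=2000, n_boot=500, seed=0)
        assert res.empty

    def test_planted_effect_direction(self, cohort, small_annotation):
        effects = EffectSpec.from_tuples([("LPC", "muscle", "T2D_vs_nonDM", -2.0)])
        data = synthdata.generate_intensities(
            cohort, small_annotation, effects, MissingnessSpec(0, 0),
            seed=2, tissues=("muscle",))
        st_ = pp.preprocess_tissue(data.intensity_tables[("muscle", "GC-MS")],
                                   data.intensity_tables[("muscle", "LC-MS")])
        res = ds.differential_screen({"muscle": st_}, data.samples,
                                     n_perms=5000, n_boot=1000, seed=0)
        lpc = {r.local_id for r in small_annotation if r.sub_class == "LPC"}
        hits = res[res.metabolite_id.isin(lpc)]
        assert hits.significant.mean() > 0.8
        assert (hits.effect < 0).mean() > 0.8


class TestPairwiseScreen:
    def test_early_marker_pattern(self, small_annotation):
        cohort = synthdata.generate_cohort(CohortSpec(seed=21))
        effects = EffectSpec.from_tuples([("LPC", "muscle", "PD_vs_CTRL", -2.0)])
        data = synthdata.generate_intensities(
            cohort, small_annotation, effects, MissingnessSpec(0, 0),
            seed=21, tissues=("muscle",))
        st_ = pp.preprocess_tissue(data.intensity_tables[("muscle", "GC-MS")],
                                   data.intensity_tables[("muscle", "LC-MS")])
        res = ds.pairwise_screen({"muscle": st_}, data.samples,
                                 n_perms=5000, n_boot=500, seed=0)
        lpc = {r.local_id for r in small_annotation if r.sub_class == "LPC"}
        patterns = (res[res.metabolite_id.isin(lpc)]
                    .drop_duplicates(["metabolite_id"])["pattern"])
        assert (patterns == "early").mean() >= 0.5


class TestRegressionHbA1c:
    def test_exact_linear_relation(self, cohort):
        h = np.array([s.hba1c_percent for s in cohort])
        mat = np.vstack([(h - h.mean()) / h.std(ddof=1)])
        scaled = _scaled_from(mat, samples=[s.sample_id for s in cohort])
        res = ds.regression_hba1c({"muscle": scaled}, cohort, n_perms=2000, seed=0)
        row = res.iloc[0]
        assert row.adj_r2 == pytest.approx(1.0)
        assert row.p_perm == pytest.approx(1 / 2001)

    def test_matches_f_test_under_null(self, cohort):
        from scipy import stats as sstats
        rng = np.random.default_rng(8)
        mat = rng.standard_normal((3, len(cohort)))
        scaled = pp.scale_zscore(
            make_intensity_frame(mat, samples=[s.sample_id for s in cohort]),
            tissue="t")
        res = ds.regression_hba1c({"t": scaled}, cohort, n_perms=20_000, seed=0)
        h = np.array([s.hba1c_percent for s in cohort])
        for _, row in res.iterrows():
            v = scaled.values.loc[row.metabolite_id].to_numpy()
            lr = sstats.linregress(v, h)
            se = np.sqrt(lr.pvalue * (1 - lr.pvalue) / 20_000)
            assert abs(row.p_perm - lr.pvalue) < 3 * se + 5e-3

    def test_adj_r2_negative_for_noise(self):
        samples = _samples_for([f"S{i}" for i in range(30)],
                               ["control"] * 15 + ["T2D"] * 15)
        rng = np.random.default_rng(0)
        found_negative = False
        for seed in range(5):
            mat = np.random.default_rng(seed).standard_normal((5, 30))
            scaled = _scaled_from(mat, samples=[s.sample_id for s in samples])
            res = ds.regression_hba1c({"muscle": scaled}, samples,
                                      n_perms=1000, seed=seed)
            found_negative |= (res.adj_r2 < 0).any()
        assert found_negative

    def test_constant_hba1c_rejected(self):
        samples = _samples_for([f"S{i}" for i in range(10)], ["control"] * 10)
        mat = np.random.default_rng(0).standard_normal((2, 10))
        scaled = _scaled_from(mat, samples=[s.sample_id for s in samples])
        with pytest.raises(MetmapError, match="constant"):
            ds.regression_hba1c({"muscle": scaled}, samples, n_perms=1000, seed=0)


class TestPairRatios:
    def test_self_pair_skipped(self, muscle_scaled, cohort):
        mid = muscle_scaled.metabolite_ids[0]
        res = ds.pair_ratios(muscle_scaled, cohort, pairs=[(mid, mid)],
                             n_perms=1000, seed=0)
        assert res.empty

    def test_opposite_effects_gain(self):
        rng = np.random.default_rng(5)
        n = 43
        groups = ["control"] * 30 + ["T2D"] * 13
        samples = _samples_for([f"S{i}" for i in range(n)], groups)
        shift = np.array([0.0] * 30 + [0.8] * 13)
        a = rng.standard_normal(n) + shift
        b = rng.standard_normal(n) - shift
        scaled = pp.scale_zscore(
            make_intensity_frame(np.vstack([a, b]),
                                 samples=[s.sample_id for s in samples]),
            tissue="muscle")
        res = ds.pair_ratios(scaled, samples, n_perms=5000, seed=0)
        row = res.iloc[0]
        assert row.p_ratio <= row.p_single_min
        assert row.p_gain >= 1.0

    def test_quadratic_blowup_guard(self, muscle_scaled, cohort):
        with pytest.raises(MetmapError, match="pairs"):
            ds.pair_ratios(muscle_scaled, cohort, max_pairs=10, seed=0)


class TestProperties:
    @settings(max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_exact_p_symmetric_in_groups(self, seed):
        """Two-sided exact p is invariant to swapping the groups."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, size=4).astype(float)
        y = rng.integers(0, 8, size=5).astype(float)
        _, p1 = ds.mwu_exact(x, y)
        _, p2 = ds.mwu_exact(y, x)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_screen_invariant_to_sample_order(self, cohort, muscle_scaled):
        res1 = ds.differential_screen({"muscle": muscle_scaled}, cohort,
                                      n_perms=2000, n_boot=500, seed=3)
        shuffled = list(reversed(cohort))
        res2 = ds.differential_screen({"muscle": muscle_scaled}, shuffled,
                                      n_perms=2000, n_boot=500, seed=3)
        assert np.allclose(res1.p_perm, res2.p_perm)
        assert np.allclose(res1.effect, res2.effect)
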