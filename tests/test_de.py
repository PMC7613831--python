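"""Differential-expression engine: size factors, dispersion, Wald test,
BH adjustment, DEG calling, concordance and corrected fractions."""

import numpy as np
import pandas as pd
import pytest

import renofao as rf
from renofao.de import DEGSet, _round_half_away
from renofao.synthetic import ModuleSpec


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


class TestSizeFactors:
    def test_doubled_column_gives_sqrt2_pair(self):
        df = pd.DataFrame([[10, 20], [100, 200], [1, 2]], columns=["a", "b"])
        sf = rf.estimate_size_factors(df)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame([[5, 5, 5], [9, 9, 9]], columns=list("abc"))
        assert np.allclose(rf.estimate_size_factors(df), 1.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(42)
        mat = pd.DataFrame(rng.integers(1, 500, size=(5, 4)), columns=list("abcd"))
        arr = mat.to_numpy(float)
        geo = np.exp(np.mean(np.log(arr), axis=1))
        expected = np.median(arr / geo[:, None], axis=0)
        assert np.allclose(rf.estimate_size_factors(mat), expected)

    def test_all_zero_rows_raise(self):
        df = pd.DataFrame([[0, 5], [3, 0]], columns=["a", "b"])
        with pytest.raises(ValueError):
            rf.estimate_size_factors(df)


class TestDispersion:
    @staticmethod
    def _study(seed, dispersion, n_per_group, n_genes=300):
        cfg = rf.SyntheticStudyConfig(
            seed=seed, dispersion=dispersion, n_genes=n_genes,
            n_per_group={g: n_per_group for g in ("healthy", "SHAM", "DMT")},
            fao_module=ModuleSpec((), 0.0), fibrosis_module=ModuleSpec((), 0.0),
        )
        cm, _ = rf.generate_count_study(cfg, "ZDF")
        return cm

    def test_constant_counts_hit_the_floor(self):
        counts = pd.DataFrame(7, index=["g1", "g2"], columns=["a", "b", "c", "d"])
        meta = pd.DataFrame({"group": ["x", "x", "y", "y"], "model": "m"},
                            index=counts.columns)
        cm = rf.CountMatrix(counts, meta)
        disp = rf.estimate_dispersion(cm, pd.Series(1.0, index=counts.columns))
        assert np.allclose(disp, 1e-8)

    def test_near_poisson_counts_give_small_alpha(self):
        cm = self._study(seed=5, dispersion=1e-6, n_per_group=50)
        disp = rf.estimate_dispersion(cm, rf.estimate_size_factors(cm))
        assert np.median(disp) <= 0.01

    def test_recovers_planted_dispersion_at_large_n(self):
        cm = self._study(seed=6, dispersion=0.5, n_per_group=200)
        disp = rf.estimate_dispersion(cm, rf.estimate_size_factors(cm))
        assert 0.4 <= np.median(disp) <= 0.6

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame([[1, 2, 3]], index=["g1"], columns=["a", "b", "c"])
        meta = pd.DataFrame({"group": ["x", "x", "y"], "model": "m"},
                            index=counts.columns)
        cm = rf.CountMatrix(counts, meta)
        with pytest.raises(ValueError):
            rf.estimate_dispersion(cm, pd.Series(1.0, index=counts.columns))


class TestWald:
    def test_identical_group_means_give_null_result(self):
        counts = pd.DataFrame(
            {"a": [10, 40], "b": [20, 80], "c": [10, 40], "d": [20, 80]},
            index=["g1", "g2"],
        )
        meta = pd.DataFrame({"group": ["x", "x", "y", "y"], "model": "m"},
                            index=counts.columns)
        cm = rf.CountMatrix(counts, meta)
        res = rf.wald_test(cm, ("y", "x"))
        assert np.allclose(res["log2FC"], 0.0)
        assert np.allclose(res["stat"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_planted_effect_estimated_unbiasedly(self):
        cfg = rf.SyntheticStudyConfig(seed=2)
        cm, truth = rf.generate_count_study(cfg, "ZDSD")
        res = rf.wald_test(cm, ("DMT", "SHAM"))
        fao = list(cfg.fao_module.genes)
        assert abs(res.loc[fao, "log2FC"].mean() - 1.5) <= 0.15

    def test_all_zero_genes_flagged_with_p_one(self):
        counts = pd.DataFrame(
            {"a": [0, 10], "b": [0, 12], "c": [0, 9], "d": [0, 11]},
            index=["gz", "g1"],
        )
        meta = pd.DataFrame({"group": ["x", "x", "y", "y"], "model": "m"},
                            index=counts.columns)
        cm = rf.CountMatrix(counts, meta)
        res = rf.wald_test(cm, ("y", "x"), pd.Series(1.0, index=counts.columns),
                           pd.Series(0.05, index=counts.index))
        assert res.loc["gz", "allzero"]
        assert res.loc["gz", "p"] == 1.0
        assert res.loc["gz", "log2FC"] == 0.0


class TestBH:
    def test_single_p_unchanged(self):
        assert rf.adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        out = rf.adjust_bh([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(out, [0.04, 0.04, 0.05, 0.05])

    def test_equal_entries_unchanged(self):
        assert np.allclose(rf.adjust_bh([0.2, 0.2, 0.2]), 0.2)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(rf.adjust_bh(p), bh_oracle(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rf.adjust_bh([0.5, 1.2])


class TestDEGCalling:
    @staticmethod
    def _de(rows):
        df = pd.DataFrame(rows, columns=["log2FC", "padj"],
                          index=[f"g{i}" for i in range(len(rows))])
        df.attrs["contrast"] = "t_vs_c"
        return df

    def test_threshold_boundaries(self):
        de = self._de([
            (0.5, 0.01),                 # FC~1.41 -> in, up
            (np.log2(1.2), 0.001),       # FC 1.2 -> out
            (np.log2(1.3), 0.049),       # exactly 1.3 -> in (inclusive)
            (-np.log2(1.3), 0.05),       # padj not < 0.05 -> out
        ])
        degs = rf.call_degs(de)
        assert degs.directions == {"g0": "up", "g2": "up"}

    def test_concordance_requires_same_direction(self):
        a = DEGSet("c", {"g1": "up", "g2": "up", "g3": "down"})
        b = DEGSet("c", {"g1": "up", "g2": "down", "g4": "down"})
        conc = rf.concordant_degs(a, b)
        assert conc.directions == {"g1": "up"}

    def test_concordance_idempotent_and_symmetric(self):
        a = DEGSet("c", {"g1": "up", "g2": "down"})
        b = DEGSet("c", {"g2": "down", "g3": "up"})
        assert rf.concordant_degs(a, a).directions == a.directions
        assert (rf.concordant_degs(a, b).directions
                == rf.concordant_degs(b, a).directions)


class TestCorrectedFraction:
    def test_opposite_direction_counts(self):
        disease = DEGSet("d", {"g1": "up", "g2": "up", "g3": "down", "g4": "up"})
        treatment = DEGSet("t", {"g1": "down", "g2": "up", "g3": "up"})
        n, pct = rf.corrected_fraction(disease, treatment)
        assert (n, pct) == (2, 50.0)

    def test_any_direction_switch(self):
        disease = DEGSet("d", {"g1": "up", "g2": "up"})
        treatment = DEGSet("t", {"g1": "up"})
        assert rf.corrected_fraction(disease, treatment)[0] == 0
        assert rf.corrected_fraction(disease, treatment, any_direction=True)[0] == 1

    def test_zero_overlap(self):
        disease = DEGSet("d", {"g1": "up"})
        treatment = DEGSet("t", {"g9": "down"})
        assert rf.corrected_fraction(disease, treatment) == (0, 0.0)

    def test_empty_disease_set_is_an_error(self):
        with pytest.raises(ValueError):
            rf.corrected_fraction(DEGSet("d", {}), DEGSet("t", {"g": "up"}))

    def test_percentage_rounding_half_away_from_zero(self):
        assert _round_half_away(54.35, 1) == 54.4
        assert _round_half_away(26.04, 1) == 26.0


class TestTransforms:
    def test_rlog_like_values(self):
        counts = pd.DataFrame({"a": [0, 2], "b": [0, 3]}, index=["g1", "g2"])
        sf = pd.Series({"a": 2.0, "b": 3.0})
        out = rf.rlog_like_transform(counts, sf)
        assert out.loc["g1", "a"] == 0.0
        assert out.loc["g2", "a"] == 1.0  # k == s -> log2(2) = 1
        assert out.loc["g2", "b"] == 1.0

    def test_rlog_monotone_within_sample(self):
        counts = pd.DataFrame({"a": [1, 5, 50]}, index=["g1", "g2", "g3"])
        out = rf.rlog_like_transform(counts, pd.Series({"a": 1.3}))
        assert out["a"].is_monotonic_increasing

    def test_pca_mirrored_samples(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["s1", "s2"])
        scores, _, frac = rf.pca_scores(m, 1)
        assert scores.iloc[0, 0] == pytest.approx(-scores.iloc[1, 0])
        assert frac[0] == pytest.approx(1.0)

    def test_pca_variance_fractions_nonincreasing_and_reconstruction(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(6, 5)))
        scores, loadings, frac = rf.pca_scores(m, 5)
        assert np.all(np.diff(frac) <= 1e-12)
        centered = m - m.mean(axis=0)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        assert np.allclose(recon, centered.to_numpy(), atol=1e-8)
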