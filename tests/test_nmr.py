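"""NMR processing: baseline, CWT peak detection, grouping, silhouette gate,
peak filling and PQN."""

import numpy as np
import pandas as pd
import pytest

import renofao as rf
from renofao.nmr import (
    Spectrum,
    build_intensity_matrix,
    estimate_baseline,
    group_silhouettes,
)


def gaussian_spectrum(centers, amps, sigma=0.005, n=12000, lo=0.2, hi=10.0,
                      sample_id="s", group="", offset=0.0, noise=None):
    ppm = np.linspace(lo, hi, n)
    y = np.full(n, float(offset))
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((ppm - c) / sigma) ** 2)
    if noise is not None:
        y = y + noise
    return Spectrum(ppm, y, sample_id, group)


class TestBaseline:
    def test_constant_offset_recovered_away_from_peaks(self):
        s = gaussian_spectrum([3.0, 7.0], [50, 80], offset=5.0)
        base = estimate_baseline(s.intensity)
        mask = (np.abs(s.ppm - 3.0) > 0.2) & (np.abs(s.ppm - 7.0) > 0.2)
        assert np.max(np.abs(base[mask] - 5.0)) <= 0.05

    def test_zero_spectrum_stays_zero(self):
        s = Spectrum(np.linspace(0, 10, 5000), np.zeros(5000), "s")
        out = rf.baseline_correct(s)
        assert np.allclose(out.intensity, 0.0)

    def test_linear_ramp_removed(self):
        ppm = np.linspace(0, 10, 10000)
        ramp = 4.0 * ppm
        s = Spectrum(ppm, ramp, "s")
        out = rf.baseline_correct(s)
        assert np.max(np.abs(out.intensity)) <= 0.02 * 40.0

    def test_idempotent_within_tolerance(self):
        s = gaussian_spectrum([3.0], [50], offset=2.0)
        once = rf.baseline_correct(s)
        twice = rf.baseline_correct(once)
        mask = np.abs(s.ppm - 3.0) > 0.2
        assert np.max(np.abs(once.intensity[mask] - twice.intensity[mask])) <= 0.5

    def test_parameter_validation(self):
        s = Spectrum(np.linspace(0, 1, 100), np.zeros(100), "s")
        with pytest.raises(ValueError):
            rf.baseline_correct(s, window=500)
        with pytest.raises(ValueError):
            rf.baseline_correct(s, window=50, step=80)


class TestDetection:
    def test_single_noiseless_gaussian_located_at_center(self):
        s = gaussian_spectrum([3.0], [10])
        peaks = rf.detect_peaks_cwt(s)
        step = s.ppm[1] - s.ppm[0]
        assert len(peaks) == 1
        assert abs(peaks["ppm"].iloc[0] - 3.0) <= step

    def test_two_well_separated_gaussians(self):
        s = gaussian_spectrum([3.0, 3.1], [10, 12])  # 20 sigma apart
        peaks = rf.detect_peaks_cwt(s)
        assert len(peaks) == 2

    def test_white_noise_rarely_triggers(self):
        rng = np.random.default_rng(4)
        detections = 0
        n_sim = 100
        for _ in range(n_sim):
            s = Spectrum(np.linspace(0.2, 10, 4000), rng.normal(0, 1, 4000), "s")
            detections += len(rf.detect_peaks_cwt(s, scales=tuple(range(2, 17, 2)),
                                                  min_snr=5.0))
        assert detections / n_sim < 0.5

    def test_scale_validation(self):
        s = gaussian_spectrum([3.0], [10])
        with pytest.raises(ValueError):
            rf.detect_peaks_cwt(s, scales=(5,))
        with pytest.raises(ValueError):
            rf.detect_peaks_cwt(s, min_snr=0)


class TestGrouping:
    @staticmethod
    def _peaklist(sample_id, positions, intensities=None):
        intensities = intensities or [10.0] * len(positions)
        return pd.DataFrame({
            "sample_id": sample_id, "ppm": positions,
            "intensity": intensities, "scale": 4, "snr": 50.0,
        })

    def test_nearby_peaks_group_to_median_position(self):
        lists = [self._peaklist("a", [2.999]), self._peaklist("b", [3.000]),
                 self._peaklist("c", [3.001])]
        out = rf.group_peaks(lists, tolerance=0.01)
        assert out["group"].nunique() == 1
        assert out["group_ppm"].iloc[0] == pytest.approx(3.000)

    def test_distant_peak_forms_separate_group(self):
        lists = [self._peaklist("a", [3.0, 5.0]), self._peaklist("b", [3.001])]
        out = rf.group_peaks(lists, tolerance=0.01)
        assert out["group"].nunique() == 2

    def test_duplicate_sample_peak_keeps_most_intense(self):
        lists = [self._peaklist("a", [3.000, 3.002], [5.0, 9.0]),
                 self._peaklist("b", [3.001])]
        out = rf.group_peaks(lists, tolerance=0.01)
        # the group containing sample b keeps only a's most intense peak
        main_group = out.loc[out["sample_id"] == "b", "group"].iloc[0]
        a_rows = out[(out["group"] == main_group) & (out["sample_id"] == "a")]
        assert len(a_rows) == 1
        assert a_rows["intensity"].iloc[0] == 9.0
        # the weaker duplicate is re-pooled into a group of its own
        assert len(out) == 3
        assert out["group"].nunique() == 2


class TestSilhouette:
    def test_hand_computed_two_cluster_value(self):
        members = pd.DataFrame({
            "sample_id": ["a", "b", "a", "b"],
            "ppm": [1.0, 1.1, 5.0, 5.1],
            "intensity": 1.0, "scale": 4, "snr": 50.0,
            "group": [0, 0, 1, 1],
        })
        sil = group_silhouettes(members)
        # s(1.0) = (4.05 - 0.1)/4.05, s(1.1) = (3.95 - 0.1)/3.95;
        # the group value is the mean of its members' silhouettes
        assert sil.loc[0] == pytest.approx((3.95 / 4.05 + 3.85 / 3.95) / 2, abs=1e-9)
        assert sil.loc[0] > 0.97
        out = rf.silhouette_filter(members)
        assert out["group"].nunique() == 2
        assert (out["silhouette"] >= 0.6).all()

    def test_merged_group_dissolved_and_resplit(self):
        members = pd.DataFrame({
            "sample_id": ["a", "b", "a", "b", "a", "b"],
            "ppm": [1.0, 1.1, 5.0, 5.1, 9.0, 9.05],
            "intensity": 1.0, "scale": 4, "snr": 50.0,
            "group": [0, 0, 0, 0, 1, 1],
        })
        out = rf.silhouette_filter(members, tolerance=0.5)
        groups = out.groupby("group")["ppm"].apply(list)
        assert len(groups) == 3
        assert (out["silhouette"] >= 0.6).all()

    def test_single_group_kept_with_unit_silhouette(self):
        members = pd.DataFrame({
            "sample_id": ["a", "b"], "ppm": [3.0, 3.001],
            "intensity": 1.0, "scale": 4, "snr": 50.0, "group": [0, 0],
        })
        out = rf.silhouette_filter(members)
        assert out["silhouette"].eq(1.0).all()


class TestFillAndPQN:
    def test_fill_from_zero_spectrum_gives_zero(self):
        matrix = pd.DataFrame({3.0: [np.nan]}, index=["s"])
        spec = Spectrum(np.linspace(0, 10, 1000), np.zeros(1000), "s")
        out = rf.fill_peaks(matrix, [spec])
        assert out.loc["s", 3.0] == 0.0

    def test_fill_recovers_missed_planted_peak(self):
        s = gaussian_spectrum([3.0], [8.0], sample_id="s")
        matrix = pd.DataFrame({3.0: [np.nan]}, index=["s"])
        out = rf.fill_peaks(matrix, [s], half_width=0.01)
        assert out.loc["s", 3.0] == pytest.approx(8.0, rel=0.05)

    def test_fill_leaves_complete_matrix_unchanged(self):
        matrix = pd.DataFrame({3.0: [5.0], 4.0: [6.0]}, index=["s"])
        s = gaussian_spectrum([3.0], [8.0], sample_id="s")
        assert rf.fill_peaks(matrix, [s]).equals(matrix)

    def test_pqn_exact_factor_for_scaled_sample(self):
        ref = pd.Series([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame([ref.to_numpy(), (3 * ref).to_numpy()], index=["r", "s"])
        norm, factors = rf.pqn_normalize(m)
        assert factors["s"] / factors["r"] == pytest.approx(3.0)
        assert np.allclose(norm.loc["s"], norm.loc["r"])

    def test_pqn_identical_samples_all_unit_factors(self):
        m = pd.DataFrame([[1.0, 2.0]] * 4, index=list("abcd"))
        _, factors = rf.pqn_normalize(m)
        assert np.allclose(factors, 1.0)

    def test_pqn_scale_equivariance(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.uniform(1, 10, size=(5, 12)))
        norm, factors = rf.pqn_normalize(m)
        m2 = m.copy()
        m2.iloc[2] *= 7.0
        norm2, factors2 = rf.pqn_normalize(m2, reference=m.median(axis=0))
        assert factors2.iloc[2] == pytest.approx(7.0 * factors.iloc[2])
        assert np.allclose(norm2.iloc[2], norm.iloc[2])

    def test_pqn_rejects_missing_or_all_zero(self):
        with pytest.raises(ValueError):
            rf.pqn_normalize(pd.DataFrame({0: [1.0, np.nan]}))
        with pytest.raises(ValueError):
            rf.pqn_normalize(pd.DataFrame({0: [1.0, 0.0], 1: [1.0, 0.0]}))


class TestCohortComposition:
    def test_doubled_dilution_doubles_integrated_intensity(self, default_config):
        import copy
        cfg1 = copy.deepcopy(default_config)
        cfg1.nmr_specs.noise_sd = 0.0
        cfg1.nmr_specs.baseline_amplitude = 0.0
        cfg1.nmr_specs.biological_cv = 0.0
        cfg1.nmr_specs.dilution_range = (1.0, 1.0)
        cfg1.nmr_specs.group_sizes = {"healthy": 1}
        s1, _ = rf.generate_nmr_cohort(cfg1)
        cfg2 = copy.deepcopy(cfg1)
        cfg2.nmr_specs.dilution_range = (2.0, 2.0)
        s2, _ = rf.generate_nmr_cohort(cfg2)
        assert np.trapezoid(s2[0].intensity, s2[0].ppm) == pytest.approx(
            2.0 * np.trapezoid(s1[0].intensity, s1[0].ppm), rel=1e-6)

    def test_pipeline_recovers_planted_structure(self, nmr_cohort, processed_cohort):
        _, truth = nmr_cohort
        out = processed_cohort
        assert out["matrix"].isna().sum().sum() == 0
        assert (out["members"]["silhouette"] >= 0.6).all()
        planted = sorted(float(p) for p in truth.peak_families)
        cols = list(out["matrix"].columns)
        recovered = sum(any(abs(c - p) <= 0.01 for c in cols) for p in planted)
        assert recovered / len(planted) >= 0.95

    def test_pqn_recovers_planted_dilutions(self, nmr_cohort, processed_cohort):
        _, truth = nmr_cohort
        factors = processed_cohort["factors"]
        dil = pd.Series(truth.dilution).loc[factors.index]
        ratio = (factors / dil).to_numpy()
        rel = np.abs(ratio / np.exp(np.mean(np.log(ratio))) - 1)
        assert rel.max() <= 0.02
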