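"""Observation-index arithmetic: RMS/MF/MPF closed forms and oracles,
House-Brackmann efficacy summaries, and the two-group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoview import clinical, synth


class TestRms:
    def test_constant_signal(self):
        assert clinical.rms(np.full(100, -3.0)) == pytest.approx(3.0)

    def test_alternating_unit_signal(self):
        assert clinical.rms(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(1.0)

    def test_sine_closed_form(self):
        t = np.arange(10_000) / 1000.0
        x = 2.0 * np.sin(2 * np.pi * 50 * t)  # integer number of periods
        assert clinical.rms(x) == pytest.approx(2.0 / np.sqrt(2.0), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            clinical.rms(np.array([]))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_naive_loop(self, seed):
        x = np.random.default_rng(seed).standard_normal(1000)
        naive = (sum(v * v for v in x) / len(x)) ** 0.5
        assert abs(clinical.rms(x) - naive) < 1e-12


class TestPowerSpectrum:
    def test_pure_sine_peak_bin(self):
        t = np.arange(4096) / 1000.0
        x = np.sin(2 * np.pi * 100 * t)
        freqs, pxx = clinical.power_spectrum(x, 1000.0)
        assert freqs[np.argmax(pxx)] == pytest.approx(100.0, abs=freqs[1])

    def test_parseval_total_power(self):
        x = np.random.default_rng(0).standard_normal(2**15)
        freqs, pxx = clinical.power_spectrum(x, 1000.0)
        total = np.trapezoid(pxx, freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_zero_signal_zero_spectrum(self):
        freqs, pxx = clinical.power_spectrum(np.zeros(1024), 1000.0)
        assert np.all(pxx == 0)

    def test_bad_fs_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            clinical.power_spectrum(np.ones(10), 0.0)


class TestMedianFrequency:
    def test_single_nonzero_bin(self):
        freqs = np.array([0.0, 50.0, 100.0, 150.0])
        pxx = np.array([0.0, 0.0, 4.0, 0.0])
        assert clinical.median_frequency(freqs, pxx) == pytest.approx(100.0, abs=50.0 / 2)

    def test_flat_band_symmetry(self, flat_band_recording):
        x = flat_band_recording.samples[:, 0]
        freqs, pxx = clinical.power_spectrum(x, 1000.0, nperseg=1024)
        assert clinical.median_frequency(freqs, pxx) == pytest.approx(110.0, abs=5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_within_one_bin_of_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.arange(0, 500.0, 3.90625)
        pxx = rng.random(freqs.size)
        # oracle: first frequency where the running power sum reaches half
        total, acc, crossing = pxx.sum(), 0.0, None
        for f, p in zip(freqs, pxx):
            acc += p
            if acc >= total / 2:
                crossing = f
                break
        mf = clinical.median_frequency(freqs, pxx)
        assert abs(mf - crossing) <= freqs[1] - freqs[0]

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="zero total power"):
            clinical.median_frequency(np.arange(4.0), np.zeros(4))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mf_and_mpf_inside_spectral_support(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.linspace(0, 500, 129)
        pxx = np.zeros(129)
        lo, hi = sorted(rng.integers(1, 128, size=2).tolist())
        hi = max(hi, lo + 1)
        pxx[lo:hi] = rng.random(hi - lo) + 1e-3
        mf = clinical.median_frequency(freqs, pxx)
        mpf = clinical.mean_power_frequency(freqs, pxx)
        support = freqs[pxx > 0]
        for v in (mf, mpf):
            assert support.min() - (freqs[1] - freqs[0]) <= v <= support.max()


class TestMeanPowerFrequency:
    def test_two_equal_lines(self):
        freqs = np.array([0.0, 50.0, 100.0, 150.0])
        pxx = np.array([0.0, 2.0, 0.0, 2.0])
        assert clinical.mean_power_frequency(freqs, pxx) == pytest.approx(100.0)

    def test_single_line(self):
        freqs = np.array([0.0, 60.0, 120.0])
        pxx = np.array([0.0, 5.0, 0.0])
        assert clinical.mean_power_frequency(freqs, pxx) == pytest.approx(60.0)

    def test_symmetric_spectrum_mf_equals_mpf(self):
        freqs = np.linspace(0, 200, 101)
        pxx = np.exp(-0.5 * ((freqs - 100) / 20) ** 2)
        mf = clinical.median_frequency(freqs, pxx)
        mpf = clinical.mean_power_frequency(freqs, pxx)
        assert mf == pytest.approx(mpf, abs=freqs[1] - freqs[0])


class TestHbSummary:
    def test_reported_control_group_rate(self):
        s = clinical.summarize_counts((39, 17, 3, 11))
        assert s.n == 70
        assert s.effective_rate == 84.29

    def test_reported_treatment_group_rate(self):
        s = clinical.summarize_counts((51, 15, 9, 5))
        assert s.n == 80
        assert s.effective_rate == 93.75

    def test_extreme_rates(self):
        assert clinical.summarize_counts((10, 0, 0, 0)).effective_rate == 100.0
        assert clinical.summarize_counts((0, 0, 0, 7)).effective_rate == 0.0

    def test_rate_invariant_under_duplication(self):
        base = (13, 5, 4, 3)
        doubled = tuple(2 * c for c in base)
        assert (clinical.summarize_counts(base).effective_rate
                == clinical.summarize_counts(doubled).effective_rate)

    def test_from_records_filters_by_group(self):
        records = synth.simulate_cohort(synth.default_cohort_params(), seed=0)
        s = clinical.hb_summary(records, "control")
        assert s.n == 70
        assert sum(s.counts) == 70
        with pytest.raises(ValueError, match="no records"):
            clinical.hb_summary(records, "placebo")


class TestCompareGroups:
    # Pearson chi-square of the dichotomized 2x2 table (59 eff/11 ineff vs
    # 75/5), computed cell by cell with Sigma (O-E)^2/E before the build:
    # E = [62.5333, 7.4667, 71.4667, 8.5333];
    # terms = 0.199645 + 1.672024 + 0.174689 + 1.463021 = 3.509379
    HAND_CHI2 = 3.509379

    def test_chi_square_matches_hand_oracle(self):
        ctrl = clinical.summarize_counts((39, 17, 3, 11))
        trt = clinical.summarize_counts((51, 15, 9, 5))
        rep = clinical.compare_groups(ctrl, trt, kind="rate")
        assert rep.statistic == pytest.approx(self.HAND_CHI2, abs=1e-4)
        assert rep.df == 1

    def test_chi_square_zero_for_identical_proportions(self):
        a = clinical.summarize_counts((30, 10, 10, 10))
        b = clinical.summarize_counts((60, 20, 20, 20))
        rep = clinical.compare_groups(a, b, kind="rate")
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)

    def test_t_test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rep = clinical.compare_groups(x, x, kind="mean")
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)
        assert not rep.significant

    def test_t_test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            clinical.compare_groups(np.ones(5), np.ones(5), kind="mean")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            clinical.compare_groups(np.ones(5), np.zeros(5), kind="median")

    def test_power_at_reported_group_parameters(self):
        """Cohorts drawn at the reported post-treatment buccinator RMS means
        (24.67 vs 18.42 μV, SD 2.4, n = 80/70) are separated by the Welch
        t-test at alpha = 0.05 in essentially every replicate."""
        params = synth.default_cohort_params()
        rejections = 0
        n_reps = 100
        for rep in range(n_reps):
            records = synth.simulate_cohort(params, seed=20_000 + rep)
            a = [r.params[("buccinator", "post")].rms
                 for r in records if r.group == "control"]
            b = [r.params[("buccinator", "post")].rms
                 for r in records if r.group == "treatment"]
            rejections += clinical.compare_groups(a, b, kind="mean").significant
        assert rejections / n_reps >= 0.99
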