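"""Signal-detection metrics: windowed rates, skew-normal fits, thresholds,
error probabilities, SNR and pairwise correlations."""

import math

import numpy as np
import pytest
from scipy import stats as sstats

from micropam.circuit import SpikeData
from micropam.detection import (
    DegenerateInputError,
    SkewNormalFit,
    compute_snr,
    decision_threshold,
    error_rates,
    error_rates_quadrature,
    fit_skew_normal,
    mean_pairwise_correlation,
    window_rates,
)
from micropam.synthetic import gen_poisson_population


def make_spikes(trains, duration=1000.0, types=None):
    types = types if types is not None else np.full(len(trains), "Pyr")
    return SpikeData(spike_times=[np.asarray(t, dtype=float) for t in trains],
                     types=np.asarray(types), duration=duration, dt=0.1)


class TestWindowRates:
    def test_single_spike_rate(self):
        """One spike of one neuron inside a 50 ms window -> 20 Hz."""
        sd = make_spikes([[500.0]], duration=1000.0)
        rw = window_rates(sd, (0.0, 1000.0))
        assert rw.rates.max() == pytest.approx(20.0)

    def test_no_spikes_all_zero(self):
        sd = make_spikes([[], []])
        rw = window_rates(sd, (0.0, 1000.0))
        assert np.all(rw.rates == 0.0)

    def test_window_count_for_3s(self):
        sd = make_spikes([[]], duration=3000.0)
        rw = window_rates(sd, (0.0, 3000.0))
        assert rw.n_windows == 2951

    def test_poisson_mean_converges(self):
        lam = 5.0
        sd = gen_poisson_population(20, lam, 60_000.0, seed=11)
        rw = window_rates(sd, (0.0, 60_000.0))
        # mean window rate -> lambda; SE ~ lam / sqrt(n_eff)
        assert rw.rates.mean() == pytest.approx(lam, rel=0.05)

    def test_interval_shorter_than_window_raises(self):
        sd = make_spikes([[]])
        with pytest.raises(ValueError):
            window_rates(sd, (0.0, 30.0))


class TestFitSkewNormal:
    def test_symmetric_normal_gives_small_shape(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 0.5, size=100_000)
        fit = fit_skew_normal(x)
        assert abs(fit.shape) < 0.5
        assert fit.mean == pytest.approx(2.0, abs=0.02)

    def test_parameter_recovery(self):
        x = sstats.skewnorm.rvs(4.0, loc=1.0, scale=0.3, size=100_000,
                                random_state=7)
        fit = fit_skew_normal(x)
        assert fit.location == pytest.approx(1.0, abs=0.05)
        assert fit.scale == pytest.approx(0.3, rel=0.05)
        assert fit.shape == pytest.approx(4.0, rel=0.25)

    def test_constant_samples_raise(self):
        with pytest.raises(DegenerateInputError):
            fit_skew_normal(np.full(500, 1.3))


class TestDecisionThreshold:
    def test_equal_variance_normals_midpoint(self):
        pre = SkewNormalFit(location=0.0, scale=1.0, shape=0.0)
        post = SkewNormalFit(location=4.0, scale=1.0, shape=0.0)
        assert decision_threshold(pre, post) == pytest.approx(2.0, abs=1e-6)

    def test_unequal_variance_matches_quadratic_root(self):
        """log pdf equality of two normals is a quadratic in x."""
        m1, s1, m2, s2 = 0.0, 1.0, 3.0, 2.0
        pre = SkewNormalFit(location=m1, scale=s1, shape=0.0)
        post = SkewNormalFit(location=m2, scale=s2, shape=0.0)
        a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
        b = m1 / s1**2 - m2 / s2**2
        c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + math.log(s2 / s1)
        roots = np.roots([a, b, c])
        root = next(r for r in roots if m1 <= r <= m2)
        assert decision_threshold(pre, post) == pytest.approx(root, abs=1e-6)

    def test_identical_distributions_raise(self):
        f = SkewNormalFit(location=1.0, scale=0.5, shape=1.0)
        with pytest.raises(ValueError):
            decision_threshold(f, f)


class TestErrorRates:
    def test_gaussian_tails(self):
        pre = SkewNormalFit(location=0.0, scale=1.0, shape=0.0)
        post = SkewNormalFit(location=4.0, scale=1.0, shape=0.0)
        p_failed, p_false = error_rates(pre, post, 2.0)
        expected = 1.0 - sstats.norm.cdf(2.0)  # = 0.02275
        assert p_false == pytest.approx(expected, abs=1e-9)
        assert p_failed == pytest.approx(expected, abs=1e-9)

    def test_extreme_threshold_limits(self):
        pre = SkewNormalFit(location=0.0, scale=1.0, shape=1.0)
        post = SkewNormalFit(location=3.0, scale=1.0, shape=-1.0)
        p_failed, p_false = error_rates(pre, post, 100.0)
        assert p_false == pytest.approx(0.0, abs=1e-12)
        assert p_failed == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("shape_pre,shape_post", [(0.0, 0.0), (3.0, -2.0),
                                                      (-1.0, 4.0)])
    def test_matches_quadrature_oracle(self, shape_pre, shape_post):
        pre = SkewNormalFit(location=1.0, scale=0.4, shape=shape_pre)
        post = SkewNormalFit(location=2.5, scale=0.8, shape=shape_post)
        thr = decision_threshold(pre, post)
        p_failed, p_false = error_rates(pre, post, thr)
        q_failed, q_false = error_rates_quadrature(pre, post, thr)
        assert p_failed == pytest.approx(q_failed, abs=1e-6)
        assert p_false == pytest.approx(q_false, abs=1e-6)

    def test_post_shift_monotonicity(self):
        """Shifting the post distribution rightward (fixed threshold)
        weakly decreases P_failed; with the threshold re-derived it also
        decreases P_false."""
        pre = SkewNormalFit(location=1.0, scale=0.5, shape=1.5)
        failed_prev, false_prev = 1.1, 1.1
        for loc in (2.0, 2.5, 3.0, 3.5):
            post = SkewNormalFit(location=loc, scale=0.5, shape=0.0)
            thr = decision_threshold(pre, post)
            p_failed, p_false = error_rates(pre, post, thr)
            assert p_failed <= failed_prev + 1e-12
            assert p_false <= false_prev + 1e-12
            failed_prev, false_prev = p_failed, p_false


class TestSnr:
    def test_identical_distributions_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert compute_snr(x, x) == pytest.approx(0.0)

    def test_two_sigma_shift(self):
        rng = np.random.default_rng(0)
        pre = rng.normal(1.0, 0.5, 5000)
        post = pre + 2.0 * pre.std(ddof=1)
        assert compute_snr(pre, post) == pytest.approx(2.0, abs=1e-9)

    def test_known_moments(self):
        pre = np.array([0.0, 2.0])  # mean 1, sd sqrt(2)
        post = np.array([4.0, 6.0])  # mean 5
        assert compute_snr(pre, post) == pytest.approx(4.0 / math.sqrt(2.0))

    def test_zero_pre_sd_raises(self):
        with pytest.raises(DegenerateInputError):
            compute_snr(np.ones(10), np.arange(10.0))


class TestPairwiseCorrelation:
    def test_identical_trains(self):
        t = np.arange(10.0, 900.0, 37.0)
        sd = make_spikes([t, t, t])
        r, skipped = mean_pairwise_correlation(sd)
        assert r == pytest.approx(1.0)
        assert skipped == 0

    def test_independent_poisson_near_zero(self):
        sd = gen_poisson_population(30, 10.0, 60_000.0, seed=5)
        r, _ = mean_pairwise_correlation(sd)
        assert abs(r) < 0.005

    def test_antiphase_regular_trains_negative(self):
        a = np.arange(0.5, 1000.0, 2.0)   # odd ms bins
        b = np.arange(1.5, 1000.0, 2.0)   # even ms bins
        sd = make_spikes([a, b])
        r, _ = mean_pairwise_correlation(sd)
        assert r < -0.9

    def test_common_modulation_positive(self):
        sd = gen_poisson_population(20, 20.0, 30_000.0, seed=9,
                                    mod_freq_hz=10.0, mod_depth=0.8)
        r, _ = mean_pairwise_correlation(sd)
        assert r > 0.0

    def test_empty_trains_raise(self):
        sd = make_spikes([[], []])
        with pytest.raises(DegenerateInputError):
            mean_pairwise_correlation(sd)
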