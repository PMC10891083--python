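"""Dipole construction, four-sphere head model and Welch spectra."""

import numpy as np
import pytest

from micropam.circuit import SpikeData
from micropam.eeg import (
    BANDS,
    FourSphereModel,
    band_power,
    bootstrap_mean_ci,
    compute_dipole,
    foursphere_potential,
    foursphere_transfer,
    homogeneous_sphere_potential,
    spike_psd,
    welch_psd,
)
from micropam.synthetic import gen_poisson_population


class TestComputeDipole:
    def test_zero_currents(self):
        P = compute_dipole(np.zeros((100, 5)), 400.0)
        assert np.all(P == 0.0)

    def test_opposite_currents_cancel(self):
        ax = np.zeros((50, 2))
        ax[:, 0] = 3.0
        ax[:, 1] = -3.0
        assert np.allclose(compute_dipole(ax, 400.0), 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        ax = rng.normal(size=(40, 3))
        assert np.allclose(compute_dipole(2 * ax, 400.0),
                           2 * compute_dipole(ax, 400.0))


class TestFourSphere:
    def test_homogeneous_limit_matches_analytic(self):
        """All conductivities equal -> classic single-sphere dipole
        potential (within 1%; in practice machine precision)."""
        sigma = 0.3
        for theta in (0.0, 0.4, 1.2):
            m = FourSphereModel(sigmas=(sigma,) * 4, electrode_theta=theta,
                                n_max=3000)
            k = foursphere_transfer(m)
            ref = homogeneous_sphere_potential(sigma, 0.090, 0.078, theta)
            assert k == pytest.approx(ref, rel=0.01)

    def test_conductivity_scaling(self):
        m1 = FourSphereModel()
        m2 = FourSphereModel(sigmas=tuple(3.0 * s for s in m1.sigmas))
        assert foursphere_transfer(m2) == pytest.approx(
            foursphere_transfer(m1) / 3.0, rel=1e-9)

    def test_radial_beats_tangential_under_electrode(self):
        m = FourSphereModel(electrode_theta=0.15)
        v_rad = abs(foursphere_transfer(m, tangential=False))
        v_tan = abs(foursphere_transfer(m, tangential=True))
        assert v_rad > v_tan

    def test_potential_linear_in_dipole(self):
        P = np.array([1.0, -2.0, 0.5])
        v = foursphere_potential(P)
        assert np.allclose(foursphere_potential(5 * P), 5 * v)

    def test_dipole_outside_sphere_rejected(self):
        with pytest.raises(ValueError):
            FourSphereModel(dipole_r_mm=85.0)

    def test_radii_must_increase(self):
        with pytest.raises(ValueError):
            FourSphereModel(radii_mm=(80.0, 79.0, 85.0, 90.0))


class TestWelchPsd:
    def test_sine_parseval(self):
        """Unit sine: band-integrated power = 1/2 (Parseval, 2%)."""
        fs = 1000.0
        t = np.arange(0, 14.0, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        psd = welch_psd(x, fs)
        total = np.trapezoid(psd.power, psd.freqs)
        assert total == pytest.approx(0.5, rel=0.02)

    def test_white_noise_level(self):
        rng = np.random.default_rng(1)
        fs = 500.0
        v = 4.0
        x = rng.normal(0, np.sqrt(v), size=int(fs * 120))
        psd = welch_psd(x, fs)
        assert psd.power[5:-5].mean() == pytest.approx(v / (fs / 2), rel=0.05)

    def test_zero_signal(self):
        psd = welch_psd(np.zeros(8000), 1000.0)
        assert np.all(psd.power == 0.0)

    def test_segment_rule_fixes_resolution(self):
        for fs in (1000.0, 4000.0):
            psd = welch_psd(np.random.default_rng(0).normal(size=int(8 * fs)),
                            fs)
            df = psd.freqs[1] - psd.freqs[0]
            assert df == pytest.approx(1.0 / 3.5, rel=1e-6)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(1000), 1000.0)


class TestBandPower:
    def test_flat_psd_theta(self):
        psd = welch_psd(np.random.default_rng(2).normal(size=40000), 1000.0)
        psd.power[:] = 2.0
        assert band_power(psd, BANDS["theta"]) == pytest.approx(8.0, rel=1e-6)

    def test_sine_concentrates_in_alpha(self):
        fs = 1000.0
        t = np.arange(0, 30.0, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        psd = welch_psd(x, fs)
        alpha = band_power(psd, BANDS["alpha"])
        assert alpha > 100 * band_power(psd, BANDS["theta"])
        assert alpha > 100 * band_power(psd, BANDS["beta"])

    def test_additivity_of_independent_signals(self):
        rng = np.random.default_rng(3)
        fs = 500.0
        n = int(fs * 60)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        pa = band_power(welch_psd(x, fs), BANDS["alpha"])
        pb = band_power(welch_psd(y, fs), BANDS["alpha"])
        pc = band_power(welch_psd(x + y, fs), BANDS["alpha"])
        assert pc == pytest.approx(pa + pb, rel=0.15)

    def test_band_outside_range_raises(self):
        psd = welch_psd(np.zeros(8000), 1000.0)
        with pytest.raises(ValueError):
            band_power(psd, (400.0, 600.0))


class TestSpikePsd:
    def test_empty_trains_zero(self):
        sd = SpikeData(spike_times=[np.array([])] * 4,
                       types=np.full(4, "Pyr"), duration=8000.0, dt=0.1)
        psd = spike_psd(sd, fs=1000.0)
        assert np.all(psd.power == 0.0)

    def test_poisson_flat_floor(self):
        """Summed Poisson train has a flat high-frequency floor at the
        total rate level (counts/s)."""
        n, lam, dur, fs = 40, 4.0, 60_000.0, 1000.0
        sd = gen_poisson_population(n, lam, dur, seed=4)
        psd = spike_psd(sd, fs=fs)
        floor = psd.power[(psd.freqs > 100) & (psd.freqs < 400)].mean()
        # bin variance n*lam/fs spread flat over [0, fs/2]
        assert floor == pytest.approx(n * lam / fs / (fs / 2), rel=0.1)

    def test_common_modulation_creates_alpha_peak(self):
        sd = gen_poisson_population(60, 10.0, 30_000.0, seed=5,
                                    mod_freq_hz=10.0, mod_depth=0.8)
        psd = spike_psd(sd, fs=500.0)
        peak_band = band_power(psd, (9.0, 11.0)) / 2.0
        floor = band_power(psd, (30.0, 60.0)) / 30.0
        assert peak_band > 3 * floor


class TestBootstrapCi:
    def _fake_psds(self, powers):
        out = []
        for p in powers:
            psd = welch_psd(np.zeros(4000), 1000.0)
            psd.power = np.asarray(p, dtype=float)
            out.append(psd)
        return out

    def test_identical_psds_zero_width(self):
        n_f = welch_psd(np.zeros(4000), 1000.0).freqs.size
        psds = self._fake_psds([np.ones(n_f)] * 5)
        mean, lo, hi = bootstrap_mean_ci(psds, seed=0)
        assert np.allclose(mean, 1.0)
        assert np.allclose(hi - lo, 0.0)

    def test_seeded_reproducible(self):
        rng = np.random.default_rng(6)
        n_f = welch_psd(np.zeros(4000), 1000.0).freqs.size
        psds = self._fake_psds(rng.normal(10, 1, size=(6, n_f)))
        a = bootstrap_mean_ci(psds, seed=3)
        b = bootstrap_mean_ci(psds, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_coverage_of_true_mean(self):
        """Percentile CI covers the true per-frequency mean ~95% of the
        time over repetitions."""
        rng = np.random.default_rng(7)
        n_f = 50
        hits = 0
        trials = 200
        for k in range(trials):
            mat = rng.normal(5.0, 1.0, size=(15, n_f))
            psds = self._fake_psds(mat)
            _, lo, hi = bootstrap_mean_ci(psds, iterations=200, seed=k)
            hits += np.mean((lo <= 5.0) & (5.0 <= hi))
        coverage = hits / trials
        assert 0.85 < coverage <= 1.0
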