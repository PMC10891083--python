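"""Synthetic fixture generators for the analysis stages.

Each generator emulates the statistical structure one analysis stage
assumes — Poisson spike trains for windowed-rate and correlation metrics,
power-law spectra with injected Gaussian peaks for the spectral
parameterization, colored-noise traces with windowed sinusoidal bursts for
event detection, and piecewise-constant clamp traces for the current-fit
stage — so that every stage can be tested round-trip without running the
circuit simulator.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import SpikeData
from .specparam import Peak, aperiodic_model, periodic_model

__all__ = [
    "gen_poisson_population",
    "gen_powerlaw_psd",
    "gen_burst_timeseries",
    "gen_clamp_trace",
    "CLAMP_LEVELS",
]

#: experimental mean tonic currents (pA, PTX-referenced)
CLAMP_LEVELS = {"GABA": -65.9, "a5pam": -95.3, "PTX": 0.0}


def gen_poisson_population(n_neurons: int, rate_hz, duration_ms: float,
                           seed: int = 0, mod_freq_hz: float | None = None,
                           mod_depth: float = 0.0,
                           stimulus_onset: float | None = None) -> SpikeData:
    """Independent homogeneous Poisson spike trains.

    With ``mod_freq_hz`` set, all neurons share a sinusoidal rate
    modulation of relative ``mod_depth`` (inhomogeneous Poisson via
    thinning), which induces positive pairwise correlations and a spectral
    peak at the modulation frequency.
    """
    rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(rate_hz, dtype=float), (n_neurons,))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    spikes = []
    for i in range(n_neurons):
        lam = rates[i] * (1.0 + mod_depth)
        n_exp = rng.poisson(lam * duration_ms / 1000.0)
        t = np.sort(rng.uniform(0.0, duration_ms, size=n_exp))
        if mod_freq_hz is not None and mod_depth > 0 and t.size:
            accept = (1.0 + mod_depth * np.sin(2e-3 * np.pi * mod_freq_hz * t)) \
                / (1.0 + mod_depth)
            t = t[rng.random(t.size) < accept]
        spikes.append(t)
    return SpikeData(spike_times=spikes,
                     types=np.full(n_neurons, "Pyr"),
                     duration=duration_ms, dt=0.1,
                     stimulus_onset=stimulus_onset, condition="synthetic",
                     seed=seed)


def gen_powerlaw_psd(offset: float, exponent: float, peaks=(),
                     noise_sd: float = 0.0, freqs=None,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic PSD: 10^offset * f^-exponent with Gaussian peaks in log
    space and multiplicative log-normal noise (inverse model of
    :func:`micropam.specparam.fit_spectrum`).

    Returns (power, freqs)."""
    if freqs is None:
        freqs = np.arange(1.0, 45.0, 0.25)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    pk = [Peak(*p) if not isinstance(p, Peak) else p for p in peaks]
    log_p = aperiodic_model(freqs, offset, exponent) + periodic_model(freqs, pk)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        log_p = log_p + rng.normal(0.0, noise_sd, size=freqs.size)
    return 10.0 ** log_p, freqs


def _colored_noise(exponent: float, n: int, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power ~ f^-exponent via FFT spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def gen_burst_timeseries(background_chi: float, bursts, fs: float,
                         duration_s: float, seed: int = 0,
                         background_sd: float = 1.0) -> np.ndarray:
    """Colored-noise background plus Hann-windowed sinusoidal bursts.

    ``bursts`` is a list of (t_center_s, freq_hz, n_cycles, amplitude).
    Overlapping bursts are allowed (they superpose), which exercises the
    event-merging logic downstream.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    x = background_sd * _colored_noise(background_chi, n, fs, rng)
    t = np.arange(n) / fs
    for (tc, f0, cycles, amp) in bursts:
        if not 1.0 <= f0 <= 100.0:
            raise ValueError("burst frequency must lie in 1-100 Hz")
        half = cycles / f0 / 2.0
        if tc - half < 0 or tc + half > duration_s:
            raise ValueError("burst extends outside the signal")
        m = (t >= tc - half) & (t <= tc + half)
        phase = 2.0 * np.pi * f0 * (t[m] - tc)
        hann = 0.5 * (1.0 + np.cos(np.pi * (t[m] - tc) / half))
        x[m] += amp * hann * np.sin(phase)
    return x


def gen_clamp_trace(levels: dict | None = None, noise_sd: float = 5.0,
                    fs: float = 2000.0, segment_s: float = 2.0,
                    seed: int = 0) -> "pd.DataFrame":
    """Piecewise-constant clamp-current trace with Gaussian noise.

    Emulates the three-condition protocol (GABA, alpha5-PAM + GABA, PTX)
    as one continuous recording; per-condition mean extraction recovers
    the levels.  Returns a DataFrame (time_ms, current_pA, condition).
    """
    import pandas as pd

    levels = dict(CLAMP_LEVELS if levels is None else levels)
    rng = np.random.default_rng(seed)
    frames = []
    t0 = 0.0
    n = int(round(segment_s * fs))
    for cond, level in levels.items():
        t = t0 + np.arange(n) / fs * 1000.0
        i = level + rng.normal(0.0, noise_sd, size=n)
        frames.append(pd.DataFrame(
            {"time_ms": t, "current_pA": i, "condition": cond}))
        t0 = t[-1] + 1000.0 / fs
    return pd.concat(frames, ignore_index=True)


def extract_clamp_levels(trace) -> dict:
    """Per-condition mean currents, referenced to the PTX segment."""
    means = trace.groupby("condition")["current_pA"].mean()
    ref = means.get("PTX", 0.0)
    return {cond: float(m - ref) for cond, m in means.items()}
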