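"""Signal-detection analysis of stimulus processing.

The stimulus-processing metrics treat the pyramidal population rate as the
decision variable of an ideal observer:

* pre-stimulus rate samples — 50 ms window sliding in 1 ms steps over a
  3 s pre-stimulus period (2951 windows per circuit);
* post-stimulus rate — one 50 ms window 5-55 ms after stimulus onset per
  circuit, pooled across randomized circuits;
* both sets are fitted with skew-normal distributions, the decision
  threshold is the pdf intersection between the two modes (optimal decision
  theory for equal priors), and the failed / false detection probabilities
  are the post-distribution mass below and the pre-distribution mass above
  the threshold.

SNR is defined here as (mean_post - mean_pre) / SD_pre of the window-rate
samples (a documented package definition; the source experiments report SNR
without printing a formula).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .circuit import SpikeData

__all__ = [
    "RateWindows",
    "SkewNormalFit",
    "DetectionResult",
    "window_rates",
    "post_stimulus_rate",
    "fit_skew_normal",
    "decision_threshold",
    "error_rates",
    "compute_snr",
    "mean_pairwise_correlation",
    "detection_analysis",
]

WINDOW_MS = 50.0
STEP_MS = 1.0
PRE_PERIOD_MS = 3000.0
POST_WINDOW_MS = (5.0, 55.0)


class DegenerateInputError(ValueError):
    """Input distribution has no usable spread."""


@dataclass
class RateWindows:
    """Sliding-window population rate samples (Hz per neuron)."""

    rates: np.ndarray
    window_ms: float = WINDOW_MS
    step_ms: float = STEP_MS
    interval: tuple[float, float] = (0.0, PRE_PERIOD_MS)

    @property
    def n_windows(self) -> int:
        return self.rates.size


def window_rates(spikes: SpikeData, interval: tuple[float, float],
                 window_ms: float = WINDOW_MS, step_ms: float = STEP_MS,
                 population: str = "Pyr") -> RateWindows:
    """Sliding-window population rate over ``interval``.

    Each sample is the total spike count of the population inside the
    window divided by (window length x population size), in Hz.
    """
    lo, hi = interval
    if hi - lo < window_ms:
        raise ValueError("interval shorter than the window length")
    idx = np.flatnonzero(spikes.types == population)
    if idx.size == 0:
        raise ValueError(f"no neurons of type {population!r}")
    all_times = np.concatenate([spikes.spike_times[i] for i in idx]) \
        if idx.size else np.array([])
    all_times = all_times[(all_times >= lo) & (all_times < hi)]
    # 1 ms binning then moving sum over window_ms bins
    n_bins = int(round((hi - lo) / step_ms))
    counts, _ = np.histogram(all_times, bins=n_bins, range=(lo, hi))
    w = int(round(window_ms / step_ms))
    csum = np.concatenate([[0], np.cumsum(counts)])
    win_counts = csum[w:] - csum[:-w]
    rates = win_counts / (window_ms / 1000.0) / idx.size
    return RateWindows(rates=rates, window_ms=window_ms, step_ms=step_ms,
                       interval=(lo, hi))


def post_stimulus_rate(spikes: SpikeData, population: str = "Pyr") -> float:
    """Population rate (Hz/neuron) in the 5-55 ms post-stimulus window."""
    if spikes.stimulus_onset is None:
        raise ValueError("spike data has no stimulus onset")
    t0 = spikes.stimulus_onset
    lo, hi = t0 + POST_WINDOW_MS[0], t0 + POST_WINDOW_MS[1]
    idx = np.flatnonzero(spikes.types == population)
    count = sum(int(np.count_nonzero((spikes.spike_times[i] >= lo)
                                     & (spikes.spike_times[i] < hi)))
                for i in idx)
    return count / idx.size / ((hi - lo) / 1000.0)


@dataclass
class SkewNormalFit:
    """Skew-normal distribution parameters (scipy convention)."""

    location: float
    scale: float
    shape: float
    loglik: float = np.nan

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def frozen(self):
        return stats.skewnorm(self.shape, loc=self.location, scale=self.scale)

    def pdf(self, x):
        return self.frozen.pdf(x)

    def cdf(self, x):
        return self.frozen.cdf(x)

    @property
    def mean(self) -> float:
        return float(self.frozen.mean())

    @property
    def mode(self) -> float:
        """Numerically located mode of the density."""
        lo, hi = self.frozen.ppf([0.001, 0.999])
        grid = np.linspace(lo, hi, 512)
        x0 = grid[np.argmax(self.pdf(grid))]
        res = optimize.minimize_scalar(
            lambda x: -self.pdf(x),
            bounds=(max(lo, x0 - self.scale), min(hi, x0 + self.scale)),
            method="bounded")
        return float(res.x)


def fit_skew_normal(samples, min_samples: int = 100) -> SkewNormalFit:
    """Maximum-likelihood skew-normal fit of rate samples."""
    x = np.asarray(samples, dtype=float)
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {x.size}")
    if np.std(x) < 1e-12:
        raise DegenerateInputError("zero-variance samples cannot be fitted")
    a, loc, scale = stats.skewnorm.fit(x)
    ll = float(np.sum(stats.skewnorm.logpdf(x, a, loc=loc, scale=scale)))
    if not np.isfinite(ll):
        # fall back to a moment-matched start and refit
        a, loc, scale = stats.skewnorm.fit(x, 0.0, loc=np.mean(x),
                                           scale=np.std(x))
        ll = float(np.sum(stats.skewnorm.logpdf(x, a, loc=loc, scale=scale)))
    return SkewNormalFit(location=float(loc), scale=float(scale),
                         shape=float(a), loglik=ll)


def decision_threshold(pre: SkewNormalFit, post: SkewNormalFit) -> float:
    """Intersection of the two fitted densities between their modes.

    Requires the post-stimulus distribution to sit above the pre-stimulus
    one.  If the pdf difference changes sign more than once between the
    modes, the root closest to the midpoint of the candidates is used.
    """
    if post.mean <= pre.mean:
        raise ValueError("post-stimulus mean must exceed pre-stimulus mean")
    m_pre, m_post = pre.mode, post.mode
    if m_post <= m_pre:
        m_pre, m_post = sorted([pre.mean, post.mean])
    grid = np.linspace(m_pre, m_post, 2048)
    diff = pre.pdf(grid) - post.pdf(grid)
    sign = np.sign(diff)
    crossings = np.flatnonzero(np.diff(sign) != 0)
    if crossings.size == 0:
        raise ValueError("no pdf intersection between the distribution modes")
    roots = []
    for i in crossings:
        roots.append(optimize.brentq(lambda x: pre.pdf(x) - post.pdf(x),
                                     grid[i], grid[i + 1], xtol=1e-12))
    if len(roots) == 1:
        return float(roots[0])
    mid = 0.5 * (m_pre + m_post)
    return float(min(roots, key=lambda r: abs(r - mid)))


def error_rates(pre: SkewNormalFit, post: SkewNormalFit,
                threshold: float) -> tuple[float, float]:
    """(P_failed, P_false) at the given threshold.

    P_false is the pre-stimulus probability mass above the threshold
    (normalized by the whole distribution, which integrates to one);
    P_failed is the post-stimulus mass below it.
    """
    p_false = float(1.0 - pre.cdf(threshold))
    p_failed = float(post.cdf(threshold))
    return p_failed, p_false


def error_rates_quadrature(pre: SkewNormalFit, post: SkewNormalFit,
                           threshold: float) -> tuple[float, float]:
    """Brute-force numerical-integration oracle for :func:`error_rates`."""
    lo_pre, hi_pre = pre.frozen.ppf([1e-12, 1 - 1e-12])
    lo_post, hi_post = post.frozen.ppf([1e-12, 1 - 1e-12])
    above, _ = integrate.quad(pre.pdf, threshold, hi_pre, limit=200)
    total_pre, _ = integrate.quad(pre.pdf, lo_pre, hi_pre, limit=200)
    below, _ = integrate.quad(post.pdf, lo_post, threshold, limit=200)
    total_post, _ = integrate.quad(post.pdf, lo_post, hi_post, limit=200)
    return below / total_post, above / total_pre


def compute_snr(pre_samples, post_samples) -> float:
    """(mean_post - mean_pre) / SD_pre of window-rate samples."""
    pre = np.asarray(pre_samples, dtype=float)
    post = np.asarray(post_samples, dtype=float)
    sd = pre.std(ddof=1)
    if sd <= 0:
        raise DegenerateInputError("pre-stimulus SD is zero")
    return float((post.mean() - pre.mean()) / sd)


def mean_pairwise_correlation(spikes: SpikeData, bin_ms: float = 1.0,
                              population: str = "Pyr",
                              interval: tuple[float, float] | None = None,
                              ) -> tuple[float, int]:
    """Mean Pearson correlation of binary (0/1) binned spike trains.

    Returns (mean r over valid unordered pairs, number of skipped pairs
    with a zero-variance train)."""
    if interval is None:
        interval = (0.0, spikes.duration)
    lo, hi = interval
    idx = np.flatnonzero(spikes.types == population)
    if idx.size < 2:
        raise ValueError("need at least two neurons")
    n_bins = int(round((hi - lo) / bin_ms))
    trains = np.zeros((idx.size, n_bins), dtype=float)
    for row, i in enumerate(idx):
        t = spikes.spike_times[i]
        t = t[(t >= lo) & (t < hi)]
        counts, _ = np.histogram(t, bins=n_bins, range=(lo, hi))
        trains[row] = np.minimum(counts, 1)
    var = trains.var(axis=1)
    valid = var > 0
    if not np.any(valid):
        raise DegenerateInputError("all spike trains are empty")
    n_valid = int(np.count_nonzero(valid))
    n_total_pairs = idx.size * (idx.size - 1) // 2
    n_valid_pairs = n_valid * (n_valid - 1) // 2
    if n_valid_pairs == 0:
        raise DegenerateInputError("fewer than two non-empty spike trains")
    corr = np.corrcoef(trains[valid])
    iu = np.triu_indices(n_valid, k=1)
    return float(np.mean(corr[iu])), n_total_pairs - n_valid_pairs


@dataclass
class DetectionResult:
    """Per-circuit detection metrics against the pooled post distribution."""

    threshold: float
    p_failed: float
    p_false: float
    snr: float
    pre_fit: SkewNormalFit | None = None
    post_fit: SkewNormalFit | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_failed <= 1.0 and 0.0 <= self.p_false <= 1.0):
            raise ValueError("detection probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "p_failed": self.p_failed,
                "p_false": self.p_false, "snr": self.snr}


def detection_analysis(spike_datasets: list,
                       population: str = "Pyr",
                       min_post_fit: int = 20) -> list:
    """Full detection pipeline over randomized circuits of one condition.

    Fits the pre-stimulus distribution per circuit (2951 windows each at
    the default 3 s period), the post-stimulus distribution across circuits
    (one 5-55 ms window per circuit), then derives a per-circuit threshold,
    failed/false probabilities and SNR.  With fewer than ``min_post_fit``
    circuits the post distribution falls back to a symmetric (normal) fit,
    since a skewness parameter is not identifiable from a handful of
    samples.
    """
    pre_windows = []
    post_rates = []
    for sd in spike_datasets:
        onset = sd.stimulus_onset
        if onset is None:
            raise ValueError("spike data lacks a stimulus onset")
        rw = window_rates(sd, (onset - PRE_PERIOD_MS, onset),
                          population=population)
        pre_windows.append(rw.rates)
        post_rates.append(post_stimulus_rate(sd, population))
    post_rates = np.asarray(post_rates)
    if len(post_rates) >= min_post_fit:
        post_fit = fit_skew_normal(post_rates, min_samples=min_post_fit)
    else:
        mu, sdv = float(np.mean(post_rates)), float(np.std(post_rates, ddof=1))
        post_fit = SkewNormalFit(location=mu, scale=sdv, shape=0.0)
    results = []
    for rates, post_r in zip(pre_windows, post_rates):
        pre_fit = fit_skew_normal(rates)
        thr = decision_threshold(pre_fit, post_fit)
        p_failed, p_false = error_rates(pre_fit, post_fit, thr)
        snr = compute_snr(rates, np.atleast_1d(post_r))
        results.append(DetectionResult(threshold=thr, p_failed=p_failed,
                                       p_false=p_false, snr=snr,
                                       pre_fit=pre_fit, post_fit=post_fit))
    return results
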