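"""Aperiodic/periodic decomposition of power spectra.

Decomposes a PSD (by default over 3-30 Hz) into a 1/f aperiodic component,
parameterized by a vertical offset and exponent chi in log10-power space
(log10 P = offset - chi * log10 f), plus up to three Gaussian oscillatory
peaks fitted to the residual in log space.  The algorithm follows the
standard iterative parameterization approach:

1. robust aperiodic fit (peaks down-weighted through residual masking);
2. iterative peak extraction on the flattened spectrum — the largest
   residual maximum is accepted while it exceeds the relative threshold
   (2 x SD of the residual) and the minimum height (0), its Gaussian
   standard deviation is seeded from the half-height width and bounded so
   the bandwidth (2 x sd) stays within [2, 6] Hz;
3. joint Gaussian refinement of all accepted peaks;
4. aperiodic re-fit on the peak-subtracted spectrum.

Candidate peaks closer than one bandwidth are merged (the larger survives)
before refinement; peaks are reported ordered by height, largest first.
Periodic band powers integrate the fitted Gaussians in log-residual space
(the package convention, stated in the docs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

__all__ = [
    "SpectralFit",
    "Peak",
    "fit_spectrum",
    "aperiodic_auc",
    "periodic_band_power",
    "aperiodic_model",
    "periodic_model",
]

FIT_RANGE = (3.0, 30.0)
MAX_PEAKS = 3
BW_LIMITS = (2.0, 6.0)           # Hz, full bandwidth = 2 * gaussian sd
PEAK_THRESHOLD_SD = 2.0          # relative peak threshold
MIN_PEAK_HEIGHT = 0.0            # log10 units


@dataclass
class Peak:
    """One oscillatory peak: center frequency (Hz), height (log10-power
    units above the aperiodic component) and bandwidth (Hz, = 2 sd)."""

    cf: float
    height: float
    bw: float

    @property
    def sd(self) -> float:
        return self.bw / 2.0


@dataclass
class SpectralFit:
    """Aperiodic offset/exponent plus up to three Gaussian peaks."""

    offset: float
    exponent: float
    peaks: list = field(default_factory=list)
    fit_range: tuple = FIT_RANGE
    r_squared: float = np.nan
    error_rms: float = np.nan

    def __post_init__(self) -> None:
        if len(self.peaks) > MAX_PEAKS:
            raise ValueError(f"at most {MAX_PEAKS} peaks allowed")

    def aperiodic(self, freqs) -> np.ndarray:
        """Aperiodic component in log10-power."""
        return aperiodic_model(np.asarray(freqs, dtype=float),
                               self.offset, self.exponent)

    def periodic(self, freqs) -> np.ndarray:
        """Summed Gaussian peaks in log10-power units."""
        return periodic_model(np.asarray(freqs, dtype=float), self.peaks)

    def model(self, freqs) -> np.ndarray:
        return self.aperiodic(freqs) + self.periodic(freqs)


def aperiodic_model(freqs, offset, exponent):
    return offset - exponent * np.log10(freqs)


def periodic_model(freqs, peaks):
    freqs = np.asarray(freqs, dtype=float)
    out = np.zeros_like(freqs)
    for pk in peaks:
        out += pk.height * np.exp(-((freqs - pk.cf) ** 2) / (2 * pk.sd ** 2))
    return out


def _fit_aperiodic(freqs, log_power) -> tuple[float, float]:
    """Robust offset/exponent fit: plain least squares, then a second pass
    restricted to points whose positive residual is below the median
    positive residual (masking oscillatory peaks)."""
    logf = np.log10(freqs)
    A = np.vstack([np.ones_like(logf), -logf]).T
    coef, *_ = np.linalg.lstsq(A, log_power, rcond=None)
    resid = log_power - A @ coef
    pos = np.clip(resid, 0.0, None)
    thresh = np.percentile(pos, 60.0)
    mask = pos <= thresh
    if np.count_nonzero(mask) >= 5:
        coef, *_ = np.linalg.lstsq(A[mask], log_power[mask], rcond=None)
    return float(coef[0]), float(coef[1])


def _guess_sd(freqs, resid, i_peak) -> float:
    """Gaussian sd estimate from the half-height width around a maximum."""
    half = resid[i_peak] / 2.0
    i_lo = i_peak
    while i_lo > 0 and resid[i_lo] > half:
        i_lo -= 1
    i_hi = i_peak
    while i_hi < resid.size - 1 and resid[i_hi] > half:
        i_hi += 1
    fwhm = freqs[i_hi] - freqs[i_lo]
    sd = fwhm / 2.355 if fwhm > 0 else BW_LIMITS[0] / 2.0
    return float(np.clip(sd, BW_LIMITS[0] / 2.0, BW_LIMITS[1] / 2.0))


def fit_spectrum(power, freqs, fit_range: tuple[float, float] = FIT_RANGE,
                 max_peaks: int = MAX_PEAKS,
                 peak_threshold_sd: float = PEAK_THRESHOLD_SD,
                 min_peak_height: float = MIN_PEAK_HEIGHT) -> SpectralFit:
    """Parameterize a PSD into aperiodic + periodic components.

    ``power`` and ``freqs`` are linear-space PSD values and their
    frequencies; the fit is performed in log10-power space over
    ``fit_range``.  Deterministic.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    f = freqs[mask]
    p = power[mask]
    if f.size < 20:
        raise ValueError("need at least 20 frequency points in the fit range")
    if np.any(p <= 0):
        raise ValueError("power must be positive inside the fit range")
    logp = np.log10(p)

    offset, exponent = _fit_aperiodic(f, logp)
    resid = logp - aperiodic_model(f, offset, exponent)

    # --- iterative peak extraction ---
    guesses: list[Peak] = []
    work = resid.copy()
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        height = work[i]
        if height < peak_threshold_sd * np.std(work) or height <= min_peak_height:
            break
        sd = _guess_sd(f, work, i)
        pk = Peak(cf=float(f[i]), height=float(height), bw=2.0 * sd)
        guesses.append(pk)
        work = work - pk.height * np.exp(-((f - pk.cf) ** 2) / (2 * pk.sd ** 2))

    # merge overlapping candidates (closer than one bandwidth): keep larger
    guesses.sort(key=lambda pk: -pk.height)
    merged: list[Peak] = []
    for pk in guesses:
        if all(abs(pk.cf - q.cf) > max(pk.bw, q.bw) for q in merged):
            merged.append(pk)

    peaks: list[Peak] = []
    if merged:
        def multi_gauss(x, *params):
            y = np.zeros_like(x)
            for j in range(0, len(params), 3):
                cf, h, sd = params[j:j + 3]
                y = y + h * np.exp(-((x - cf) ** 2) / (2 * sd ** 2))
            return y

        p0, lo, hi = [], [], []
        for pk in merged:
            p0 += [pk.cf, pk.height, pk.sd]
            lo += [fit_range[0], 0.0, BW_LIMITS[0] / 2.0]
            hi += [fit_range[1], np.inf, BW_LIMITS[1] / 2.0]
        try:
            popt, _ = curve_fit(multi_gauss, f, resid, p0=p0,
                                bounds=(lo, hi), maxfev=5000)
            peaks = [Peak(cf=float(popt[j]), height=float(popt[j + 1]),
                          bw=2.0 * float(popt[j + 2]))
                     for j in range(0, len(popt), 3)]
        except RuntimeError:
            peaks = merged
        peaks = [pk for pk in peaks if pk.height > min_peak_height]
        peaks.sort(key=lambda pk: -pk.height)
        peaks = peaks[:max_peaks]

    # --- aperiodic re-fit on the peak-subtracted spectrum ---
    flat = logp - periodic_model(f, peaks)
    logf = np.log10(f)
    A = np.vstack([np.ones_like(logf), -logf]).T
    coef, *_ = np.linalg.lstsq(A, flat, rcond=None)
    offset, exponent = float(coef[0]), float(coef[1])

    fit = SpectralFit(offset=offset, exponent=exponent, peaks=peaks,
                      fit_range=tuple(fit_range))
    model = fit.model(f)
    ss_res = float(np.sum((logp - model) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    fit.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit.error_rms = float(np.sqrt(ss_res / f.size))
    return fit


def aperiodic_auc(fit: SpectralFit,
                  band: tuple[float, float] | None = None) -> float:
    """Integral of the linear-space aperiodic model over ``band``
    (default: the fit range).  Closed form of int 10^offset f^-chi df."""
    lo, hi = band if band is not None else fit.fit_range
    o, chi = fit.offset, fit.exponent
    if abs(chi - 1.0) < 1e-12:
        return float(10.0 ** o * np.log(hi / lo))
    return float(10.0 ** o * (hi ** (1.0 - chi) - lo ** (1.0 - chi))
                 / (1.0 - chi))


def periodic_band_power(fit: SpectralFit, band: tuple[float, float]) -> float:
    """Integral of the summed Gaussian peaks over ``band`` in log-residual
    units (analytic, via the error function)."""
    lo, hi = band
    total = 0.0
    for pk in fit.peaks:
        s = pk.sd * np.sqrt(2.0)
        total += pk.height * pk.sd * np.sqrt(2.0 * np.pi) * 0.5 * (
            erf((hi - pk.cf) / s) - erf((lo - pk.cf) / s))
    return float(total)
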