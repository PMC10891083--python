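"""EEG forward model and power spectra.

A single equivalent current dipole summarizes the microcircuit: every
pyramidal neuron's somato-apical axial current, multiplied by the
compartment separation along the cortical depth axis, is summed into one
dipole moment time series P(t).  The scalp potential follows from the
quasi-static four-sphere volume conductor (grey matter, CSF, skull, scalp;
radii 79/80/85/90 mm, conductivities 0.047/1.71/0.02/0.41 S/m), with the
dipole placed radially just beneath the grey-matter surface and the
electrode at the scalp apex directly above it.

The concentric-sphere solution is built from first principles: the source
potential of the dipole in an unbounded medium is expanded in (associated)
Legendre harmonics, and for every degree n a small linear system enforces
continuity of potential and radial current density at the three interfaces
plus the insulating outer boundary.  The expansion is truncated once terms
fall below a relative tolerance.

Power spectra use Welch's method with Hann tapers, 50% overlap and a
segment length fixed at 3.5 s x fs, so the spectral resolution
(~0.286 Hz) is independent of the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.special import eval_legendre, lpmv

from .circuit import SpikeData

__all__ = [
    "FourSphereModel",
    "PsdResult",
    "BANDS",
    "compute_dipole",
    "foursphere_transfer",
    "foursphere_potential",
    "homogeneous_sphere_potential",
    "welch_psd",
    "band_power",
    "spike_psd",
    "bootstrap_mean_ci",
]

#: analysis bands (Hz): theta, alpha, lower beta
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 21.0)}

SEGMENT_SECONDS = 3.5


@dataclass(frozen=True)
class FourSphereModel:
    """Concentric-sphere head model.

    Radii in mm (strictly increasing: grey matter, CSF, skull, scalp) and
    conductivities in S/m.  ``dipole_r_mm`` is the radial dipole depth
    (inside the innermost sphere); ``electrode_theta`` the polar angle of
    the scalp electrode relative to the dipole axis (0 = directly above).
    """

    radii_mm: tuple = (79.0, 80.0, 85.0, 90.0)
    sigmas: tuple = (0.047, 1.71, 0.02, 0.41)
    dipole_r_mm: float = 78.0
    electrode_theta: float = 0.0
    n_max: int = 400
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.radii_mm, self.radii_mm[1:])):
            raise ValueError("radii must be strictly increasing")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("conductivities must be positive")
        if not 0 < self.dipole_r_mm < self.radii_mm[0]:
            raise ValueError("dipole must sit inside the innermost sphere")


def compute_dipole(axial_pA: np.ndarray, separation_um: float) -> np.ndarray:
    """Dipole moment time series from per-Pyr axial currents.

    ``axial_pA`` has shape (n_steps, n_pyr) in pA; ``separation_um`` is the
    somatic-to-apical compartment separation along the depth axis.  Returns
    P(t) in nA*um (1 nA*um = 1e-15 A*m), oriented apical-above-soma.
    """
    axial = np.asarray(axial_pA, dtype=float)
    if axial.ndim != 2:
        raise ValueError("axial currents must be (n_steps, n_neurons)")
    return axial.sum(axis=1) * 1e-3 * separation_um  # pA -> nA


def _layer_of(r: float, radii) -> int:
    for j, R in enumerate(radii):
        if r <= R:
            return j
    raise ValueError("radius outside the outermost sphere")


@lru_cache(maxsize=64)
def _transfer_coefficients(model: FourSphereModel, tangential: bool):
    """Per-degree scaled expansion coefficients of the scalp-surface
    potential.

    Returns (n values, coefficients c_n) such that the potential at the
    outer surface is  sum_n c_n * f_n(cos theta) * p / (4 pi sigma1 b^2),
    with f_n = P_n for a radial dipole and P_n^1 for a tangential one.
    """
    radii = np.asarray(model.radii_mm, dtype=float) * 1e-3  # m
    sig = np.asarray(model.sigmas, dtype=float)
    b = model.dipole_r_mm * 1e-3
    R4 = radii[-1]
    ns, coefs = [], []
    prev_max = 0.0
    for n in range(1, model.n_max + 1):
        # infinite-medium source expansion, scaled so that
        # phi_src = [p / (4 pi sigma1 b^2)] * s_n * (b/r)^(n+1) * f_n(cos th)
        # radial dipole:     f_n = P_n,   s_n = n
        # tangential dipole: f_n = P_n^1, s_n = -1 (Condon-Shortley P_n^1)
        s_n = -1.0 if tangential else float(n)
        # unknowns: A1, A2, B2, A3, B3, A4, B4 where
        # phi_j(r) = A_j (r/R4)^n + B_j (b/r)^(n+1)  [+ s_n (b/r)^(n+1) in j=1]
        M = np.zeros((7, 7))
        rhs = np.zeros(7)

        def pow_up(r):
            return (r / R4) ** n

        def pow_dn(r):
            return (b / r) ** (n + 1)

        def dpow_up(r):
            return n * (r / R4) ** (n - 1) / R4

        def dpow_dn(r):
            return -(n + 1) * b ** (n + 1) / r ** (n + 2)

        cols = {"A1": 0, "A2": 1, "B2": 2, "A3": 3, "B3": 4, "A4": 5, "B4": 6}
        row = 0
        for j, R in enumerate(radii[:-1]):  # interfaces at R1..R3
            Aj = cols[f"A{j + 1}"]
            Ak = cols[f"A{j + 2}"]
            Bk = cols[f"B{j + 2}"]
            # potential continuity
            M[row, Aj] += pow_up(R)
            if j > 0:
                M[row, cols[f"B{j + 1}"]] += pow_dn(R)
            M[row, Ak] -= pow_up(R)
            M[row, Bk] -= pow_dn(R)
            if j == 0:
                rhs[row] = -s_n * pow_dn(R)
            row += 1
            # radial current continuity: sigma_j dphi_j = sigma_{j+1} dphi_{j+1}
            M[row, Aj] += sig[j] * dpow_up(R)
            if j > 0:
                M[row, cols[f"B{j + 1}"]] += sig[j] * dpow_dn(R)
            M[row, Ak] -= sig[j + 1] * dpow_up(R)
            M[row, Bk] -= sig[j + 1] * dpow_dn(R)
            if j == 0:
                rhs[row] = -sig[0] * s_n * dpow_dn(R)
            row += 1
        # insulating outer boundary
        M[row, cols["A4"]] = dpow_up(R4)
        M[row, cols["B4"]] = dpow_dn(R4)
        sol = np.linalg.solve(M, rhs)
        c_n = sol[cols["A4"]] * pow_up(R4) + sol[cols["B4"]] * pow_dn(R4)
        ns.append(n)
        coefs.append(c_n)
        prev_max = max(prev_max, abs(c_n))
        if n > 10 and abs(c_n) < model.tol * prev_max:
            break
    else:
        if abs(coefs[-1]) > 1e-6 * prev_max:
            raise RuntimeError(
                f"multipole expansion not converged after {model.n_max} terms")
    return np.asarray(ns), np.asarray(coefs)


def foursphere_transfer(model: FourSphereModel,
                        tangential: bool = False) -> float:
    """Scalp potential (volts) per unit dipole moment (A*m).

    Radial dipole by default; with ``tangential=True`` the dipole is
    tangential and the associated-Legendre (m=1) harmonics are used.
    """
    ns, coefs = _transfer_coefficients(model, tangential)
    b = model.dipole_r_mm * 1e-3
    ct = np.cos(model.electrode_theta)
    if tangential:
        basis = lpmv(1, ns, ct)
    else:
        basis = eval_legendre(ns, ct)
    sigma1 = model.sigmas[0]
    return float(np.sum(coefs * basis) / (4.0 * np.pi * sigma1 * b ** 2))


def homogeneous_sphere_potential(sigma: float, R_m: float, b_m: float,
                                 theta: float, p_Am: float = 1.0,
                                 n_max: int = 2000) -> float:
    """Analytic surface potential of a radial dipole in a homogeneous
    conducting sphere with insulating exterior (independent oracle).

    phi(R, theta) = p / (4 pi sigma R^2) * sum_n (2n+1) (b/R)^(n-1) P_n.
    """
    ns = np.arange(1, n_max + 1)
    terms = (2 * ns + 1) * (b_m / R_m) ** (ns - 1) * eval_legendre(ns, np.cos(theta))
    return float(p_Am / (4.0 * np.pi * sigma * R_m ** 2) * np.sum(terms))


def foursphere_potential(P_nAum, model: FourSphereModel | None = None,
                         ) -> np.ndarray:
    """EEG trace (mV) at the electrode for dipole moment series P (nA*um).

    The transfer is linear in P, so the whole series is scaled by a single
    precomputed factor (radial dipole under the apex electrode).
    """
    model = model or FourSphereModel()
    k = foursphere_transfer(model)  # V per A*m
    P = np.asarray(P_nAum, dtype=float) * 1e-15  # nA*um -> A*m
    return P * k * 1e3  # V -> mV


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class PsdResult:
    """One-sided power spectral density."""

    freqs: np.ndarray        # Hz
    power: np.ndarray        # signal_units^2 / Hz
    nperseg: int
    fs: float

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power density must be non-negative")


def welch_psd(x, fs: float, segment_seconds: float = SEGMENT_SECONDS,
              ) -> PsdResult:
    """Welch PSD with Hann taper, 50% overlap and 3.5 s segments."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_seconds * fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal ({x.size} samples) shorter than one segment ({nperseg})")
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")
    return PsdResult(freqs=f, power=p, nperseg=nperseg, fs=fs)


def band_power(psd: PsdResult, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi] (signal units^2)."""
    lo, hi = band
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError(f"band {band} outside the PSD frequency range")
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    f = psd.freqs[mask]
    p = psd.power[mask]
    # include exact band edges by interpolation
    if f[0] > lo:
        f = np.concatenate([[lo], f])
        p = np.concatenate([[np.interp(lo, psd.freqs, psd.power)], p])
    if f[-1] < hi:
        f = np.concatenate([f, [hi]])
        p = np.concatenate([p, [np.interp(hi, psd.freqs, psd.power)]])
    return float(np.trapezoid(p, f))


def spike_psd(spikes: SpikeData, fs: float = 1000.0,
              population: str = "Pyr",
              segment_seconds: float = SEGMENT_SECONDS) -> PsdResult:
    """Welch PSD of the population-summed binary spike train.

    Spike times are binned at 1/fs into 0/1 vectors per neuron, summed
    across the population, and passed to the same Welch estimator as the
    EEG (3.5 s segments)."""
    idx = np.flatnonzero(spikes.types == population)
    if idx.size == 0:
        raise ValueError(f"empty population {population!r}")
    n_bins = int(round(spikes.duration / 1000.0 * fs))
    summed = np.zeros(n_bins)
    for i in idx:
        t = spikes.spike_times[i]
        counts, _ = np.histogram(t, bins=n_bins, range=(0.0, spikes.duration))
        summed += np.minimum(counts, 1)
    return welch_psd(summed, fs, segment_seconds)


def bootstrap_mean_ci(psds: list, iterations: int = 100, level: float = 95.0,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile-bootstrap mean and CI of per-seed PSDs, per frequency.

    Returns (mean, ci_low, ci_high) arrays on the common frequency grid.
    """
    if len(psds) < 2:
        raise ValueError("need at least two PSDs")
    mat = np.vstack([p.power for p in psds])
    rng = np.random.default_rng(seed)
    n = mat.shape[0]
    boot = np.empty((iterations, mat.shape[1]))
    for it in range(iterations):
        pick = rng.integers(0, n, size=n)
        boot[it] = mat[pick].mean(axis=0)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(boot, [alpha, 100.0 - alpha], axis=0)
    return mat.mean(axis=0), lo, hi
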