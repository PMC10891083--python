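"""Effect sizes, tests, dose-response fits and the condition-sweep runner.

Cohen's d uses the pooled-SD formula

    d = (x_bar - y_bar) / sqrt(((Nx-1) sx^2 + (Ny-1) sy^2) / (Nx+Ny-2))

applied to independent-group summaries (the convention of the source
analyses, which pair it with paired-sample t-tests).  The sign convention
(first minus second group) is stated per call site.

``run_condition_sweep`` orchestrates the reduced-model experiments: for a
grid of conditions (healthy, depression, depression + alpha5-PAM doses,
depression + non-selective PAM) and paired random seeds it builds the
circuit, applies the condition, simulates, and collects firing-rate,
detection and (optionally) EEG/spectral metrics into a tidy table.
Within one seed index the circuit structure and background noise seeds are
shared across conditions, so condition contrasts are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from . import detection as det
from . import eeg as eegmod
from . import specparam as spmod
from .circuit import CircuitConfig, basal_stimulus, build_circuit, \
    attach_stimulus, simulate
from .interventions import apply_condition

__all__ = [
    "GroupSummary",
    "DoseResponse",
    "cohens_d",
    "cohens_d_samples",
    "paired_t",
    "fit_dose_response",
    "run_condition_sweep",
    "sweep_eeg",
    "summarize_sweep",
]


@dataclass
class GroupSummary:
    """Two-group summary statistics for effect-size computation."""

    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("group sizes must be at least 2")
        if self.sd_x < 0 or self.sd_y < 0:
            raise ValueError("group SDs must be non-negative")


def cohens_d(summary: GroupSummary) -> float:
    """Pooled-SD Cohen's d, sign = (x - y).

    A zero pooled SD with unequal means returns signed infinity."""
    s = summary
    pooled = np.sqrt(((s.n_x - 1) * s.sd_x ** 2 + (s.n_y - 1) * s.sd_y ** 2)
                     / (s.n_x + s.n_y - 2))
    diff = s.mean_x - s.mean_y
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def cohens_d_samples(x, y) -> float:
    """Cohen's d from raw samples (x minus y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(GroupSummary(x.mean(), y.mean(),
                                 x.std(ddof=1), y.std(ddof=1),
                                 x.size, y.size))


def paired_t(x, y, side: str = "two-sided") -> tuple[float, float]:
    """Paired-sample t-test; ``side`` in {'two-sided', 'less', 'greater'}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences")
    res = sstats.ttest_rel(x, y, alternative=side)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DoseResponse:
    """Dose-response fits: linear, exponential and sigmoid, with SSEs."""

    doses: np.ndarray
    values: np.ndarray
    linear: tuple = ()
    exponential: tuple | None = None
    sigmoid: tuple | None = None
    sse: dict = field(default_factory=dict)
    pearson_r: float = np.nan
    pearson_p: float = np.nan

    def sse_improvement(self, model: str) -> float:
        """Relative SSE improvement of a nonlinear model over linear."""
        if model not in self.sse or np.isnan(self.sse[model]):
            return np.nan
        return 1.0 - self.sse[model] / self.sse["linear"]


def fit_dose_response(doses, values) -> DoseResponse:
    """Least-squares linear / exponential / sigmoid fits plus Pearson r.

    Models: y = a + b x;  y = a + b exp(c x);  y = a + b / (1 + exp(-(x -
    x0)/s)).  Non-convergent nonlinear fits are flagged (None) while the
    linear fit is always returned.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 dose points")
    if np.std(y) == 0:
        raise ValueError("constant values: correlation undefined")
    res = DoseResponse(doses=x, values=y)
    b, a = np.polyfit(x, y, 1)
    res.linear = (a, b)
    res.sse["linear"] = float(np.sum((y - (a + b * x)) ** 2))
    r, p = sstats.pearsonr(x, y)
    res.pearson_r, res.pearson_p = float(r), float(p)

    def expo(xx, a0, b0, c0):
        return a0 + b0 * np.exp(np.clip(c0 * xx, -50, 50))

    try:
        c0 = -1.0 if b < 0 else 1.0
        popt, _ = optimize.curve_fit(expo, x, y, p0=[y.mean(), b, c0],
                                     maxfev=10000)
        res.exponential = tuple(popt)
        res.sse["exponential"] = float(np.sum((y - expo(x, *popt)) ** 2))
    except (RuntimeError, optimize.OptimizeWarning):
        res.exponential = None
        res.sse["exponential"] = np.nan

    def sigm(xx, a0, b0, x0, s0):
        return a0 + b0 / (1.0 + np.exp(-np.clip((xx - x0) / s0, -50, 50)))

    if x.size >= 4:
        try:
            popt, _ = optimize.curve_fit(
                sigm, x, y,
                p0=[y.min(), y.max() - y.min(), x.mean(), np.ptp(x) / 4],
                maxfev=10000)
            res.sigmoid = tuple(popt)
            res.sse["sigmoid"] = float(np.sum((y - sigm(x, *popt)) ** 2))
        except (RuntimeError, optimize.OptimizeWarning):
            res.sigmoid = None
            res.sse["sigmoid"] = np.nan
    return res


# ---------------------------------------------------------------------------
# Condition sweep
# ---------------------------------------------------------------------------

def _seed_pair(master_seed: int, seed_index: int) -> tuple[int, int]:
    """Derive (structure seed, noise seed) for one seed index.

    Both are shared across conditions within the index so that condition
    contrasts are paired; different indices give independent circuits."""
    ss = np.random.SeedSequence([int(master_seed), int(seed_index)])
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


DEFAULT_CONDITIONS = ("healthy", "mdd", "mdd+a5pam:100", "mdd+nspam")


def run_condition_sweep(cfg: CircuitConfig | None = None,
                        conditions=DEFAULT_CONDITIONS,
                        n_seeds: int = 20,
                        master_seed: int = 0,
                        stimulus=None,
                        progress: bool = False):
    """Simulate every (condition, seed) cell and compute spiking metrics.

    Returns (tidy results table, per-condition detection table).  The tidy
    table has one row per (condition, seed, metric).  Detection metrics
    (threshold, failed/false probabilities) are computed per condition from
    the pooled post-stimulus distribution and per-circuit pre-stimulus
    fits.  Failures of any stage are recorded as NaN rows and the sweep
    continues.
    """
    cfg = cfg or CircuitConfig()
    rows = []
    spikes_by_condition: dict[str, list] = {c: [] for c in conditions}
    for k in range(n_seeds):
        s_struct, s_noise = _seed_pair(master_seed, k)
        healthy = build_circuit(cfg, seed=s_struct)
        proto = stimulus or basal_stimulus(onset=cfg.duration - 300.0)
        for cond in conditions:
            try:
                circ = apply_condition(healthy, cond)
                circ = attach_stimulus(circ, proto, seed=s_struct + 1)
                sd, _ = simulate(circ, seed=s_noise, record_axial=False)
                spikes_by_condition[cond].append(sd)
                onset = sd.stimulus_onset
                pre = (onset - det.PRE_PERIOD_MS, onset)
                metrics = {
                    "baseline_rate_Pyr": sd.population_rate("Pyr", pre),
                    "baseline_rate_SST": sd.population_rate("SST", pre),
                    "baseline_rate_PV": sd.population_rate("PV", pre),
                    "baseline_rate_VIP": sd.population_rate("VIP", pre),
                    "post_rate_Pyr": det.post_stimulus_rate(sd),
                }
                for m, v in metrics.items():
                    rows.append((cond, k, m, v))
            except Exception as exc:  # record and continue
                rows.append((cond, k, "error", np.nan))
                if progress:
                    print(f"[sweep] {cond} seed {k} failed: {exc}")
        if progress:
            print(f"[sweep] seed index {k + 1}/{n_seeds} done")

    # detection per condition (pooled post distribution)
    for cond, datasets in spikes_by_condition.items():
        if len(datasets) < 2:
            continue
        try:
            results = det.detection_analysis(datasets)
        except Exception as exc:
            if progress:
                print(f"[sweep] detection for {cond} failed: {exc}")
            continue
        for k, r in enumerate(results):
            rows.append((cond, k, "p_failed", r.p_failed))
            rows.append((cond, k, "p_false", r.p_false))
            rows.append((cond, k, "snr", r.snr))
            rows.append((cond, k, "threshold", r.threshold))
    table = pd.DataFrame(rows, columns=["condition", "seed", "metric", "value"])
    return table, spikes_by_condition


def sweep_eeg(cfg: CircuitConfig | None = None,
              conditions=("healthy", "mdd", "mdd+a5pam:100"),
              n_seeds: int = 10, master_seed: int = 0,
              duration_ms: float = 10700.0, settle_ms: float = 200.0,
              dipole_separation_um: float = 400.0,
              progress: bool = False):
    """EEG arm of the sweep: long unstimulated simulations -> dipole ->
    four-sphere EEG -> Welch PSD -> aperiodic/periodic decomposition.

    Returns (tidy metric table, {condition: [PsdResult, ...]}).
    """
    cfg = cfg or CircuitConfig()
    model = eegmod.FourSphereModel()
    rows = []
    psds: dict[str, list] = {c: [] for c in conditions}
    fs = 1000.0 / cfg.dt
    n_settle = int(settle_ms / cfg.dt)
    for k in range(n_seeds):
        s_struct, s_noise = _seed_pair(master_seed, k)
        healthy = build_circuit(cfg, seed=s_struct)
        for cond in conditions:
            circ = apply_condition(healthy, cond)
            _, axial = simulate(circ, duration=duration_ms, seed=s_noise,
                                record_axial=True)
            P = eegmod.compute_dipole(axial[n_settle:], dipole_separation_um)
            trace = eegmod.foursphere_potential(P, model)
            psd = eegmod.welch_psd(trace, fs)
            psds[cond].append(psd)
            fit = spmod.fit_spectrum(psd.power, psd.freqs)
            rows.append((cond, k, "eeg_power_theta",
                         eegmod.band_power(psd, eegmod.BANDS["theta"])))
            rows.append((cond, k, "eeg_power_alpha",
                         eegmod.band_power(psd, eegmod.BANDS["alpha"])))
            rows.append((cond, k, "eeg_power_beta",
                         eegmod.band_power(psd, eegmod.BANDS["beta"])))
            rows.append((cond, k, "aperiodic_exponent", fit.exponent))
            rows.append((cond, k, "aperiodic_auc", spmod.aperiodic_auc(fit)))
            rows.append((cond, k, "periodic_theta",
                         spmod.periodic_band_power(fit, eegmod.BANDS["theta"])))
            rows.append((cond, k, "periodic_beta",
                         spmod.periodic_band_power(fit, eegmod.BANDS["beta"])))
        if progress:
            print(f"[eeg] seed index {k + 1}/{n_seeds} done")
    table = pd.DataFrame(rows, columns=["condition", "seed", "metric", "value"])
    return table, psds


def summarize_sweep(table: pd.DataFrame,
                    reference: str = "healthy",
                    reference2: str = "mdd") -> pd.DataFrame:
    """Per (condition, metric) mean, SD, n and Cohen's d vs the references.

    d convention: condition minus reference."""
    out = []
    for (cond, metric), grp in table.groupby(["condition", "metric"]):
        vals = grp["value"].dropna().to_numpy()
        if vals.size < 2:
            continue
        row = {"condition": cond, "metric": metric,
               "mean": vals.mean(), "sd": vals.std(ddof=1), "n": vals.size}
        for label, ref in (("d_vs_healthy", reference), ("d_vs_mdd", reference2)):
            sel = table[(table.condition == ref) & (table.metric == metric)]
            ref_vals = sel["value"].dropna().to_numpy()
            if ref_vals.size >= 2 and cond != ref:
                row[label] = cohens_d_samples(vals, ref_vals)
            else:
                row[label] = np.nan
        out.append(row)
    return pd.DataFrame(out)
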