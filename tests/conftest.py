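"""Shared fixtures: reduced-model smoke sweeps reused across acceptance
tests so each condition grid is simulated once per session."""

import numpy as np
import pytest

from micropam.circuit import CircuitConfig, build_circuit, simulate
from micropam.eeg import compute_dipole, foursphere_potential, welch_psd
from micropam.interventions import apply_condition
from micropam.stats import run_condition_sweep, summarize_sweep, _seed_pair

SMOKE_SEEDS = 10
SMOKE_MASTER_SEED = 0
DOSES = (25, 50, 75, 100, 125, 150)
SWEEP_CONDITIONS = ("healthy", "mdd") \
    + tuple(f"mdd+a5pam:{d}" for d in DOSES) + ("mdd+nspam",)

EEG_SEEDS = 8
EEG_CONDITIONS = ("healthy", "mdd", "mdd+a5pam:100")
EEG_DURATION_MS = 7700.0
EEG_SETTLE_MS = 200.0
DIPOLE_SEPARATION_UM = 400.0


@pytest.fixture(scope="session")
def smoke_sweep():
    """Spiking sweep over all conditions (10 paired seeds)."""
    table, _ = run_condition_sweep(
        CircuitConfig(), SWEEP_CONDITIONS, n_seeds=SMOKE_SEEDS,
        master_seed=SMOKE_MASTER_SEED)
    return table, summarize_sweep(table)


@pytest.fixture(scope="session")
def eeg_smoke():
    """Seed-mean EEG spectra for healthy / depression / reference-dose
    PAM (paired seeds)."""
    cfg = CircuitConfig()
    fs = 1000.0 / cfg.dt
    n_settle = int(EEG_SETTLE_MS / cfg.dt)
    out = {}
    freqs = None
    for cond in EEG_CONDITIONS:
        powers = []
        for k in range(EEG_SEEDS):
            s_struct, s_noise = _seed_pair(SMOKE_MASTER_SEED, k)
            circ = build_circuit(cfg, seed=s_struct)
            circ = apply_condition(circ, cond)
            _, axial = simulate(circ, duration=EEG_DURATION_MS, seed=s_noise)
            P = compute_dipole(axial[n_settle:], DIPOLE_SEPARATION_UM)
            trace = foursphere_potential(P)
            psd = welch_psd(trace, fs)
            powers.append(psd.power)
            freqs = psd.freqs
        out[cond] = np.mean(powers, axis=0)
    return freqs, out


def metric_values(table, condition, metric):
    sel = table[(table.condition == condition) & (table.metric == metric)]
    return sel["value"].dropna().to_numpy()
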