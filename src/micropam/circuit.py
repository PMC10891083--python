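"""Reduced human L2/3 microcircuit: construction, background drive, stimuli
and simulation.

The circuit holds four populations (Pyr 80%, SST 5%, PV 7%, VIP 8% of
``N_total``), optionally scaled down by a factor ``s`` while preserving the
population balance.  Pyramidal neurons are two-compartment adaptive LIF
cells (somatic-basal + apical, see :mod:`micropam.cells`); interneurons are
single-compartment LIF cells.  Connectivity is Bernoulli per connection
class.  Every neuron receives an excitatory Ornstein-Uhlenbeck (OU)
conductance background whose mean and SD both equal ``g * exp(X_relative)``
where ``X_relative`` is the relative distance of the input site from the
soma; the inhibitory OU conductance is zero.  Pyramidal apical dendrites
receive five additional OU processes at relative distances 0.1/0.3/0.5/
0.7/0.9, folded in the two-compartment reduction into a single effective
apical OU drive with the same total mean and variance.

``simulate`` returns all spikes plus the somato-apical coupling (axial)
current of every pyramidal neuron, from which the EEG forward model builds
the equivalent current dipole.

Connection probabilities and synaptic weights of the original full-scale
model are not published as a compact table; the defaults here are a
documented stand-in calibrated so that the healthy circuit fires at the
target baseline rate (Pyr ~0.75 Hz, interneurons faster) -- see
docs/methods.md.  All of them can be overridden via the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numba
import numpy as np
import pandas as pd
import yaml

from .cells import (
    APICAL,
    SOMATIC,
    InterneuronParams,
    ParameterError,
    PyrNeuronParams,
    SynapseParams,
    TonicConductance,
    rectification,
    syn_norm_factor,
    tonic_conductance_ns,
)

__all__ = [
    "POPULATIONS",
    "CircuitConfig",
    "OUInput",
    "StimulusProtocol",
    "SpikeData",
    "Circuit",
    "ou_params",
    "place_ou_processes",
    "default_synapse_table",
    "basal_stimulus",
    "apical_stimulus",
    "build_circuit",
    "attach_stimulus",
    "simulate",
]

POPULATIONS = ("Pyr", "SST", "PV", "VIP")
FRACTIONS = {"Pyr": 0.80, "SST": 0.05, "PV": 0.07, "VIP": 0.08}

#: relative distances of the five extra apical OU processes
APICAL_OU_SITES = (0.1, 0.3, 0.5, 0.7, 0.9)


class ConfigError(ValueError):
    """Invalid circuit configuration."""


class SimulationError(RuntimeError):
    """Numeric failure during network integration."""


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck background drive
# ---------------------------------------------------------------------------

@dataclass
class OUInput:
    """One OU conductance process attached to a compartment.

    Mean and SD are tied (``g_mean == g_sd``), both in nS; ``tau`` is the
    correlation time in ms.  The conductance is floored at zero during
    integration.
    """

    compartment: str
    X_relative: float
    g_mean: float
    g_sd: float
    tau: float = 3.0
    E_exc: float = 0.0


def ou_params(g: float, X_relative: float) -> tuple[float, float]:
    """Mean and SD of the excitatory OU conductance at relative distance X.

    Both equal ``g * exp(X_relative)``: background drive grows with distance
    from the soma.  The inhibitory OU conductance is zero everywhere.
    """
    if not 0.0 <= X_relative <= 1.0:
        raise ConfigError(f"X_relative must lie in [0, 1], got {X_relative}")
    if g < 0:
        raise ConfigError("g must be non-negative")
    val = g * np.exp(X_relative)
    return val, val


def place_ou_processes(cell_params, g: float, tau: float = 3.0) -> list[OUInput]:
    """OU processes for one neuron.

    Each dendritic arbor carries one process at its midway point
    (X_relative = 0.5); pyramidal apical dendrites additionally carry five
    processes at X_relative in {0.1, 0.3, 0.5, 0.7, 0.9}.
    """
    procs = []
    for comp in cell_params.compartments:
        m, s = ou_params(g, 0.5)
        procs.append(OUInput(comp, 0.5, m, s, tau))
        if comp == APICAL:
            for x in APICAL_OU_SITES:
                m, s = ou_params(g, x)
                procs.append(OUInput(comp, x, m, s, tau))
    return procs


def _aggregate_ou(procs: list[OUInput], compartment: str) -> tuple[float, float]:
    """Fold several independent OU processes on one compartment into one.

    A sum of independent OU processes with common correlation time is again
    OU, with summed means and summed variances.
    """
    means = [p.g_mean for p in procs if p.compartment == compartment]
    sds = [p.g_sd for p in procs if p.compartment == compartment]
    return float(np.sum(means)), float(np.sqrt(np.sum(np.square(sds))))


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------

@dataclass
class StimulusGroup:
    population: str
    count: int
    delay_window: tuple[float, float]   # ms after stimulus onset
    g_syn: float                        # nS
    target: str = SOMATIC


@dataclass
class StimulusProtocol:
    """Brief afferent volley: per-population stimulated counts, uniform
    delay windows (ms post-onset) and synaptic conductances (nS)."""

    target: str = "basal"
    groups: tuple[StimulusGroup, ...] = ()
    onset: float = 3200.0   # ms

    def __post_init__(self) -> None:
        for grp in self.groups:
            lo, hi = grp.delay_window
            if hi < lo:
                raise ConfigError("delay window must be non-empty")


def basal_stimulus(onset: float = 3200.0) -> StimulusProtocol:
    """Basal-input protocol: 55 Pyr (2-4 ms, 4 nS), 35 PV (2-2.5 ms, 2 nS),
    65 early VIP (0.5-4.5 ms, 2.8 nS), 80 late VIP (7-12 ms, 2.2 nS)."""
    return StimulusProtocol(
        target="basal",
        onset=onset,
        groups=(
            StimulusGroup("Pyr", 55, (2.0, 4.0), 4.0, SOMATIC),
            StimulusGroup("PV", 35, (2.0, 2.5), 2.0, SOMATIC),
            StimulusGroup("VIP", 65, (0.5, 4.5), 2.8, SOMATIC),
            StimulusGroup("VIP", 80, (7.0, 12.0), 2.2, SOMATIC),
        ),
    )


def apical_stimulus(onset: float = 3200.0) -> StimulusProtocol:
    """Apical-input variant: 85 Pyr stimulated on the apical compartment."""
    return StimulusProtocol(
        target="apical",
        onset=onset,
        groups=(
            StimulusGroup("Pyr", 85, (2.0, 4.0), 4.0, APICAL),
            StimulusGroup("PV", 35, (2.0, 2.5), 2.0, SOMATIC),
            StimulusGroup("VIP", 65, (0.5, 4.5), 2.8, SOMATIC),
            StimulusGroup("VIP", 80, (7.0, 12.0), 2.2, SOMATIC),
        ),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_synapse_table() -> dict[tuple[str, str], SynapseParams]:
    """Connection classes: (pre, post) -> SynapseParams (with probability).

    Excitatory kinetics approximate AMPA/NMDA mixtures, inhibitory kinetics
    GABA-A.  SST->Pyr targets the apical compartment, PV->Pyr the
    somatic-basal compartment, Pyr->Pyr both (weight split equally).
    Weights/probabilities are the package's calibrated defaults.
    """
    exc = dict(tau_r=0.6, tau_d=4.0, E_syn=0.0)
    inh = dict(tau_r=0.8, tau_d=8.0, E_syn=-80.0)
    t = {
        ("Pyr", "Pyr"): SynapseParams("Pyr", "Pyr", SOMATIC, 0.35, p_connect=0.15, **exc),
        ("Pyr", "SST"): SynapseParams("Pyr", "SST", SOMATIC, 0.45, p_connect=0.25, **exc),
        ("Pyr", "PV"): SynapseParams("Pyr", "PV", SOMATIC, 0.60, p_connect=0.30, **exc),
        ("Pyr", "VIP"): SynapseParams("Pyr", "VIP", SOMATIC, 0.35, p_connect=0.25, **exc),
        ("SST", "Pyr"): SynapseParams("SST", "Pyr", APICAL, 0.8, p_connect=0.30, **inh),
        ("SST", "PV"): SynapseParams("SST", "PV", SOMATIC, 0.3, p_connect=0.30, **inh),
        ("SST", "VIP"): SynapseParams("SST", "VIP", SOMATIC, 0.7, p_connect=0.30, **inh),
        ("PV", "Pyr"): SynapseParams("PV", "Pyr", SOMATIC, 3.5, p_connect=0.35, **inh),
        ("PV", "PV"): SynapseParams("PV", "PV", SOMATIC, 1.0, p_connect=0.35, **inh),
        ("VIP", "SST"): SynapseParams("VIP", "SST", SOMATIC, 1.4, p_connect=0.45, **inh),
        ("VIP", "PV"): SynapseParams("VIP", "PV", SOMATIC, 0.5, p_connect=0.20, **inh),
    }
    return t


@dataclass
class CircuitConfig:
    """Full parameterization of the reduced microcircuit.

    ``scale`` shrinks every population count (and stimulated counts)
    proportionally; the desk-scale default is 0.2 (200 neurons).  ``ou_g``
    is the per-population OU base magnitude g (nS) before the exp(X)
    distance scaling; ``m_ou`` multiplies the pyramidal background
    (1x/3x/6x activity regimes).  ``tonic_G`` is the shared conductance
    density (mS/cm^2); ``sst_tonic_fraction`` is the assumed SST-mediated
    share of interneuron tonic inhibition.
    """

    N_total: int = 1000
    fractions: dict = field(default_factory=lambda: dict(FRACTIONS))
    scale: float = 0.2
    synapses: dict = field(default_factory=default_synapse_table)
    pyr: PyrNeuronParams = field(default_factory=PyrNeuronParams)
    interneurons: dict = field(default_factory=lambda: {
        "SST": InterneuronParams("SST", C_m=90.0, g_L=5.0, V_th=-52.0),
        "PV": InterneuronParams("PV", C_m=70.0, g_L=7.0, V_th=-52.0, t_ref=1.5),
        "VIP": InterneuronParams("VIP", C_m=60.0, g_L=4.5, V_th=-52.0),
    })
    tonic_G: float = 0.15              # mS/cm^2 (reduced-model fit scale)
    tonic: TonicConductance = field(default_factory=lambda: TonicConductance(
        G_tonic=0.15, E_GABA=-80.0))
    sst_tonic_fraction: dict = field(default_factory=lambda: {
        "SST": 0.18, "PV": 0.18, "VIP": 0.18})
    ou_g: dict = field(default_factory=lambda: {
        "Pyr": 0.75, "SST": 1.20, "PV": 1.10, "VIP": 1.00})
    m_ou: float = 1.0
    ou_tau: float = 3.0
    stim_gain: dict = field(default_factory=lambda: {
        "Pyr": 8.0, "PV": 0.5, "VIP": 3.0})
    duration: float = 3500.0           # ms
    dt: float = 0.1                    # ms
    seed: int = 0
    volume_um = (500.0, 500.0, 950.0)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"population fractions must sum to 1, got {total}")
        if not 0.0 < self.scale <= 1.0:
            raise ConfigError("scale must lie in (0, 1]")

    def counts(self) -> dict[str, int]:
        return {p: int(round(self.fractions[p] * self.N_total * self.scale))
                for p in POPULATIONS}

    # -- config file round trip (YAML) ------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "N_total": self.N_total,
            "fractions": self.fractions,
            "scale": self.scale,
            "tonic_G": self.tonic_G,
            "sst_tonic_fraction": self.sst_tonic_fraction,
            "ou_g": self.ou_g,
            "m_ou": self.m_ou,
            "ou_tau": self.ou_tau,
            "duration": self.duration,
            "dt": self.dt,
            "seed": self.seed,
            "synapses": {
                f"{k[0]}->{k[1]}": {
                    "target": v.target, "g_syn": v.g_syn, "tau_r": v.tau_r,
                    "tau_d": v.tau_d, "E_syn": v.E_syn, "p_connect": v.p_connect,
                } for k, v in self.synapses.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CircuitConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        syn = doc.pop("synapses", None)
        cfg = cls(**doc)
        if syn:
            table = {}
            for key, v in syn.items():
                pre, post = key.split("->")
                table[(pre, post)] = SynapseParams(pre, post, **v)
            cfg.synapses = table
        return cfg


# ---------------------------------------------------------------------------
# Built circuit
# ---------------------------------------------------------------------------

@dataclass
class _Channel:
    """Aggregated synaptic channel: all connection classes sharing target
    compartment, kinetics and reversal use one weight matrix and one pair of
    rise/decay state vectors."""

    target: str            # 'soma' or 'apical'
    tau_r: float
    tau_d: float
    E_syn: float
    W: np.ndarray          # (N_pre_total, n_post) weights in nS (peak-normalized)


@dataclass
class Circuit:
    """A built, simulation-ready microcircuit."""

    cfg: CircuitConfig
    seed: int
    types: np.ndarray                      # str array length N
    positions: np.ndarray                  # (N, 3) um
    channels: list
    class_index: dict                      # (pre,post) -> (chan_id, pre_idx, post_idx)
    G_ton_soma: np.ndarray                 # nS per neuron
    G_ton_api: np.ndarray                  # nS per Pyr
    ou_mean_soma: np.ndarray
    ou_sd_soma: np.ndarray
    ou_mean_api: np.ndarray
    ou_sd_api: np.ndarray
    stimulus: StimulusProtocol | None = None
    stim_events: list = field(default_factory=list)  # (time_ms, channel, post, weight)
    condition: str = "healthy"

    @property
    def N(self) -> int:
        return self.types.size

    @property
    def pyr_idx(self) -> np.ndarray:
        return np.flatnonzero(self.types == "Pyr")

    def pop_idx(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.types == pop)

    def copy(self) -> "Circuit":
        new = replace(self)
        new.channels = [replace(ch, W=ch.W.copy()) for ch in self.channels]
        new.G_ton_soma = self.G_ton_soma.copy()
        new.G_ton_api = self.G_ton_api.copy()
        new.stim_events = list(self.stim_events)
        return new

    def total_inhibitory_synaptic(self) -> float:
        """Sum of all inhibitory synaptic weights (bookkeeping)."""
        return float(sum(ch.W.sum() for ch in self.channels if ch.E_syn < -50))


def build_circuit(cfg: CircuitConfig, seed: int | None = None) -> Circuit:
    """Construct a circuit: population counts, Bernoulli connectivity,
    positions in the 500x500x950 um^3 volume (dipole-orientation
    bookkeeping only), tonic conductances and OU drive parameters.
    Deterministic given (cfg, seed)."""
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    counts = cfg.counts()
    types = np.concatenate([np.full(counts[p], p) for p in POPULATIONS])
    N = types.size
    vol = np.asarray(cfg.volume_um)
    positions = rng.uniform(0.0, 1.0, size=(N, 3)) * vol

    pyr = np.flatnonzero(types == "Pyr")
    n_pyr = pyr.size
    pop_index = {p: np.flatnonzero(types == p) for p in POPULATIONS}

    # group connection classes into channels
    chan_key_to_id: dict = {}
    channels: list[_Channel] = []
    class_index: dict = {}
    for (pre, post), sp in cfg.synapses.items():
        tgt = "apical" if sp.target == APICAL else "soma"
        if tgt == "apical" and post != "Pyr":
            raise ConfigError("apical targets exist only on Pyr neurons")
        key = (tgt, sp.tau_r, sp.tau_d, sp.E_syn)
        if key not in chan_key_to_id:
            n_post = n_pyr if tgt == "apical" else N
            chan_key_to_id[key] = len(channels)
            channels.append(_Channel(tgt, sp.tau_r, sp.tau_d, sp.E_syn,
                                     np.zeros((N, n_post))))
        cid = chan_key_to_id[key]
        pre_idx = pop_index[pre]
        post_idx_global = pop_index[post]
        if tgt == "apical":
            post_cols = np.searchsorted(pyr, post_idx_global)
        else:
            post_cols = post_idx_global
        # Bernoulli adjacency; no autapses
        adj = rng.random((pre_idx.size, post_cols.size)) < sp.p_connect
        if pre == post:
            np.fill_diagonal(adj, False)
        W = channels[cid].W
        # Pyr->Pyr excitation contacts both compartments: weight split equally
        weight = sp.g_syn
        if pre == "Pyr" and post == "Pyr":
            weight = sp.g_syn * 0.5
            # mirror onto the apical excitatory channel
            akey = ("apical", sp.tau_r, sp.tau_d, sp.E_syn)
            if akey not in chan_key_to_id:
                chan_key_to_id[akey] = len(channels)
                channels.append(_Channel("apical", sp.tau_r, sp.tau_d, sp.E_syn,
                                         np.zeros((N, n_pyr))))
            acid = chan_key_to_id[akey]
            apost = np.searchsorted(pyr, post_idx_global)
            channels[acid].W[np.ix_(pre_idx, apost)] += weight * adj
            class_index[("Pyr", "Pyr", "apical")] = (acid, pre_idx, apost)
        W[np.ix_(pre_idx, post_cols)] += weight * adj
        class_index[(pre, post)] = (cid, pre_idx, post_cols)

    # tonic conductance folded to absolute nS per compartment
    tc = replace(cfg.tonic, G_tonic=cfg.tonic_G)
    G_soma = np.zeros(N)
    for p in POPULATIONS:
        if p == "Pyr":
            area = cfg.pyr.area_cm2[0]
        else:
            area = cfg.interneurons[p].area_cm2
        G_soma[pop_index[p]] = tonic_conductance_ns(tc, area)
    G_api = np.full(n_pyr, tonic_conductance_ns(tc, cfg.pyr.area_cm2[1]))

    # OU drive: aggregate per compartment
    ou_mean_soma = np.zeros(N)
    ou_sd_soma = np.zeros(N)
    for p in POPULATIONS:
        g = cfg.ou_g[p] * (cfg.m_ou if p == "Pyr" else 1.0)
        cell = cfg.pyr if p == "Pyr" else cfg.interneurons[p]
        procs = place_ou_processes(cell, g, cfg.ou_tau)
        m, s = _aggregate_ou(procs, SOMATIC)
        ou_mean_soma[pop_index[p]] = m
        ou_sd_soma[pop_index[p]] = s
    g_pyr = cfg.ou_g["Pyr"] * cfg.m_ou
    procs = place_ou_processes(cfg.pyr, g_pyr, cfg.ou_tau)
    am, asd = _aggregate_ou(procs, APICAL)
    ou_mean_api = np.full(n_pyr, am)
    ou_sd_api = np.full(n_pyr, asd)

    return Circuit(cfg=cfg, seed=seed, types=types, positions=positions,
                   channels=channels, class_index=class_index,
                   G_ton_soma=G_soma, G_ton_api=G_api,
                   ou_mean_soma=ou_mean_soma, ou_sd_soma=ou_sd_soma,
                   ou_mean_api=ou_mean_api, ou_sd_api=ou_sd_api)


def attach_stimulus(circuit: Circuit, proto: StimulusProtocol,
                    seed: int) -> Circuit:
    """Attach one stimulus synapse to randomly chosen neurons per group.

    Stimulated counts scale with the circuit's scale factor (round half-up,
    minimum 1); delays are uniform within each group's window.  The
    configured per-population ``stim_gain`` folds the multiple synaptic
    contacts a stimulated morphological neuron receives into the single
    stimulus synapse of the reduction (contact counts differ per target
    cell type).  Returns a modified copy."""
    rng = np.random.default_rng(seed)
    circ = circuit.copy()
    circ.stimulus = proto
    s = circ.cfg.scale
    pyr = circ.pyr_idx
    # stimulus channels: excitatory kinetics, one per target compartment
    exc = next(sp for sp in circ.cfg.synapses.values() if sp.E_syn >= -20)
    events = []
    for grp in proto.groups:
        n = max(1, int(np.floor(grp.count * s + 0.5)))
        pool = circ.pop_idx(grp.population)
        if n > pool.size:
            raise ConfigError(
                f"stimulated count {n} exceeds population {grp.population}"
                f" size {pool.size}")
        chosen = rng.choice(pool, size=n, replace=False)
        delays = rng.uniform(grp.delay_window[0], grp.delay_window[1], size=n)
        target = "apical" if grp.target == APICAL else "soma"
        for neuron, d in zip(chosen, delays):
            if target == "apical":
                post = int(np.searchsorted(pyr, neuron))
            else:
                post = int(neuron)
            gain = circ.cfg.stim_gain.get(grp.population, 1.0)
            events.append((proto.onset + float(d), target,
                           exc.tau_r, exc.tau_d, exc.E_syn, post,
                           grp.g_syn * gain))
    circ.stim_events = sorted(events)
    return circ


# ---------------------------------------------------------------------------
# Spike container
# ---------------------------------------------------------------------------

@dataclass
class SpikeData:
    """Spike times (ms) per neuron with type labels."""

    spike_times: list                 # list of float arrays, one per neuron
    types: np.ndarray
    duration: float
    dt: float
    stimulus_onset: float | None = None
    condition: str = "healthy"
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def population_rate(self, pop: str = "Pyr",
                        interval: tuple[float, float] | None = None) -> float:
        """Mean single-neuron rate (Hz) of a population over ``interval``."""
        if interval is None:
            interval = (0.0, self.duration)
        lo, hi = interval
        idx = np.flatnonzero(self.types == pop)
        count = sum(int(np.count_nonzero((self.spike_times[i] >= lo)
                                         & (self.spike_times[i] < hi)))
                    for i in idx)
        return count / idx.size / ((hi - lo) / 1000.0)

    def to_csv(self, path, sidecar: bool = True) -> None:
        rows = [(i, self.types[i], t)
                for i in range(self.n_neurons)
                for t in self.spike_times[i]]
        df = pd.DataFrame(rows, columns=["neuron_id", "type", "time_ms"])
        df.to_csv(path, index=False)
        if sidecar:
            meta = {"duration": self.duration, "dt": self.dt,
                    "stimulus_onset": self.stimulus_onset,
                    "condition": self.condition, "seed": self.seed,
                    "n_neurons": self.n_neurons,
                    "types": self.types.tolist()}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh)

    @classmethod
    def from_csv(cls, path) -> "SpikeData":
        df = pd.read_csv(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        n = meta["n_neurons"]
        spikes = [np.array([], dtype=float) for _ in range(n)]
        for nid, grp in df.groupby("neuron_id"):
            spikes[int(nid)] = np.sort(grp["time_ms"].to_numpy(dtype=float))
        return cls(spike_times=spikes, types=np.asarray(meta["types"]),
                   duration=meta["duration"], dt=meta["dt"],
                   stimulus_onset=meta.get("stimulus_onset"),
                   condition=meta.get("condition", "healthy"),
                   seed=meta.get("seed"))


# ---------------------------------------------------------------------------
# Simulation engine (exponential-Euler, numba-compiled inner loop)
# ---------------------------------------------------------------------------

_RNG_CHUNK = 4096  # steps of pre-drawn OU innovations per kernel call


@numba.njit(cache=True)
def _run_chunk(step0, n_sub, dt,
               V_s, V_a, adapt, ref,
               xr_s, xd_s, xr_a, xd_a,
               er_s, ed_s, E_s, er_a, ed_a, E_a,
               Wn_s, Wn_a,
               g_ou_s, g_ou_a, ou_mean_s, ou_sd_s, ou_mean_a, ou_sd_a,
               ou_rho, ou_noise, innov_s, innov_a,
               stim_step, stim_chan, stim_apical, stim_post, stim_w, stim_ptr,
               C_s, gL_s, E_L, V_th, V_reset, t_ref, w_ad, ad_decay,
               C_a, gL_a, E_L_a, g_c, pyr_idx, pyr_col,
               Gts, Gta, fmin, V_half, inv_k, E_gaba,
               axial, record_axial,
               spike_step, spike_id, spike_count):
    N = V_s.size
    n_pyr = V_a.size
    n_ch_s = er_s.size
    n_ch_a = er_a.size
    one_minus_fmin = 1.0 - fmin
    for sub in range(n_sub):
        step = step0 + sub
        # OU update (exact discretization, floored at 0)
        for i in range(N):
            g = g_ou_s[i] + (ou_mean_s[i] - g_ou_s[i]) * (1.0 - ou_rho) \
                + ou_sd_s[i] * ou_noise * innov_s[sub, i]
            g_ou_s[i] = g if g > 0.0 else 0.0
        for i in range(n_pyr):
            g = g_ou_a[i] + (ou_mean_a[i] - g_ou_a[i]) * (1.0 - ou_rho) \
                + ou_sd_a[i] * ou_noise * innov_a[sub, i]
            g_ou_a[i] = g if g > 0.0 else 0.0

        # stimulus arrivals
        while stim_ptr[0] < stim_step.size and stim_step[stim_ptr[0]] == step:
            k = stim_ptr[0]
            c = stim_chan[k]
            post = stim_post[k]
            w = stim_w[k]
            if stim_apical[k]:
                xr_a[c, post] += w
                xd_a[c, post] += w
            else:
                xr_s[c, post] += w
                xd_s[c, post] += w
            stim_ptr[0] += 1

        # synaptic channel decay
        for c in range(n_ch_s):
            for i in range(N):
                xr_s[c, i] *= er_s[c]
                xd_s[c, i] *= ed_s[c]
        for c in range(n_ch_a):
            for i in range(n_pyr):
                xr_a[c, i] *= er_a[c]
                xd_a[c, i] *= ed_a[c]

        # soma update
        for i in range(N):
            g_syn = 0.0
            drive = 0.0
            for c in range(n_ch_s):
                g = xd_s[c, i] - xr_s[c, i]
                g_syn += g
                drive += g * E_s[c]
            r = fmin + one_minus_fmin * 0.5 * (
                1.0 + np.tanh(0.5 * (V_s[i] - V_half) * inv_k))
            gt = Gts[i] * r
            g_tot = gL_s[i] + g_syn + g_ou_s[i] + gt
            num = gL_s[i] * E_L[i] + drive + gt * E_gaba - adapt[i]
            pc = pyr_col[i]
            if pc >= 0:
                g_tot += g_c
                num += g_c * V_a[pc]
            v_inf = num / g_tot
            V_s[i] = v_inf + (V_s[i] - v_inf) * np.exp(-dt * g_tot / C_s[i])

        # apical update
        for j in range(n_pyr):
            g_syn = 0.0
            drive = 0.0
            for c in range(n_ch_a):
                g = xd_a[c, j] - xr_a[c, j]
                g_syn += g
                drive += g * E_a[c]
            r = fmin + one_minus_fmin * 0.5 * (
                1.0 + np.tanh(0.5 * (V_a[j] - V_half) * inv_k))
            gt = Gta[j] * r
            g_tot = gL_a + g_syn + g_ou_a[j] + gt + g_c
            num = gL_a * E_L_a + drive + gt * E_gaba + g_c * V_s[pyr_idx[j]]
            v_inf = num / g_tot
            V_a[j] = v_inf + (V_a[j] - v_inf) * np.exp(-dt * g_tot / C_a)

        # refractory clamp, spike detection, adaptation, propagation
        for i in range(N):
            adapt[i] *= ad_decay[i]
            if ref[i] > 0.0:
                V_s[i] = V_reset[i]
                ref[i] -= dt
            elif V_s[i] >= V_th[i]:
                V_s[i] = V_reset[i]
                ref[i] = t_ref[i]
                adapt[i] += w_ad[i]
                k = spike_count[0]
                if k < spike_step.size:
                    spike_step[k] = step + 1
                    spike_id[k] = i
                    spike_count[0] = k + 1
                for c in range(n_ch_s):
                    for p in range(N):
                        w = Wn_s[c, i, p]
                        if w != 0.0:
                            xr_s[c, p] += w
                            xd_s[c, p] += w
                for c in range(n_ch_a):
                    for p in range(n_pyr):
                        w = Wn_a[c, i, p]
                        if w != 0.0:
                            xr_a[c, p] += w
                            xd_a[c, p] += w

        if record_axial:
            for j in range(n_pyr):
                axial[sub, j] = g_c * (V_a[j] - V_s[pyr_idx[j]])
    return 0


def simulate(circuit: Circuit, duration: float | None = None,
             dt: float | None = None, seed: int = 0,
             record_axial: bool = True,
             ) -> tuple[SpikeData, np.ndarray | None]:
    """Run the network and return (spikes, per-Pyr axial current trace).

    The axial trace (pA, shape ``(n_steps, n_pyr)``, float32) is the
    somato-apical coupling current ``g_c * (V_apical - V_soma)`` of every
    pyramidal neuron sampled at ``1/dt``; the EEG module turns it into an
    equivalent dipole moment.  Deterministic given ``seed``.
    """
    cfg = circuit.cfg
    if duration is None:
        duration = cfg.duration
    if dt is None:
        dt = cfg.dt
    if duration <= 0:
        raise ConfigError("duration must be positive")
    rng = np.random.default_rng(seed)

    N = circuit.N
    types = circuit.types
    pyr = circuit.pyr_idx
    n_pyr = pyr.size
    n_steps = int(round(duration / dt))

    # --- per-neuron parameter arrays (soma) ---
    C_s = np.empty(N); gL_s = np.empty(N); E_L = np.empty(N)
    V_th = np.empty(N); V_reset = np.empty(N); t_ref = np.empty(N)
    w_ad = np.zeros(N); tau_ad = np.full(N, 100.0)
    p = cfg.pyr
    C_s[pyr] = p.C_m[0]; gL_s[pyr] = p.g_L[0]; E_L[pyr] = p.E_L
    V_th[pyr] = p.V_th; V_reset[pyr] = p.V_reset; t_ref[pyr] = p.t_ref
    w_ad[pyr] = p.w_adapt * 1e3; tau_ad[pyr] = p.tau_adapt
    for pop, ip in cfg.interneurons.items():
        idx = circuit.pop_idx(pop)
        C_s[idx] = ip.C_m; gL_s[idx] = ip.g_L; E_L[idx] = ip.E_L
        V_th[idx] = ip.V_th; V_reset[idx] = ip.V_reset; t_ref[idx] = ip.t_ref
        w_ad[idx] = ip.w_adapt * 1e3; tau_ad[idx] = ip.tau_adapt
    C_a = p.C_m[1]; gL_a = p.g_L[1]; g_c = p.g_c

    tc = cfg.tonic
    E_gaba = tc.E_GABA

    # --- synaptic channels grouped by target compartment ---
    soma_ch = [ch for ch in circuit.channels if ch.target == "soma"]
    api_ch = [ch for ch in circuit.channels if ch.target == "apical"]

    def _stack(chs, n_post):
        if not chs:
            return (np.zeros(0), np.zeros(0), np.zeros(0),
                    np.zeros((0, N, n_post)),
                    np.zeros((0, n_post)), np.zeros((0, n_post)))
        er = np.array([np.exp(-dt / c.tau_r) for c in chs])
        ed = np.array([np.exp(-dt / c.tau_d) for c in chs])
        E = np.array([c.E_syn for c in chs])
        Wn = np.stack([c.W * syn_norm_factor(c.tau_r, c.tau_d) for c in chs])
        return er, ed, E, Wn, np.zeros((len(chs), n_post)), np.zeros((len(chs), n_post))

    er_s, ed_s, E_s, Wn_s, xr_s, xd_s = _stack(soma_ch, N)
    er_a, ed_a, E_a, Wn_a, xr_a, xd_a = _stack(api_ch, n_pyr)

    # stimulus events -> flat arrays sorted by step
    stim = sorted(circuit.stim_events)
    stim_step = np.array([int(round(ev[0] / dt)) for ev in stim], dtype=np.int64)
    stim_apical = np.zeros(len(stim), dtype=np.bool_)
    stim_chan = np.zeros(len(stim), dtype=np.int64)
    stim_post = np.zeros(len(stim), dtype=np.int64)
    stim_w = np.zeros(len(stim))
    for k, (t_ev, target, tau_r, tau_d, E_syn, post, w) in enumerate(stim):
        group = api_ch if target == "apical" else soma_ch
        cid = None
        for i, ch in enumerate(group):
            if ch.tau_r == tau_r and ch.tau_d == tau_d and ch.E_syn == E_syn:
                cid = i
                break
        if cid is None:
            raise ConfigError("no synaptic channel matches stimulus kinetics")
        stim_apical[k] = target == "apical"
        stim_chan[k] = cid
        stim_post[k] = post
        stim_w[k] = w * syn_norm_factor(tau_r, tau_d)
    stim_ptr = np.zeros(1, dtype=np.int64)

    # --- OU processes ---
    ou_rho = float(np.exp(-dt / cfg.ou_tau))
    ou_noise = float(np.sqrt(1.0 - ou_rho**2))
    g_ou_s = circuit.ou_mean_soma.copy()
    g_ou_a = circuit.ou_mean_api.copy()

    # --- state ---
    V_s = E_L.copy()
    V_a = np.full(n_pyr, p.E_L)
    adapt = np.zeros(N)
    ref = np.zeros(N)
    ad_decay = np.exp(-dt / tau_ad)
    pyr_col = np.full(N, -1, dtype=np.int64)
    pyr_col[pyr] = np.arange(n_pyr)

    axial = np.empty((n_steps, n_pyr), dtype=np.float32) if record_axial \
        else np.empty((0, n_pyr), dtype=np.float32)
    cap = max(10_000, int(N * duration / 1000.0 * 200))  # 200 Hz headroom
    spike_step = np.zeros(cap, dtype=np.int64)
    spike_id = np.zeros(cap, dtype=np.int64)
    spike_count = np.zeros(1, dtype=np.int64)

    nz = np.random.default_rng(rng.integers(2**31))
    step0 = 0
    while step0 < n_steps:
        n_sub = min(_RNG_CHUNK, n_steps - step0)
        innov_s = nz.standard_normal((n_sub, N))
        innov_a = nz.standard_normal((n_sub, n_pyr))
        ax_chunk = axial[step0:step0 + n_sub] if record_axial \
            else np.empty((0, n_pyr), dtype=np.float32)
        _run_chunk(step0, n_sub, dt,
                   V_s, V_a, adapt, ref,
                   xr_s, xd_s, xr_a, xd_a,
                   er_s, ed_s, E_s, er_a, ed_a, E_a,
                   Wn_s, Wn_a,
                   g_ou_s, g_ou_a,
                   circuit.ou_mean_soma, circuit.ou_sd_soma,
                   circuit.ou_mean_api, circuit.ou_sd_api,
                   ou_rho, ou_noise, innov_s, innov_a,
                   stim_step, stim_chan, stim_apical, stim_post, stim_w,
                   stim_ptr,
                   C_s, gL_s, E_L, V_th, V_reset, t_ref, w_ad, ad_decay,
                   C_a, gL_a, p.E_L, g_c, pyr, pyr_col,
                   circuit.G_ton_soma, circuit.G_ton_api,
                   tc.f_min, tc.V_half, 1.0 / tc.k, E_gaba,
                   ax_chunk, record_axial,
                   spike_step, spike_id, spike_count)
        if not (np.all(np.isfinite(V_s)) and np.all(np.isfinite(V_a))):
            bad_s = np.flatnonzero(~np.isfinite(V_s))
            bad = int(bad_s[0]) if bad_s.size else \
                int(pyr[np.flatnonzero(~np.isfinite(V_a))[0]])
            raise SimulationError(
                f"non-finite potential for neuron {bad} by "
                f"t={(step0 + n_sub) * dt} ms")
        step0 += n_sub

    n_spk = int(spike_count[0])
    if n_spk >= cap:
        raise SimulationError("spike buffer overflow (runaway activity)")
    times = spike_step[:n_spk] * dt
    ids = spike_id[:n_spk]
    spikes = [np.sort(times[ids == i]) for i in range(N)]

    sd = SpikeData(
        spike_times=spikes,
        types=types, duration=duration, dt=dt,
        stimulus_onset=(circuit.stimulus.onset if circuit.stimulus else None),
        condition=circuit.condition, seed=seed)
    return sd, (axial if record_axial else None)
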