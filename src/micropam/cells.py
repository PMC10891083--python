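"""Point-neuron, synapse and tonic-inhibition primitives.

Units follow the convention used throughout the package: membrane potential
in mV, time in ms, conductance in nS, capacitance in pF and current in pA
(note 1 nS x 1 mV = 1 pA and 1 pF / 1 nS = 1 ms, so the membrane equations
need no unit conversion factors).  Tonic conductance densities are kept in
mS/cm^2, the unit in which experimental fits are reported, and folded to
absolute nS through configurable compartment areas (cm^2):
1 mS/cm^2 x 1 cm^2 = 1e6 nS.

The pyramidal neuron is an adaptive leaky integrate-and-fire model with two
electrically coupled compartments, a spiking somatic-basal compartment and a
passive apical compartment.  The two-compartment reduction preserves the
dendritic targeting logic the pharmacological interventions rely on: SST
inhibition and alpha5-sensitive tonic inhibition act on the apical
compartment, perisomatic PV inhibition on the somatic-basal compartment.
Interneurons (SST, PV, VIP) are single-compartment integrate-and-fire cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PyrNeuronParams",
    "InterneuronParams",
    "TonicConductance",
    "SynapseParams",
    "NeuronState",
    "MS_PER_CM2_TO_NS",
    "rectification",
    "tonic_current",
    "syn_peak_time",
    "syn_norm_factor",
    "synaptic_conductance",
    "synaptic_current",
    "init_state",
    "step_neuron",
]

#: absolute conductance (nS) per (mS/cm^2 x cm^2)
MS_PER_CM2_TO_NS = 1.0e6

SOMATIC = "somatic-basal"
APICAL = "apical"


class ParameterError(ValueError):
    """Invalid model parameters."""


class NumericError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class PyrNeuronParams:
    """Two-compartment adaptive LIF pyramidal neuron.

    ``C_m``, ``g_L`` and ``area_cm2`` are given per compartment in the order
    (somatic-basal, apical).  ``g_c`` couples the compartments; ``w_adapt``
    (nA) increments a spike-triggered adaptation current decaying with
    ``tau_adapt``.
    """

    C_m: tuple[float, float] = (150.0, 90.0)       # pF
    g_L: tuple[float, float] = (9.0, 5.0)          # nS
    E_L: float = -72.0                             # mV
    V_th: float = -50.0                            # mV
    V_reset: float = -62.0                         # mV
    t_ref: float = 3.0                             # ms
    g_c: float = 12.0                              # nS
    w_adapt: float = 0.02                          # nA per spike
    tau_adapt: float = 120.0                       # ms
    area_cm2: tuple[float, float] = (0.5e-5, 4.0e-5)
    compartments: tuple[str, str] = (SOMATIC, APICAL)

    def __post_init__(self) -> None:
        if len(self.compartments) != 2:
            raise ParameterError("pyramidal neuron has exactly two compartments")
        if any(g < 0 for g in self.g_L) or self.g_c < 0:
            raise ParameterError("conductances must be non-negative")
        if self.t_ref <= 0:
            raise ParameterError("t_ref must be positive")

    @property
    def n_compartments(self) -> int:
        return 2


@dataclass
class InterneuronParams:
    """Single-compartment LIF interneuron (one instance per SST/PV/VIP class)."""

    cell_type: str = "SST"
    C_m: float = 90.0
    g_L: float = 6.0
    E_L: float = -70.0
    V_th: float = -50.0
    V_reset: float = -60.0
    t_ref: float = 2.0
    w_adapt: float = 0.0
    tau_adapt: float = 100.0
    area_cm2: float = 4.0e-5
    compartments: tuple[str] = (SOMATIC,)

    def __post_init__(self) -> None:
        if len(self.compartments) != 1:
            raise ParameterError("interneurons have exactly one compartment")
        if self.g_L < 0:
            raise ParameterError("conductances must be non-negative")
        if self.t_ref <= 0:
            raise ParameterError("t_ref must be positive")

    @property
    def n_compartments(self) -> int:
        return 1


@dataclass
class TonicConductance:
    """Outwardly rectifying tonic GABA-A conductance.

    ``G_tonic`` is a density (mS/cm^2).  The voltage-dependent rectification
    factor is ``r(V) = f_min + (1 - f_min) / (1 + exp(-(V - V_half)/k))``,
    bounded in [f_min, 1] and monotone in V, so the conductance is largest at
    depolarized potentials (outward rectification).
    """

    G_tonic: float = 0.0          # mS/cm^2
    E_GABA: float = -80.0         # mV
    V_half: float = -50.0         # mV
    k: float = 10.0               # mV
    f_min: float = 0.4

    def __post_init__(self) -> None:
        if self.G_tonic < 0:
            raise ParameterError("G_tonic must be non-negative")
        if not 0.0 <= self.f_min <= 1.0:
            raise ParameterError("f_min must lie in [0, 1]")
        if self.k <= 0:
            raise ParameterError("rectification slope k must be positive")


def rectification(V, tc: TonicConductance):
    """Rectification factor r(V) in [f_min, 1]."""
    x = (np.asarray(V, dtype=float) - tc.V_half) / tc.k
    sig = 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically safe logistic
    return tc.f_min + (1.0 - tc.f_min) * sig


def tonic_current(V, tc: TonicConductance, area_cm2: float | None = None):
    """Tonic inhibition current at potential ``V``.

    With ``area_cm2=None`` the current density is returned in uA/cm^2
    (mS/cm^2 x mV); with an area, the absolute current in pA.  Sign
    convention: a negative value is an inward current at the electrode in
    voltage clamp (V below the GABA reversal gives a negative, inward
    current).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ParameterError("V must be finite")
    density = tc.G_tonic * rectification(V, tc) * (V - tc.E_GABA)  # uA/cm^2
    if area_cm2 is None:
        return density
    return density * area_cm2 * 1e6  # uA -> pA

def tonic_conductance_ns(tc: TonicConductance, area_cm2: float) -> float:
    """Fold a conductance density into an absolute conductance (nS)."""
    return tc.G_tonic * area_cm2 * MS_PER_CM2_TO_NS


@dataclass
class SynapseParams:
    """Conductance-based synapse with a double-exponential waveform.

    One instance describes a connection class (pre-type -> post-type ->
    target compartment).  The waveform is normalized so its peak equals
    ``g_syn``.  ``stp`` is a hook for short-term plasticity parameters; the
    default model is static.
    """

    pre: str = "Pyr"
    post: str = "Pyr"
    target: str = SOMATIC
    g_syn: float = 1.0            # nS
    tau_r: float = 0.5            # ms
    tau_d: float = 5.0            # ms
    E_syn: float = 0.0            # mV
    p_connect: float = 0.0
    stp: dict | None = None

    def __post_init__(self) -> None:
        if not self.tau_d > self.tau_r > 0:
            raise ParameterError("need tau_d > tau_r > 0")
        if self.g_syn < 0:
            raise ParameterError("g_syn must be non-negative")
        if not 0.0 <= self.p_connect <= 1.0:
            raise ParameterError("connection probability must lie in [0, 1]")

    @property
    def is_inhibitory(self) -> bool:
        return self.E_syn < -50.0


def syn_peak_time(tau_r: float, tau_d: float) -> float:
    """Time to peak of the double-exponential conductance, after onset."""
    return tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)


def syn_norm_factor(tau_r: float, tau_d: float) -> float:
    """Factor scaling (exp(-t/tau_d) - exp(-t/tau_r)) to unit peak."""
    tp = syn_peak_time(tau_r, tau_d)
    return 1.0 / (math.exp(-tp / tau_d) - math.exp(-tp / tau_r))


def synaptic_conductance(t, sp: SynapseParams, spike_times) -> np.ndarray:
    """Summed conductance waveform (nS) at times ``t`` for the given spikes."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size > 1 and np.any(np.diff(spikes) < 0):
        raise ParameterError("spike times must be sorted")
    f = syn_norm_factor(sp.tau_r, sp.tau_d)
    g = np.zeros_like(t)
    for ts in spikes:
        dt = t - ts
        m = dt >= 0
        g[m] += f * (np.exp(-dt[m] / sp.tau_d) - np.exp(-dt[m] / sp.tau_r))
    return sp.g_syn * g


def synaptic_current(t, V, sp: SynapseParams, spike_times) -> np.ndarray:
    """Synaptic current (pA) at times ``t`` and potential ``V`` (mV)."""
    return synaptic_conductance(t, sp, spike_times) * (np.asarray(V) - sp.E_syn)


# ---------------------------------------------------------------------------
# Single-neuron forward integration (reference/oracle path; the network
# engine in `circuit` vectorizes the same update across neurons)
# ---------------------------------------------------------------------------

@dataclass
class NeuronState:
    """Mutable integration state of a single neuron."""

    V: np.ndarray                  # mV, one entry per compartment
    adapt: float = 0.0             # pA adaptation current
    refractory: float = 0.0        # ms remaining
    spiked: bool = False
    t: float = 0.0                 # ms


def init_state(params) -> NeuronState:
    n = params.n_compartments
    return NeuronState(V=np.full(n, params.E_L, dtype=float))


def _as_pair(x, n):
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    return arr


def step_neuron(state: NeuronState, params, I_ext, dt: float,
                tonic: TonicConductance | None = None) -> NeuronState:
    """Advance one integration step with exponential-Euler.

    ``I_ext`` is the external current (pA) per compartment (scalar for
    single-compartment neurons).  Compartment 0 is the spiking
    somatic-basal compartment; compartment 1 (pyramidal only) is the passive
    apical compartment coupled through ``g_c``.  Tonic inhibition, when
    given, acts on every compartment with the rectified conductance frozen
    at the pre-step potential.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    n = params.n_compartments
    V = state.V
    if not np.all(np.isfinite(V)):
        raise NumericError(f"non-finite membrane potential at t={state.t} ms: {V}")
    I = _as_pair(I_ext, n)
    C = _as_pair(params.C_m, n)
    gL = _as_pair(params.g_L, n)
    if isinstance(params, PyrNeuronParams):
        areas = np.asarray(params.area_cm2, dtype=float)
    else:
        areas = np.asarray([params.area_cm2], dtype=float)

    g_tot = gL.copy()
    drive = gL * params.E_L + I - state.adapt
    if tonic is not None and tonic.G_tonic > 0:
        g_ton = tonic.G_tonic * areas * MS_PER_CM2_TO_NS * rectification(V, tonic)
        g_tot = g_tot + g_ton
        drive = drive + g_ton * tonic.E_GABA
    if n == 2:
        gc = params.g_c
        g_tot = g_tot + gc
        drive = drive + gc * V[::-1]

    V_inf = drive / g_tot
    V_new = V_inf + (V - V_inf) * np.exp(-dt * g_tot / C)

    adapt = state.adapt * math.exp(-dt / params.tau_adapt) if params.tau_adapt > 0 else 0.0
    refractory = max(0.0, state.refractory - dt)
    spiked = False
    if state.refractory > 0:
        V_new[0] = params.V_reset
    elif V_new[0] >= params.V_th:
        spiked = True
        V_new[0] = params.V_reset
        refractory = params.t_ref
        adapt += params.w_adapt * 1e3  # nA -> pA
    if not np.all(np.isfinite(V_new)):
        raise NumericError(f"integration diverged at t={state.t + dt} ms")
    return NeuronState(V=V_new, adapt=adapt, refractory=refractory,
                       spiked=spiked, t=state.t + dt)
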