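"""Condition transforms: depression, alpha5-PAM dose, non-selective PAM.

Every intervention is a purely multiplicative transform of conductances on a
built circuit:

* depression — 40% loss of SST-mediated inhibition: all SST->X synaptic
  weights x0.6; pyramidal apical tonic conductance x0.6 (apical
  compartments only); each interneuron's tonic conductance reduced by 40%
  of its configured SST-mediated fraction.
* alpha5-PAM at dose fraction delta — apical pyramidal tonic conductance and
  SST->Pyr synaptic weights x(1 + delta * m) with reference modulation
  m = 0.60 (the fitted 60% conductance increase at the experimental
  reference dose); nothing else is touched, reflecting the negligible
  alpha5 expression in interneurons.
* non-selective PAM — the same x1.60 applied to every inhibitory synaptic
  weight and every tonic conductance in the circuit (benzodiazepine-like).

Transforms compose only in the order the study design uses:
healthy -> depression -> (one PAM).  Re-applying a transform raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Circuit

__all__ = [
    "REFERENCE_MODULATION",
    "Intervention",
    "apply_depression",
    "apply_a5pam",
    "apply_nonselective_pam",
    "apply_condition",
    "parse_condition",
]

#: fitted conductance modulation at the experimental reference dose
REFERENCE_MODULATION = 0.60

#: fractional loss of SST-mediated inhibition in the depression condition
DEPRESSION_LOSS = 0.40


class InterventionError(RuntimeError):
    """Illegal intervention composition."""


@dataclass
class Intervention:
    """Named condition expressed as multiplicative conductance scalings."""

    name: str = "healthy"
    sst_synaptic_scale: float = 1.0
    sst_tonic_scale: float = 1.0
    apical_tonic_scale: float = 1.0
    sst_to_pyr_scale: float = 1.0
    global_inhibitory_scale: float = 1.0
    dose: float = 0.0
    m: float = REFERENCE_MODULATION

    def __post_init__(self) -> None:
        for v in (self.sst_synaptic_scale, self.sst_tonic_scale,
                  self.apical_tonic_scale, self.sst_to_pyr_scale,
                  self.global_inhibitory_scale):
            if v <= 0:
                raise ValueError("intervention scales must be positive")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


def _scale_class(circ: Circuit, pre: str, post: str, factor: float) -> None:
    key = (pre, post)
    if key not in circ.class_index:
        return
    cid, pre_idx, post_idx = circ.class_index[key]
    circ.channels[cid].W[np.ix_(pre_idx, post_idx)] *= factor


def apply_depression(circuit: Circuit) -> Circuit:
    """40% reduction of SST-mediated synaptic and tonic inhibition.

    Returns a transformed copy; raises if the circuit is already in a
    non-healthy condition (the transform is not idempotent)."""
    if circuit.condition != "healthy":
        raise InterventionError(
            f"depression must start from a healthy circuit, got "
            f"{circuit.condition!r}")
    circ = circuit.copy()
    keep = 1.0 - DEPRESSION_LOSS
    for (pre, post) in list(circ.cfg.synapses):
        if pre == "SST":
            _scale_class(circ, pre, post, keep)
    # Pyr tonic: apical compartments only
    circ.G_ton_api *= keep
    # interneuron tonic: reduce the SST-mediated share by 40%
    for pop, frac in circ.cfg.sst_tonic_fraction.items():
        idx = circ.pop_idx(pop)
        circ.G_ton_soma[idx] *= (1.0 - DEPRESSION_LOSS * frac)
    circ.condition = "mdd"
    return circ


def apply_a5pam(circuit: Circuit, dose: float = 1.0) -> Circuit:
    """Alpha5-selective PAM at ``dose`` (fraction of the reference dose).

    Scales the pyramidal apical tonic conductance and the SST->Pyr synaptic
    weights by ``1 + dose * m``; the sweep of the study uses dose in
    {0.25, ..., 1.5}."""
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    if "pam" in circuit.condition:
        raise InterventionError("a PAM transform was already applied")
    circ = circuit.copy()
    factor = 1.0 + dose * REFERENCE_MODULATION
    _scale_class(circ, "SST", "Pyr", factor)
    circ.G_ton_api *= factor
    circ.condition = (circuit.condition +
                      f"+a5pam:{int(round(dose * 100))}").lstrip("+")
    return circ


def apply_nonselective_pam(circuit: Circuit) -> Circuit:
    """Non-selective PAM: x(1 + m) on every inhibitory synaptic weight and
    every tonic conductance (all populations, all compartments)."""
    if "pam" in circuit.condition:
        raise InterventionError("a PAM transform was already applied")
    circ = circuit.copy()
    factor = 1.0 + REFERENCE_MODULATION
    for ch in circ.channels:
        if ch.E_syn < -50:
            ch.W *= factor
    circ.G_ton_soma *= factor
    circ.G_ton_api *= factor
    circ.condition = circuit.condition + "+nspam"
    return circ


def parse_condition(spec: str) -> dict:
    """Parse a condition label: ``healthy | mdd | mdd+a5pam:<dose%> |
    mdd+nspam``."""
    spec = spec.strip().lower()
    if spec == "healthy":
        return {"depression": False, "pam": None, "dose": 0.0}
    if not spec.startswith("mdd"):
        raise ValueError(f"unknown condition {spec!r}")
    out = {"depression": True, "pam": None, "dose": 0.0}
    rest = spec[3:]
    if not rest:
        return out
    if rest.startswith("+a5pam"):
        out["pam"] = "a5pam"
        dose = 100.0
        if ":" in rest:
            dose = float(rest.split(":", 1)[1].rstrip("%"))
        out["dose"] = dose / 100.0
    elif rest == "+nspam":
        out["pam"] = "nspam"
    else:
        raise ValueError(f"unknown condition {spec!r}")
    return out


def apply_condition(circuit: Circuit, condition: str) -> Circuit:
    """Apply a condition label to a healthy circuit."""
    parsed = parse_condition(condition)
    circ = circuit
    if parsed["depression"]:
        circ = apply_depression(circ)
    if parsed["pam"] == "a5pam":
        circ = apply_a5pam(circ, parsed["dose"])
    elif parsed["pam"] == "nspam":
        circ = apply_nonselective_pam(circ)
    return circ
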