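"""Pre-synaptic bouton dynamics.

The bouton is described by Tsodyks-Markram-style trace equations: the
retrograde-messenger uptake trace (RMtrace) integrates the messenger arriving
from the post-synaptic side, the inhibitory complex (Inh) is produced from
RMtrace jointly with the spike-activity trace C, the neurotransmitter trace D
jumps at release events, and the synaptic weight omega grows with the product
Prel*C*D (its rate of change is the synaptic efficacy).  The transmitted
synaptic current is an alpha-function superposition, realized either in closed
form (the analytic oracle) or as the pair of coupled linear ODEs Y/Z that the
fixed-step engine integrates.

Two evaluation modes exist for the inhibition probability:

``exact``
    A double-exponential sigmoid ``exp(exp(-s / (g*Inh))) - 1`` rising from 0;
    ``s`` is the printed scale constant (1e-7) and ``g`` the operating-region
    adjustment of the inhibitory-complex equilibrium point (the source model's
    threshold is impractically high and is explicitly adjusted so impulse
    effects are visible).  ``g`` is calibrated so the exact curve crosses the
    rectangular hyperbola tangentially (equal value and slope) at the
    default operating concentration Inh = 1.433e-4, the region of operation
    where the hyperbola most closely resembles the curve.
``approx``
    The rectangular hyperbola ``-7e-5/(Inh - 1e-5) + 1.1`` used by the
    hardware-faithful linearized mode.

Both raw forms can leave [0, 1] (the hyperbola is negative just above its
zero, and both exceed 1 at large Inh); since they are used as probabilities
they are clamped, and the engine counts clamping events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PreSynParams",
    "PreSynState",
    "hebbian_delta",
    "p_inh",
    "p_rel",
    "presyn_derivs",
    "syn_current_closed",
]


@dataclass(frozen=True)
class PreSynParams:
    """Time constants, thresholds and approximation constants of the bouton.

    All time constants are in seconds.  ``P_init`` is the initial
    neurotransmitter release probability (0.5 describes the low-pass
    glutamatergic synapse).  ``RM_rest`` is the RMtrace threshold whose
    crossing marks the post-synaptic side as active for the Hebbian rule.
    """

    tau_r: float = 0.1          # RM influx trace
    tau_inh: float = 1.0        # inhibitory complex
    tau_c: float = 0.1          # spike-activity trace
    tau_d: float = 0.1          # neurotransmitter trace
    tau_syn: float = 0.05       # alpha-current kernel
    P_init: float = 0.5
    RM_rest: float = 1e-4
    pinh_scale: float = 1e-7    # printed scale constant of the exact form
    inh_operating_gain: float = 8.8414e-4  # equilibrium-point adjustment, see module docstring
    approx_num: float = 7e-5    # rectangular-hyperbola numerator
    approx_off: float = 1e-5    # rectangular-hyperbola offset
    approx_base: float = 1.1    # rectangular-hyperbola asymptote
    nmdar_gain: float = 1.0     # weight-stage gain (scaled by the Shank/Neuroglin scenario)

    def __post_init__(self):
        for name in ("tau_r", "tau_inh", "tau_c", "tau_d", "tau_syn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.P_init <= 1.0:
            raise ValueError(f"P_init must be in [0, 1], got {self.P_init}")
        for name in ("pinh_scale", "inh_operating_gain", "approx_num", "approx_off",
                     "approx_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def replace(self, **kw) -> "PreSynParams":
        return replace(self, **kw)


@dataclass
class PreSynState:
    """State variables of the pre-synaptic region (all model units)."""

    RMtrace: float = 0.0
    Inh: float = 0.0
    C: float = 0.0
    D: float = 0.0
    omega: float = 0.0
    Y: float = 0.0
    Z: float = 0.0
    Pinh: float = 0.0
    Prel: float = 0.0
    Isyn: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.RMtrace, self.Inh, self.C, self.D, self.omega, self.Y, self.Z]
        )


def hebbian_delta(pre_active: int, post_active: int) -> int:
    """Anti-symmetric Hebbian plasticity increment.

    Potentiation (+1) when pre- and post-synaptic sides are co-active,
    depression (-1) when exactly one side is active, nothing (0) otherwise.
    ``post_active`` is the indicator ``RMtrace > RM_rest``.
    """
    if pre_active not in (0, 1):
        raise ValueError(f"pre_active must be 0 or 1, got {pre_active!r}")
    if post_active not in (0, 1):
        raise ValueError(f"post_active must be 0 or 1, got {post_active!r}")
    if pre_active and post_active:
        return 1
    if pre_active or post_active:
        return -1
    return 0


def _clamp01(x):
    return np.clip(x, 0.0, 1.0)


def p_inh(Inh, mode: str = "exact", params: PreSynParams | None = None):
    """Probability of inhibition of neurotransmitter release.

    Monotone non-decreasing in the inhibitory-complex concentration over the
    operating region; the raw value is clamped to [0, 1].  Accepts scalars or
    arrays.
    """
    params = params or PreSynParams()
    Inh = np.asarray(Inh, dtype=float)
    if np.any(Inh < 0):
        raise ValueError("Inh must be >= 0")
    if mode == "exact":
        scaled = params.inh_operating_gain * Inh
        with np.errstate(divide="ignore"):
            inner = np.where(scaled > 0, -params.pinh_scale / np.where(scaled > 0, scaled, 1.0), -np.inf)
        raw = np.expm1(np.exp(inner))
    elif mode == "approx":
        denom = Inh - params.approx_off
        with np.errstate(divide="ignore"):
            raw = np.where(
                denom != 0,
                -params.approx_num / np.where(denom != 0, denom, 1.0) + params.approx_base,
                np.inf,
            )
        # below the offset the hyperbola branch is above its asymptote -> clamps to 1
    else:
        raise ValueError(f"unknown p_inh mode {mode!r}")
    out = _clamp01(raw)
    return float(out) if out.ndim == 0 else out


def p_rel(params: PreSynParams, Pinh) -> float:
    """Release probability ``P_init * (1 - Pinh)``, in [0, P_init]."""
    Pinh = np.asarray(Pinh, dtype=float)
    if np.any((Pinh < 0) | (Pinh > 1)):
        raise ValueError("Pinh must be in [0, 1]")
    out = params.P_init * (1.0 - Pinh)
    return float(out) if out.ndim == 0 else out


def presyn_derivs(
    state: PreSynState,
    params: PreSynParams,
    RM: float,
    spike_now: int = 0,
    mode: str = "exact",
):
    """Continuous derivatives of the bouton state plus spike-jump updates.

    Returns ``(derivs, jumps)`` where ``derivs`` is a PreSynState of d/dt
    values and ``jumps`` a dict of increments to apply when ``spike_now`` is 1
    (C by the Hebbian delta, D and Z by one).  The trace equations are linear,
    so exact and linearized modes share them; the mode selects the inhibition
    probability entering d(omega)/dt.
    """
    if RM < 0:
        raise ValueError("RM must be >= 0")
    for name in ("RMtrace", "Inh", "C", "D", "omega", "Y", "Z"):
        if not math.isfinite(getattr(state, name)):
            raise FloatingPointError(f"non-finite pre-synaptic state variable {name}")
    pin = p_inh(state.Inh, "approx" if mode == "linearized" else "exact", params)
    prel = p_rel(params, pin)
    derivs = PreSynState(
        RMtrace=-state.RMtrace / params.tau_r + RM,
        Inh=-state.Inh / params.tau_inh + state.RMtrace * state.C,
        C=-state.C / params.tau_c,
        D=-state.D / params.tau_d,
        omega=params.nmdar_gain * prel * state.C * state.D,
        Y=(state.Z - state.Y) / params.tau_syn,
        Z=-state.Z / params.tau_syn,
        Pinh=pin,
        Prel=prel,
        Isyn=state.omega * state.Y,
    )
    jumps = {}
    if spike_now:
        post_active = 1 if state.RMtrace > params.RM_rest else 0
        jumps = {"C": float(hebbian_delta(1, post_active)), "D": 1.0, "Z": 1.0}
    return derivs, jumps


def syn_current_closed(t, spikes, omega: float, tau_syn: float):
    """Closed-form synaptic current: alpha-function superposition.

    ``omega * sum_k s_k * exp(-s_k)`` with ``s_k = (t - t_k)/tau_syn`` over
    past spikes.  Serves as the analytic oracle for the Y/Z differential form.
    Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    times = spikes.times if hasattr(spikes, "times") else np.asarray(spikes, float)
    s = (t[..., None] - times[None, ...]) / tau_syn
    contrib = np.where(s > 0, s * np.exp(-np.where(s > 0, s, 0.0)), 0.0)
    out = omega * contrib.sum(axis=-1)
    return float(out) if out.ndim == 0 else out
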