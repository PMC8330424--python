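"""Post-synaptic dendrite dynamics.

Cytoplasmic calcium Cc exchanges with the endoplasmic-reticulum store Ce
through the two-variable flux f(Cc, Ce), receives external influx
``r + alpha*(Wpost - Wpost_rest) + beta*Sm`` and a mitochondrial contribution
``k_mito * dm/dt``.  The IP3-like secondary mediator Sm is gated by the
synaptic current through a tanh threshold at I_Sm, the membrane is a
FitzHugh-Nagumo pair (Vpost, Wpost), and the retrograde-messenger output RM
is a decreasing function of Cc (clamped to [0, 1]).

Full mode uses the nonlinear forms; linearized mode (the hardware-faithful
realization) sets f = 0 and Ce = 0, replaces the mitochondrial Michaelis-
Menten terms by their printed series, the tanh gate by a cubic polynomial in
the gate variable ks (clipped to a configurable range where the cubic tracks
tanh), the FHN cubic by a piecewise-linear surrogate, and the RM exponential
by its third-order series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PostSynParams",
    "PostSynState",
    "f_cc_ce",
    "rm_concentration",
    "sm_gain",
    "fhn_nonlinearity",
    "postsyn_derivs",
]


@dataclass(frozen=True)
class PostSynParams:
    """Control constants of the post-synaptic region.

    Units: time constants in seconds; concentrations and currents in model
    units.  ``Wpost_rest=None`` means "the quiescent recovery value of the
    configured membrane at zero synaptic current", resolved by the engine so
    the calcium influx coupling vanishes at rest.
    """

    tau_cc: float = 1.0
    tau_ce: float = 1.0
    tau_sm: float = 0.5
    c1: float = 1.0
    c2: float = 1.0
    c3: float = 0.05
    c4: float = 0.1             # coupling of f(Cc, Ce) into the Cc equation
    r: float = 0.1              # baseline calcium influx
    alpha: float = 0.05         # coupling to (Wpost - Wpost_rest)
    beta: float = 0.5           # coupling to Sm
    k_mito: float = 0.05        # coupling of dm/dt into the Cc equation
    v1max: float = 0.5
    v2max: float = 0.2
    Kd: float = 1.0             # calcium half-saturation
    K_Na: float = 1.0           # sodium half-saturation
    Na_conc: float = 1.0
    S_Sm: float = 4.0           # mediator gate gain
    I_Sm: float = 0.05          # mediator activation threshold on Isyn
    d_Sm: float = 0.5           # mediator decay
    rm_k1: float = 2.0447       # RM exponent constant
    rm_k2: float = 9.1799e-12   # RM scale constant
    Wpost_rest: float | None = None
    Ipost: float = 1.05         # membrane bias current
    tau_v: float = 0.01         # membrane time constant (1.0 = dimensionless form)
    tau_w: float = 0.04         # recovery time constant (1.0 = dimensionless form)
    ks_clip: float = 1.5        # gate-variable clip range for the cubic surrogate
    cc_floor: float = 1e-6      # guard for the Ce equation's division by Cc
    sm_poly: str = "printed"    # "printed": 1+ks-ks^3; "canonical": 1+ks-ks^3/3
    fhn_surrogate: str = "product"  # "product": V*(1-|V|/2); "printed": 1-|V|/2
    rm_decreasing: bool = True  # direction flag for the RM(Cc) curve

    def __post_init__(self):
        for name in ("tau_cc", "tau_ce", "tau_sm", "tau_v", "tau_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.rm_k2 < 0:
            raise ValueError("rm_k2 must be >= 0")
        for name in ("Kd", "K_Na"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sm_poly not in ("printed", "canonical"):
            raise ValueError(f"unknown sm_poly {self.sm_poly!r}")
        if self.fhn_surrogate not in ("product", "printed"):
            raise ValueError(f"unknown fhn_surrogate {self.fhn_surrogate!r}")

    def replace(self, **kw) -> "PostSynParams":
        return replace(self, **kw)

    # sodium activation of the mitochondrial exchanger is constant in time
    @property
    def k_na(self) -> float:
        na2 = self.Na_conc**2
        return na2 / (self.K_Na**2 + na2)

    def quiescent_membrane(self, mode: str = "full") -> tuple[float, float]:
        """Fixed point (Vpost, Wpost) of the membrane at zero synaptic current."""
        v = -self.Ipost
        return v, fhn_nonlinearity(v, self, mode)


@dataclass
class PostSynState:
    """State variables of the post-synaptic region."""

    Cc: float = 0.0
    Ce: float = 0.0
    m: float = 0.0
    Sm: float = 0.0
    Vpost: float = 0.0
    Wpost: float = 0.0
    RM: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.Cc, self.Ce, self.m, self.Sm, self.Vpost, self.Wpost])


def f_cc_ce(Cc, Ce, params: PostSynParams | None = None):
    """Cytoplasm/ER calcium exchange flux.

    ``c1*(Cc^2/(1+Cc^2) - Ce^2/(1+Ce^2))*(Cc^4/(c2^4+Cc^4)) - c3*Ce``
    """
    params = params or PostSynParams()
    Cc = np.asarray(Cc, dtype=float)
    Ce = np.asarray(Ce, dtype=float)
    if np.any(Cc < 0) or np.any(Ce < 0):
        raise ValueError("concentrations must be >= 0")
    sat = Cc**2 / (1.0 + Cc**2) - Ce**2 / (1.0 + Ce**2)
    gate = Cc**4 / (params.c2**4 + Cc**4)
    out = params.c1 * sat * gate - params.c3 * Ce
    return float(out) if out.ndim == 0 else out


def rm_concentration(Cc, mode: str = "exact", params: PostSynParams | None = None):
    """Retrograde-messenger output as a function of cytoplasmic calcium.

    ``poly`` mode evaluates the third-order series ``1 - x + x^2/2 - x^3/6``
    with ``x = rm_k2 * Cc**rm_k1``; ``exact`` mode evaluates the exponential
    ``exp(-x)`` that the series truncates.  Both are clamped to [0, 1].  With
    ``rm_decreasing=False`` the direction is flipped (``1 - RM``), exposing
    the biologically-increasing alternative without changing the default.
    """
    params = params or PostSynParams()
    Cc = np.asarray(Cc, dtype=float)
    if np.any(Cc < 0):
        raise ValueError("Cc must be >= 0")
    x = params.rm_k2 * Cc**params.rm_k1
    if mode == "poly":
        raw = 1.0 - x + x**2 / 2.0 - x**3 / 6.0
    elif mode == "exact":
        raw = np.exp(-x)
    else:
        raise ValueError(f"unknown rm_concentration mode {mode!r}")
    out = np.clip(raw, 0.0, 1.0)
    if not params.rm_decreasing:
        out = 1.0 - out
    return float(out) if out.ndim == 0 else out


def sm_gain(ks, params: PostSynParams | None = None, mode: str = "full"):
    """Mediator production gate ``1 + tanh(ks)`` or its cubic surrogate.

    In linearized mode ``ks`` is clipped to ``[-ks_clip, ks_clip]`` (the cubic
    diverges from tanh outside) and the polynomial value is floored at 0 so
    the gate can switch off.  Returns ``(gain, clipped)`` where ``clipped``
    is the count of clipped samples.
    """
    params = params or PostSynParams()
    ks = np.asarray(ks, dtype=float)
    if mode == "full":
        out = 1.0 + np.tanh(ks)
        clipped = 0
    else:
        kc = np.clip(ks, -params.ks_clip, params.ks_clip)
        clipped = int(np.sum(kc != ks))
        if params.sm_poly == "printed":
            out = 1.0 + kc - kc**3
        else:
            out = 1.0 + kc - kc**3 / 3.0
        out = np.maximum(out, 0.0)
    return (float(out) if out.ndim == 0 else out), clipped


def fhn_nonlinearity(V, params: PostSynParams | None = None, mode: str = "full"):
    """Membrane nonlinearity f(V): cubic ``V - V^3/3`` or its linearized surrogate."""
    params = params or PostSynParams()
    V = np.asarray(V, dtype=float)
    if mode == "full":
        out = V - V**3 / 3.0
    elif params.fhn_surrogate == "product":
        out = V * (1.0 - np.abs(V) / 2.0)
    else:  # verbatim printed surrogate
        out = 1.0 - np.abs(V) / 2.0
    return float(out) if out.ndim == 0 else out


def _dm_dt(Cc: float, m: float, params: PostSynParams, mode: str) -> float:
    if mode == "full":
        uptake = params.v1max * Cc**2 / (params.Kd**2 + Cc**2)
        release = params.v2max * params.k_na * m / (1.0 + m)
    else:
        u = Cc**2 / params.Kd**2
        uptake = params.v1max * u * (1.0 - u + u**2)
        release = params.v2max * params.k_na * (1.0 - m + m**2) * m
    return uptake - release


def postsyn_derivs(
    state: PostSynState,
    params: PostSynParams,
    Isyn: float,
    mode: str = "full",
    overrides: dict | None = None,
):
    """Time derivatives of the post-synaptic state.

    ``overrides`` carries scenario modifications: ``ism_scale`` (activation-
    threshold multiplier), ``sm_gain_scale`` (production-gain multiplier) and
    ``sm_production_factor`` (inhibitory multiplier on the production term).
    Returns ``(derivs, info)`` where ``info`` reports clipped gate samples.
    """
    for name in ("Cc", "Ce", "m", "Sm", "Vpost", "Wpost"):
        if not math.isfinite(getattr(state, name)):
            raise FloatingPointError(f"non-finite post-synaptic state variable {name}")
    ov = overrides or {}
    ism = params.I_Sm * ov.get("ism_scale", 1.0)
    gain_scale = ov.get("sm_gain_scale", 1.0)
    prod_factor = ov.get("sm_production_factor", 1.0)

    w_rest = params.Wpost_rest
    if w_rest is None:
        w_rest = params.quiescent_membrane(mode)[1]

    dm = _dm_dt(state.Cc, state.m, params, mode)
    influx = params.r + params.alpha * (state.Wpost - w_rest) + params.beta * state.Sm

    if mode == "full":
        f = f_cc_ce(max(state.Cc, 0.0), max(state.Ce, 0.0), params)
        dCc = (-state.Cc - params.c4 * f + influx + params.k_mito * dm) / params.tau_cc
        dCe = f / (params.tau_ce * max(state.Cc, params.cc_floor))
    else:
        # linearized: f(Cc, Ce) = 0 and Ce = 0 identically
        dCc = (-state.Cc + influx + params.k_mito * dm) / params.tau_cc
        dCe = 0.0

    ks = params.S_Sm * (Isyn - ism)
    g, clipped = sm_gain(ks, params, mode)
    g = g * gain_scale * prod_factor
    dSm = (g * (1.0 - state.Sm) - state.Sm * params.d_Sm) / params.tau_sm

    dV = (fhn_nonlinearity(state.Vpost, params, mode) - state.Wpost) / params.tau_v
    dW = (state.Vpost + params.Ipost - Isyn) / params.tau_w

    derivs = PostSynState(Cc=dCc, Ce=dCe, m=dm, Sm=dSm, Vpost=dV, Wpost=dW, RM=0.0)
    return derivs, {"ks_clipped": clipped}
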