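"""ASD synaptopathy mechanisms as composable modifiers of the healthy synapse.

Five mechanisms are implemented, each a perturbation of one stage of the
healthy model, each with a seeded noise source attached to its
noise-carrying parameter:

``fxs``
    Loss of FMRP-mediated suppression of mGluR5: an influx accumulator
    integrates ``d(influx)/dt = -k_fmrp(t) * k_t * Isyn`` (the sign of
    ``k_fmrp`` is configurable) and adds onto the synaptic current entering
    the post-synaptic region.  ``k_fmrp`` carries the noise.
``tsc_nam`` / ``tsc_pam``
    Allosteric modulation of mGluR5 in tuberous sclerosis.  The receptor rate
    follows the unstable equilibrium construct ``dk/dt = +k -+ k_nam/pam``
    (capped at saturation bounds); its ratio to baseline scales both the
    mediator activation threshold and the output/mediator gain.  Under NAM
    the ratio falls: the activation threshold drops faster than the
    amplitude, giving the high-frequency, lower-amplitude phenotype (more
    supra-threshold events, smaller peaks).  Under PAM the ratio rises:
    higher amplitude and a stronger low-pass.  ``k_mGluR5(t)`` carries the
    noise, entering through its rate of change.
``dcycloserine``
    Competitive NMDAR channel dynamics: an auxiliary current ``x`` follows
    ``dx/dt = (Isyn + x)*k_glutamate - N(t)*k_dcs + 1/k_adjust`` (capped),
    modified current ``Isyn + x``.  The D-cycloserine concentration ``N``
    carries the noise (D-cycloserine is not an activated pathway, which makes
    it the system's noise source).
``shank_ng``
    Scaffold/adhesion composite: pointwise current scaling
    ``Isyn * k_shank * k_neuroglin * k_adjust`` plus an NMDAR gain on the
    synaptic-weight stage.  ``k_shank`` carries the noise.
``chr15``
    Chromosome-15 inhibitory receptor action on the mediator: the Sm
    production term is multiplied by ``1/(1 + k_chr15(t))``.  ``k_chr15``
    carries the noise.

``mechanism="none"`` and any mechanism with neutral parameters and zero noise
amplitude are strict no-ops: the engine's traces are bit-identical to the
healthy run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .stimulus import NoiseSeries, noise_series

__all__ = [
    "MECHANISMS",
    "ScenarioSpec",
    "ScenarioState",
    "apply_fxs",
    "apply_tsc",
    "apply_dcycloserine",
    "apply_shank_ng",
    "apply_chr15",
]

MECHANISMS = ("none", "fxs", "tsc_nam", "tsc_pam", "dcycloserine", "shank_ng", "chr15")


@dataclass(frozen=True)
class ScenarioSpec:
    """Which mechanism is active, its rate constants, and its noise source."""

    mechanism: str = "none"
    # FXS
    k_fmrp: float = 0.5
    k_t: float = 1.0
    # TSC
    k_mGluR5: float = 1.0
    k_nam: float = 1.5
    k_pam: float = 0.5
    tsc_threshold_coupling: float = 1.0   # how strongly k(t)/k0 scales I_Sm
    tsc_gain_coupling: float = 0.25       # how strongly k(t)/k0 scales output/Sm gain
    tsc_k_min_frac: float = 0.25          # saturation bounds on k(t), as fractions of k0
    tsc_k_max_frac: float = 4.0
    nam_amplitude_cap: float = math.inf   # optional hard ceiling on the NAM output
    # D-cycloserine
    k_glutamate: float = 0.3
    k_dcs: float = 1.0
    N_conc: float = 1.0
    k_adjust: float = 1.0                 # N*k_dcs = 1/k_adjust: passive state is an equilibrium
    dcs_cap: float = 5.0                  # |x| saturation of the competitive channel
    # Shank / Neuroglin
    k_shank: float = 1.2
    k_neuroglin: float = 1.25
    k_adjust_sh: float = 1.0
    k_nmdar: float = 1.5
    # Chromosome 15
    k_chr15: float = 1.0
    # noise attached to the mechanism's noise-carrying parameter
    noise_sigma: float = 0.0
    noise_seed: int = 0
    noise_distribution: str = "gaussian"

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism in ("tsc_nam", "tsc_pam"):
            if not (self.k_nam > self.k_mGluR5 > self.k_pam):
                raise ValueError(
                    "TSC rate ordering violated: the equilibrium construct "
                    "requires k_nam > k_mGluR5 > k_pam, got "
                    f"k_nam={self.k_nam}, k_mGluR5={self.k_mGluR5}, k_pam={self.k_pam}"
                )
        if self.mechanism == "dcycloserine" and self.k_adjust == 0:
            raise ValueError("k_adjust must be nonzero (1/k_adjust source term)")
        if self.k_chr15 < 0:
            raise ValueError("k_chr15 base must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("k_mGluR5", "k_nam", "k_pam", "k_shank", "k_neuroglin",
                     "k_adjust_sh", "k_nmdar"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "ScenarioSpec":
        return replace(self, **kw)

    @property
    def is_identity(self) -> bool:
        """True when the scenario provably never alters any trace."""
        if self.mechanism == "none":
            return True
        if self.noise_sigma > 0:
            return False
        if self.mechanism == "fxs":
            return self.k_fmrp == 0.0 or self.k_t == 0.0
        if self.mechanism in ("tsc_nam", "tsc_pam"):
            return (
                self.tsc_threshold_coupling == 0.0
                and self.tsc_gain_coupling == 0.0
                and math.isinf(self.nam_amplitude_cap)
            )
        if self.mechanism == "dcycloserine":
            return (
                self.k_glutamate == 0.0
                and (self.k_dcs == 0.0 or self.N_conc == 0.0)
                and math.isinf(self.k_adjust)
            )
        if self.mechanism == "shank_ng":
            return (
                self.k_shank * self.k_neuroglin * self.k_adjust_sh == 1.0
                and self.k_nmdar == 1.0
            )
        if self.mechanism == "chr15":
            return self.k_chr15 == 0.0
        return False

    def neutral(self) -> "ScenarioSpec":
        """The identity-configured variant of this mechanism (zero noise)."""
        kw: dict = {"noise_sigma": 0.0}
        if self.mechanism == "fxs":
            kw["k_fmrp"] = 0.0
        elif self.mechanism in ("tsc_nam", "tsc_pam"):
            kw.update(tsc_threshold_coupling=0.0, tsc_gain_coupling=0.0,
                      nam_amplitude_cap=math.inf)
        elif self.mechanism == "dcycloserine":
            kw.update(k_glutamate=0.0, k_dcs=0.0, k_adjust=math.inf)
        elif self.mechanism == "shank_ng":
            kw.update(k_shank=1.0, k_neuroglin=1.0, k_adjust_sh=1.0, k_nmdar=1.0)
        elif self.mechanism == "chr15":
            kw["k_chr15"] = 0.0
        return self.replace(**kw)

    def noise(self, n: int) -> NoiseSeries:
        return noise_series(self.noise_sigma, n, self.noise_seed,
                            self.noise_distribution)


@dataclass
class ScenarioState:
    """Run-time accumulators of the active mechanism (reset at run start)."""

    influx: float = 0.0        # FXS current accumulator
    k_mGluR5_t: float = 0.0    # TSC time-varying receptor rate
    x_dcs: float = 0.0         # D-cycloserine competitive channel current
    noise_walk: float = 0.0    # integrated noise on a gain parameter (shank/chr15)
    cap_events: int = 0

    @classmethod
    def initial(cls, spec: ScenarioSpec) -> "ScenarioState":
        return cls(influx=0.0, k_mGluR5_t=spec.k_mGluR5, x_dcs=0.0,
                   noise_walk=0.0, cap_events=0)


# ---------------------------------------------------------------------------
# per-mechanism modifiers (fixed-step semantics: evaluate, then advance by dt)
# ---------------------------------------------------------------------------

def apply_fxs(Isyn: float, scen: ScenarioState, spec: ScenarioSpec,
              dt: float, noise_sample: float = 0.0) -> float:
    """Return the FXS-modified current and advance the influx accumulator."""
    if spec.mechanism != "fxs":
        raise ValueError("apply_fxs requires mechanism='fxs'")
    out = Isyn + scen.influx
    k_fmrp_t = spec.k_fmrp + noise_sample
    scen.influx += dt * (-k_fmrp_t * spec.k_t * Isyn)
    return out


def apply_tsc(spec: ScenarioSpec, mode: str, scen: ScenarioState,
              dt: float, noise_sample: float = 0.0) -> dict:
    """Advance the receptor-rate construct and return parameter overrides.

    Overrides: ``ism_scale`` multiplies the mediator activation threshold,
    ``gain`` multiplies the output current and mediator production,
    ``amplitude_cap`` caps the output current (NAM only).
    """
    if mode not in ("nam", "pam"):
        raise ValueError(f"TSC mode must be 'nam' or 'pam', got {mode!r}")
    if spec.mechanism != f"tsc_{mode}":
        raise ValueError(f"apply_tsc mode {mode!r} requires mechanism 'tsc_{mode}'")
    lo = spec.tsc_k_min_frac * spec.k_mGluR5
    hi = spec.tsc_k_max_frac * spec.k_mGluR5
    # unstable linear growth as printed, with the molecular noise entering the
    # rate dynamics; trajectories saturate at the caps (events counted)
    dk = scen.k_mGluR5_t - (spec.k_nam if mode == "nam" else -spec.k_pam)
    k_new = scen.k_mGluR5_t + dt * (dk + noise_sample)
    if k_new < lo or k_new > hi:
        scen.cap_events += 1
        k_new = min(max(k_new, lo), hi)
    scen.k_mGluR5_t = k_new
    rho = k_new / spec.k_mGluR5
    ism_scale = max(1.0 + spec.tsc_threshold_coupling * (rho - 1.0),
                    spec.tsc_k_min_frac)
    gain = max(1.0 + spec.tsc_gain_coupling * (rho - 1.0), 0.0)
    cap = spec.nam_amplitude_cap if mode == "nam" else math.inf
    return {"ism_scale": ism_scale, "gain": gain, "amplitude_cap": cap}


def apply_dcycloserine(Isyn: float, spec: ScenarioSpec, scen: ScenarioState,
                       dt: float, noise_sample: float = 0.0) -> float:
    """Return the competition-modified current and advance the channel state."""
    if spec.mechanism != "dcycloserine":
        raise ValueError("apply_dcycloserine requires mechanism='dcycloserine'")
    out = Isyn + scen.x_dcs
    N_t = spec.N_conc + noise_sample
    source = 0.0 if math.isinf(spec.k_adjust) else 1.0 / spec.k_adjust
    x_new = scen.x_dcs + dt * (
        (Isyn + scen.x_dcs) * spec.k_glutamate - N_t * spec.k_dcs + source
    )
    if abs(x_new) > spec.dcs_cap:
        scen.cap_events += 1
        x_new = math.copysign(spec.dcs_cap, x_new)
    scen.x_dcs = x_new
    return out


def apply_shank_ng(Isyn: float, spec: ScenarioSpec,
                   noise_sample: float = 0.0) -> float:
    """Pointwise current scaling by the Shank/Neuroglin/adjustment product.

    ``noise_sample`` is the integrated (random-walk) perturbation of
    ``k_shank``, supplied by the runtime.
    """
    if spec.mechanism != "shank_ng":
        raise ValueError("apply_shank_ng requires mechanism='shank_ng'")
    return Isyn * (max(spec.k_shank + noise_sample, 0.0) * spec.k_neuroglin
                   * spec.k_adjust_sh)


def apply_chr15(spec: ScenarioSpec, dt: float, noise_sample: float = 0.0) -> dict:
    """Inhibitory multiplier on the mediator production term.

    ``noise_sample`` is the integrated (random-walk) perturbation of
    ``k_chr15``, supplied by the runtime.
    """
    if spec.mechanism != "chr15":
        raise ValueError("apply_chr15 requires mechanism='chr15'")
    k_t = max(spec.k_chr15 + noise_sample, 0.0)
    return {"sm_production_factor": 1.0 / (1.0 + k_t)}


class ScenarioRuntime:
    """Stateful per-run driver composing the mechanism modifiers.

    The engine calls :meth:`modify` once per step with the pre-synaptic
    current; the runtime returns the current entering the post-synaptic
    region plus the mediator-stage overrides, and advances its internal
    state by ``dt``.  For identity scenarios every call is a strict no-op.
    """

    def __init__(self, spec: ScenarioSpec, n_steps: int, dt: float):
        self.spec = spec
        self.dt = dt
        self.state = ScenarioState.initial(spec)
        self.active = not spec.is_identity
        if self.active and spec.noise_sigma > 0:
            self.noise = spec.noise(n_steps + 1).values
        else:
            self.noise = np.zeros(n_steps + 1)

    @property
    def weight_gain(self) -> float:
        """Gain applied to the synaptic-weight stage (Shank/Neuroglin only)."""
        if self.active and self.spec.mechanism == "shank_ng":
            return self.spec.k_nmdar
        return 1.0

    def modify(self, Isyn: float, i: int) -> tuple[float, dict]:
        if not self.active:
            return Isyn, {}
        spec, st, dt = self.spec, self.state, self.dt
        nz = self.noise[i]
        if spec.mechanism == "fxs":
            return apply_fxs(Isyn, st, spec, dt, nz), {}
        if spec.mechanism in ("tsc_nam", "tsc_pam"):
            ov = apply_tsc(spec, spec.mechanism[4:], st, dt, nz)
            out = min(Isyn, ov["amplitude_cap"]) * ov["gain"]
            return out, {"ism_scale": ov["ism_scale"],
                         "sm_gain_scale": ov["gain"]}
        if spec.mechanism == "dcycloserine":
            return apply_dcycloserine(Isyn, spec, st, dt, nz), {}
        if spec.mechanism == "shank_ng":
            st.noise_walk += dt * nz
            return apply_shank_ng(Isyn, spec, st.noise_walk), {}
        if spec.mechanism == "chr15":
            st.noise_walk += dt * nz
            return Isyn, apply_chr15(spec, dt, st.noise_walk)
        return Isyn, {}
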