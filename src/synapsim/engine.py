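"""Coupled pre/post synapse integration in two faithful modes.

``reference``
    Continuous-time integration of the full nonlinear equations with
    scipy's adaptive solver, spike jumps applied at exact event times and
    retrograde-messenger feedback without artificial delay.  This is the
    mathematical ideal against which the hardware-faithful mode is judged.

``discretized``
    Fixed-step forward Euler on the linearized equations — the scheme a
    one-update-per-clock datapath realizes.  The step ``delta`` maps one
    hardware clock cycle onto simulated time.  Spikes are binned onto the
    step grid (binary ``u[n]``), the messenger is fed back through a delay
    line of ``feedback_delay_steps`` cycles, the synaptic weight starts at 0
    and the initialization window is flagged for rejection (values are
    stored untouched; only the mask marks them), and every state store can
    be quantized to IEEE-754 binary32.

Both modes are deterministic: identical configuration (including seeds)
reproduces the TraceSet bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import presynaptic as pre
from . import postsynaptic as post
from .presynaptic import PreSynParams
from .postsynaptic import PostSynParams
from .scenarios import ScenarioSpec, ScenarioRuntime
from .stimulus import SpikeTrain

__all__ = [
    "EngineConfig",
    "TraceSet",
    "IntegrationError",
    "quantize",
    "simulate",
    "simulate_reference",
    "simulate_discretized",
]

#: state-variable series stored by both engines, in storage order
STATE_KEYS = (
    "RMtrace", "Inh", "C", "D", "omega", "Y", "Z",
    "Cc", "Ce", "m", "Sm", "Vpost", "Wpost",
)
DERIVED_KEYS = ("Pinh", "Prel", "Isyn_in", "Isyn_eff", "I_Sm_eff", "RM", "RM_in")

#: the series the distortion metrics and fidelity comparisons are computed on
OUTPUT_KEY = "Isyn_eff"


class IntegrationError(RuntimeError):
    """Raised when a state variable leaves the finite range during a run."""


@dataclass(frozen=True)
class EngineConfig:
    """Integration configuration shared by both engine modes.

    ``delta`` is the fixed step of the discretized mode (seconds per clock
    cycle).  ``dt`` is the output sampling step of the reference mode and
    defaults to ``delta`` so the two modes share a grid.  ``warmup_samples``
    defaults to the samples covering the 0.031 s initialization latency at
    the configured ``delta``.
    """

    mode: str = "discretized"
    delta: float = 1e-4
    dt: float | None = None
    horizon: float = 10.0
    feedback_delay_steps: int = 25
    warmup_samples: int | None = None
    precision: str = "double"
    seed: int = 0
    rm_mode: str = "constant"      # "constant": external drive; "feedback": RM(Cc) loop
    rm_value: float = 1.433e-3
    equations: str = "auto"        # auto -> exact (reference) / linearized (discretized)
    init: str = "equilibrium"      # or "rest"
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-11
    solver_max_step: float = math.inf

    def __post_init__(self):
        if self.mode not in ("reference", "discretized"):
            raise ValueError(f"unknown engine mode {self.mode!r}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.feedback_delay_steps < 0:
            raise ValueError("feedback_delay_steps must be >= 0")
        if self.warmup_samples is not None and self.warmup_samples < 0:
            raise ValueError("warmup_samples must be >= 0")
        if self.precision not in ("double", "single"):
            raise ValueError(f"unknown precision {self.precision!r}")
        if self.rm_mode not in ("constant", "feedback"):
            raise ValueError(f"unknown rm_mode {self.rm_mode!r}")
        if self.equations not in ("auto", "exact", "linearized"):
            raise ValueError(f"unknown equations setting {self.equations!r}")
        if self.init not in ("equilibrium", "rest"):
            raise ValueError(f"unknown init mode {self.init!r}")

    def replace(self, **kw) -> "EngineConfig":
        return replace(self, **kw)

    @property
    def sample_step(self) -> float:
        return self.delta if self.dt is None else self.dt

    @property
    def resolved_warmup(self) -> int:
        if self.warmup_samples is not None:
            return self.warmup_samples
        return int(round(0.031 / self.sample_step))

    def resolved_equations(self) -> str:
        if self.equations != "auto":
            return self.equations
        return "exact" if self.mode == "reference" else "linearized"


@dataclass
class TraceSet:
    """Sampled time series of every state variable plus run metadata.

    The metadata embeds the fully resolved configuration, so any TraceSet can
    be re-run bit-identically from its own snapshot.  The warm-up mask flags
    rejected initialization samples without altering stored values.
    """

    time: np.ndarray
    series: dict
    metadata: dict

    def __post_init__(self):
        n = self.time.size
        for key, val in self.series.items():
            if np.asarray(val).size != n:
                raise ValueError(f"series {key!r} length mismatch with time grid")

    @property
    def warmup_mask(self) -> np.ndarray:
        mask = np.zeros(self.time.size, dtype=bool)
        mask[: int(self.metadata.get("warmup_samples", 0))] = True
        return mask

    def output(self, after_warmup: bool = False) -> np.ndarray:
        """The synaptic output potential series."""
        key = self.metadata.get("output_key", OUTPUT_KEY)
        s = np.asarray(self.series[key])
        return s[~self.warmup_mask] if after_warmup else s

    def to_frame(self):
        import pandas as pd

        data = {"time": self.time}
        data.update({k: np.asarray(v) for k, v in self.series.items()})
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "time": self.time.tolist(),
            "series": {k: np.asarray(v).tolist() for k, v in self.series.items()},
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TraceSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            time=np.asarray(d["time"], dtype=float),
            series={k: np.asarray(v, dtype=float) for k, v in d["series"].items()},
            metadata=d["metadata"],
        )


def quantize(value, precision: str = "double"):
    """Round a value to the configured storage precision.

    ``double`` is the identity; ``single`` rounds to the nearest IEEE-754
    binary32 value (24-bit significand, round-to-nearest-even).  Overflow to
    infinity is propagated and caught by the engine.
    """
    if precision == "double":
        return value
    if precision != "single":
        raise ValueError(f"unknown precision {precision!r}")
    out = np.float32(value).astype(float) if isinstance(value, np.ndarray) else float(np.float32(value))
    return out


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def _sm_equilibrium(pp: PostSynParams, isyn: float, lin: bool) -> float:
    ks = pp.S_Sm * (isyn - pp.I_Sm)
    g, _ = post.sm_gain(ks, pp, "linearized" if lin else "full")
    return g / (g + pp.d_Sm) if (g + pp.d_Sm) > 0 else 0.0


def _m_equilibrium(pp: PostSynParams, cc: float, lin: bool) -> float:
    def dm(m):
        return post._dm_dt(cc, m, pp, "linearized" if lin else "full")

    if dm(0.0) <= 0:
        return 0.0
    hi = 1.0
    while dm(hi) > 0 and hi < 1e6:
        hi *= 2.0
    return brentq(dm, 0.0, hi) if dm(hi) <= 0 else hi


def _ce_equilibrium(pp: PostSynParams, cc: float) -> float:
    if cc <= 0:
        return 0.0

    def f(ce):
        return post.f_cc_ce(cc, ce, pp)

    if f(0.0) <= 0:
        return 0.0
    hi = 1.0
    while f(hi) > 0 and hi < 1e6:
        hi *= 2.0
    return brentq(f, 0.0, hi) if f(hi) <= 0 else hi


def _initial_state(
    prp: PreSynParams,
    pp: PostSynParams,
    config: EngineConfig,
    stimulus: SpikeTrain,
    lin: bool,
) -> np.ndarray:
    """Initial 13-vector in STATE_KEYS order.

    ``equilibrium`` starts the run at the stabilized operating point of the
    constant-drive system (omega always starts at 0, per the warm-up rule);
    ``rest`` zeroes every trace and puts the membrane at its quiescent fixed
    point.
    """
    mode = "linearized" if lin else "full"
    v0, w0 = pp.quiescent_membrane(mode)
    y = np.zeros(len(STATE_KEYS))
    idx = {k: i for i, k in enumerate(STATE_KEYS)}
    y[idx["Vpost"]] = v0
    y[idx["Wpost"]] = w0
    if config.init == "rest":
        return y
    # post-synaptic quiescent point at zero synaptic current (f = 0, dm = 0)
    sm0 = _sm_equilibrium(pp, 0.0, lin)
    cc0 = pp.r + pp.beta * sm0
    y[idx["Sm"]] = sm0
    y[idx["Cc"]] = cc0
    y[idx["m"]] = _m_equilibrium(pp, cc0, lin)
    y[idx["Ce"]] = 0.0 if lin else _ce_equilibrium(pp, cc0)
    # pre-synaptic quasi-steady point under constant drive and the mean
    # spike-driven trace levels
    if config.rm_mode == "constant":
        rm0 = config.rm_value
    else:
        rm_mode = "poly" if lin else "exact"
        rm0 = post.rm_concentration(cc0, rm_mode, pp)
    rate = len(stimulus) / stimulus.horizon if stimulus.horizon > 0 else 0.0
    rmtrace0 = prp.tau_r * rm0
    cbar = rate * prp.tau_c if rmtrace0 > prp.RM_rest else 0.0
    y[idx["RMtrace"]] = rmtrace0
    y[idx["C"]] = cbar
    y[idx["D"]] = rate * prp.tau_d
    y[idx["Inh"]] = prp.tau_inh * rmtrace0 * cbar
    # omega, Y, Z start at zero: the weight is pinned to 0 at initialization
    return y


# ---------------------------------------------------------------------------
# discretized (hardware-faithful) engine
# ---------------------------------------------------------------------------

def _bin_spikes(stimulus: SpikeTrain, delta: float, n_steps: int):
    """Binary u[n]: a spike in [n*delta, (n+1)*delta) sets u[n] = 1."""
    u = np.zeros(n_steps, dtype=bool)
    collisions = 0
    idx = np.floor(stimulus.times / delta + 1e-12).astype(int)
    idx = idx[(idx >= 0) & (idx < n_steps)]
    for i in idx:
        if u[i]:
            collisions += 1
        u[i] = True
    return u, collisions


def simulate_discretized(
    presyn: PreSynParams,
    postsyn: PostSynParams,
    scenario: ScenarioSpec,
    stimulus: SpikeTrain,
    config: EngineConfig,
) -> TraceSet:
    """Forward-Euler fixed-step run emulating the clocked hardware datapath."""
    if config.mode != "discretized":
        raise ValueError("config.mode must be 'discretized'")
    lin = config.resolved_equations() == "linearized"
    delta = config.delta
    n = int(round(config.horizon / delta))
    u, collisions = _bin_spikes(stimulus, delta, n)
    runtime = ScenarioRuntime(scenario, n, delta)

    y = _initial_state(presyn, postsyn, config, stimulus, lin)
    (rmt, inh, c, d, om, yy, zz, cc, ce, m, sm, v, w) = y
    single = config.precision == "single"
    if single:
        f32 = np.float32
        rmt, inh, c, d, om, yy, zz, cc, ce, m, sm, v, w = (
            float(f32(x)) for x in (rmt, inh, c, d, om, yy, zz, cc, ce, m, sm, v, w)
        )

    # parameter locals (loop speed)
    tau_r, tau_inh, tau_c, tau_d, tau_syn = (
        presyn.tau_r, presyn.tau_inh, presyn.tau_c, presyn.tau_d, presyn.tau_syn)
    p_init, rm_rest = presyn.P_init, presyn.RM_rest
    a_num, a_off, a_base = presyn.approx_num, presyn.approx_off, presyn.approx_base
    pinh_scale, op_gain = presyn.pinh_scale, presyn.inh_operating_gain
    wgain = presyn.nmdar_gain * runtime.weight_gain
    pp = postsyn
    w_rest = pp.Wpost_rest
    if w_rest is None:
        w_rest = pp.quiescent_membrane("linearized" if lin else "full")[1]
    k_na = pp.k_na
    printed_poly = pp.sm_poly == "printed"
    product_fhn = pp.fhn_surrogate == "product"

    # feedback delay line (messenger produced at step j drives step j + L)
    rm_const = config.rm_mode == "constant"
    L = config.feedback_delay_steps
    if rm_const:
        rm_buffer = None
    else:
        rm_mode0 = "poly" if lin else "exact"
        rm_buffer = [post.rm_concentration(cc, rm_mode0, pp)] * max(L, 1)

    store = {k: np.empty(n + 1) for k in STATE_KEYS + DERIVED_KEYS}
    events = {"pinh_clamped": 0, "ks_clipped": 0, "spike_bin_collisions": collisions}

    for i in range(n + 1):
        # ---- evaluated quantities at sample i -------------------------
        if lin:
            denom = inh - a_off
            raw = math.inf if denom == 0 else -a_num / denom + a_base
        else:
            scaled = op_gain * inh
            raw = 0.0 if scaled <= 0 else math.expm1(math.exp(-pinh_scale / scaled))
        if raw < 0.0 or raw > 1.0:
            events["pinh_clamped"] += 1
        pinh = min(max(raw, 0.0), 1.0)
        prel = p_init * (1.0 - pinh)
        isyn = om * yy
        isyn_eff, ov = runtime.modify(isyn, i)
        ism_eff = pp.I_Sm * ov.get("ism_scale", 1.0)
        g_scale = ov.get("sm_gain_scale", 1.0) * ov.get("sm_production_factor", 1.0)
        rm_prod = post.rm_concentration(max(cc, 0.0), "poly" if lin else "exact", pp)
        if rm_const:
            rm_in = config.rm_value
        elif L == 0:
            rm_in = rm_prod
        else:
            rm_in = rm_buffer[i % L]

        st = store
        st["RMtrace"][i] = rmt; st["Inh"][i] = inh; st["C"][i] = c
        st["D"][i] = d; st["omega"][i] = om; st["Y"][i] = yy; st["Z"][i] = zz
        st["Cc"][i] = cc; st["Ce"][i] = ce; st["m"][i] = m; st["Sm"][i] = sm
        st["Vpost"][i] = v; st["Wpost"][i] = w
        st["Pinh"][i] = pinh; st["Prel"][i] = prel
        st["Isyn_in"][i] = isyn; st["Isyn_eff"][i] = isyn_eff
        st["I_Sm_eff"][i] = ism_eff; st["RM"][i] = rm_prod; st["RM_in"][i] = rm_in

        if i == n:
            break

        # ---- derivatives from the state at sample i -------------------
        d_rmt = -rmt / tau_r + rm_in
        d_inh = -inh / tau_inh + rmt * c
        d_c = -c / tau_c
        d_d = -d / tau_d
        d_om = wgain * prel * c * d
        d_y = (zz - yy) / tau_syn
        d_z = -zz / tau_syn

        if lin:
            u_cc = cc * cc / (pp.Kd * pp.Kd)
            dm = pp.v1max * u_cc * (1.0 - u_cc + u_cc * u_cc) \
                - pp.v2max * k_na * m * (1.0 - m + m * m)
            d_cc = (-cc + pp.r + pp.alpha * (w - w_rest) + pp.beta * sm
                    + pp.k_mito * dm) / pp.tau_cc
            d_ce = 0.0
            ks = pp.S_Sm * (isyn_eff - ism_eff)
            kc = ks
            if kc > pp.ks_clip:
                kc = pp.ks_clip
                events["ks_clipped"] += 1
            elif kc < -pp.ks_clip:
                kc = -pp.ks_clip
                events["ks_clipped"] += 1
            gate = 1.0 + kc - kc**3 if printed_poly else 1.0 + kc - kc**3 / 3.0
            if gate < 0.0:
                gate = 0.0
            gate *= g_scale
            d_sm = (gate * (1.0 - sm) - sm * pp.d_Sm) / pp.tau_sm
            fv = v * (1.0 - abs(v) / 2.0) if product_fhn else 1.0 - abs(v) / 2.0
        else:
            f = post.f_cc_ce(max(cc, 0.0), max(ce, 0.0), pp)
            dm = pp.v1max * cc * cc / (pp.Kd**2 + cc * cc) \
                - pp.v2max * k_na * m / (1.0 + m)
            d_cc = (-cc - pp.c4 * f + pp.r + pp.alpha * (w - w_rest)
                    + pp.beta * sm + pp.k_mito * dm) / pp.tau_cc
            d_ce = f / (pp.tau_ce * max(cc, pp.cc_floor))
            gate = (1.0 + math.tanh(pp.S_Sm * (isyn_eff - ism_eff))) * g_scale
            d_sm = (gate * (1.0 - sm) - sm * pp.d_Sm) / pp.tau_sm
            fv = v - v**3 / 3.0
        d_v = (fv - w) / pp.tau_v
        d_w = (v + pp.Ipost - isyn_eff) / pp.tau_w

        # ---- Euler update + spike jumps -------------------------------
        rmt_old = rmt
        rmt += delta * d_rmt
        inh += delta * d_inh
        c += delta * d_c
        d += delta * d_d
        om += delta * d_om
        yy += delta * d_y
        zz += delta * d_z
        cc += delta * d_cc
        ce += delta * d_ce
        m += delta * dm
        sm += delta * d_sm
        v += delta * d_v
        w += delta * d_w
        if u[i]:
            post_active = 1 if rmt_old > rm_rest else 0
            c += float(pre.hebbian_delta(1, post_active))
            d += 1.0
            zz += 1.0

        if single:
            f32 = np.float32
            vals = [rmt, inh, c, d, om, yy, zz, cc, ce, m, sm, v, w]
            for j, x in enumerate(vals):
                q = float(f32(x))
                if not math.isfinite(q):
                    raise IntegrationError(
                        f"single-precision overflow in {STATE_KEYS[j]} at step {i + 1}"
                    )
                vals[j] = q
            rmt, inh, c, d, om, yy, zz, cc, ce, m, sm, v, w = vals
        elif not (math.isfinite(om) and math.isfinite(cc) and math.isfinite(v)
                  and math.isfinite(inh)):
            for j, x in enumerate([rmt, inh, c, d, om, yy, zz, cc, ce, m, sm, v, w]):
                if not math.isfinite(x):
                    raise IntegrationError(
                        f"non-finite {STATE_KEYS[j]} at step {i + 1} "
                        f"(t = {(i + 1) * delta:.6g} s)"
                    )

        if rm_buffer is not None and L > 0:
            # the messenger produced at sample i becomes available at i + L
            rm_buffer[i % L] = rm_prod

    events["scenario_cap_events"] = runtime.state.cap_events
    time = np.arange(n + 1) * delta
    metadata = _metadata(presyn, postsyn, scenario, stimulus, config,
                         warmup=min(config.resolved_warmup, n + 1), events=events)
    return TraceSet(time=time, series=store, metadata=metadata)


# ---------------------------------------------------------------------------
# continuous-time reference engine
# ---------------------------------------------------------------------------

def simulate_reference(
    presyn: PreSynParams,
    postsyn: PostSynParams,
    scenario: ScenarioSpec,
    stimulus: SpikeTrain,
    config: EngineConfig,
) -> TraceSet:
    """Adaptive continuous-time integration of the full nonlinear model.

    The synaptopathy layer is defined per clock step and runs on the discretized
    engine; the reference engine is the healthy mathematical ideal and only
    accepts identity scenarios.
    """
    if config.mode != "reference":
        raise ValueError("config.mode must be 'reference'")
    if scenario is not None and not scenario.is_identity:
        raise NotImplementedError(
            "the reference engine models the healthy synapse; run ASD scenarios "
            "on the discretized engine"
        )
    lin = config.resolved_equations() == "linearized"
    mode = "linearized" if lin else "full"
    pp = postsyn
    prp = presyn
    w_rest = pp.Wpost_rest
    if w_rest is None:
        w_rest = pp.quiescent_membrane(mode)[1]
    pp_resolved = pp.replace(Wpost_rest=w_rest)
    rm_const = config.rm_mode == "constant"
    rm_eval_mode = "poly" if lin else "exact"

    idx = {k: i for i, k in enumerate(STATE_KEYS)}

    def rhs(t, y):
        rmt, inh, c, d, om, yy, zz, cc, ce, m, sm, v, w = y
        if rm_const:
            rm_in = config.rm_value
        else:
            rm_in = post.rm_concentration(max(cc, 0.0), rm_eval_mode, pp_resolved)
        pinh = pre.p_inh(max(inh, 0.0), "approx" if lin else "exact", prp)
        prel = prp.P_init * (1.0 - pinh)
        isyn = om * yy
        pstate = post.PostSynState(Cc=cc, Ce=ce, m=m, Sm=sm, Vpost=v, Wpost=w)
        pderiv, _ = post.postsyn_derivs(pstate, pp_resolved, isyn, mode)
        return [
            -rmt / prp.tau_r + rm_in,
            -inh / prp.tau_inh + rmt * c,
            -c / prp.tau_c,
            -d / prp.tau_d,
            prp.nmdar_gain * prel * c * d,
            (zz - yy) / prp.tau_syn,
            -zz / prp.tau_syn,
            pderiv.Cc, pderiv.Ce, pderiv.m, pderiv.Sm, pderiv.Vpost, pderiv.Wpost,
        ]

    h = config.sample_step
    n = int(round(config.horizon / h))
    grid = np.arange(n + 1) * h
    y = _initial_state(prp, pp_resolved, config, stimulus, lin)
    samples = np.empty((n + 1, len(STATE_KEYS)))
    samples[0] = y

    # segment boundaries: spike times partition the horizon; grid samples at a
    # spike time take the pre-jump (left-limit) value, matching the
    # discretized convention that a spike in [n*delta, (n+1)*delta) first
    # influences sample n+1.
    T = float(grid[-1])
    spike_set = {float(t) for t in stimulus.times if 0.0 <= t < T}
    bounds = sorted({0.0, T} | spike_set)
    filled = 1
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a in spike_set:
            post_active = 1 if y[idx["RMtrace"]] > prp.RM_rest else 0
            y[idx["C"]] += float(pre.hebbian_delta(1, post_active))
            y[idx["D"]] += 1.0
            y[idx["Z"]] += 1.0
        if b <= a:
            continue
        sol = solve_ivp(
            rhs, (a, b), y, method="RK45", dense_output=True,
            rtol=config.solver_rtol, atol=config.solver_atol,
            max_step=config.solver_max_step,
        )
        if not sol.success:
            raise IntegrationError(
                f"reference solver failed on [{a:.6g}, {b:.6g}] s: {sol.message}")
        if not np.all(np.isfinite(sol.y[:, -1])):
            bad = STATE_KEYS[int(np.argmax(~np.isfinite(sol.y[:, -1])))]
            raise IntegrationError(f"non-finite {bad} near t = {b:.6g} s")
        in_seg = grid[(grid > a) & (grid <= b)]
        if in_seg.size:
            samples[filled : filled + in_seg.size] = sol.sol(in_seg).T
            filled += in_seg.size
        y = sol.y[:, -1].copy()

    series = {k: samples[:, i].copy() for i, k in enumerate(STATE_KEYS)}
    inh_s = np.maximum(series["Inh"], 0.0)
    series["Pinh"] = np.asarray(pre.p_inh(inh_s, "approx" if lin else "exact", prp))
    series["Prel"] = prp.P_init * (1.0 - series["Pinh"])
    series["Isyn_in"] = series["omega"] * series["Y"]
    series["Isyn_eff"] = series["Isyn_in"].copy()
    series["I_Sm_eff"] = np.full(n + 1, pp.I_Sm)
    series["RM"] = np.asarray(
        post.rm_concentration(np.maximum(series["Cc"], 0.0), rm_eval_mode, pp_resolved))
    series["RM_in"] = (np.full(n + 1, config.rm_value) if rm_const
                       else series["RM"].copy())
    metadata = _metadata(presyn, postsyn, scenario or ScenarioSpec(), stimulus,
                         config, warmup=0, events={})
    return TraceSet(time=grid, series=series, metadata=metadata)


def simulate(
    presyn: PreSynParams,
    postsyn: PostSynParams,
    scenario: ScenarioSpec,
    stimulus: SpikeTrain,
    config: EngineConfig,
) -> TraceSet:
    """Dispatch on ``config.mode``."""
    if config.mode == "reference":
        return simulate_reference(presyn, postsyn, scenario, stimulus, config)
    return simulate_discretized(presyn, postsyn, scenario, stimulus, config)


def _metadata(presyn, postsyn, scenario, stimulus, config, warmup, events):
    return {
        "presyn": asdict(presyn),
        "postsyn": asdict(postsyn),
        "scenario": asdict(scenario),
        "engine": asdict(config),
        "stimulus": {
            "horizon": stimulus.horizon,
            "n_spikes": len(stimulus),
            "times": stimulus.times.tolist(),
        },
        "warmup_samples": warmup,
        "output_key": OUTPUT_KEY,
        "events": events,
    }
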