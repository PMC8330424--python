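"""Small feed-forward networks of synapse units and failure-fraction estimation.

Units are chained: each unit's post-synaptic membrane potential is thresholded
into a spike train (upward crossings with a short refractory window) that
drives the next unit.  A seeded subset of units carries the configured
synaptopathy scenario; the rest are healthy.  The question asked of the
network is the minimum fraction of dysfunctional units that makes the network
fail to coordinate its pre-synaptic input with its post-synaptic output.

Failure is judged on pre/post coordination across the whole network, against
the all-healthy reference chain under the same stimulus.  The default
criterion (``train_agreement``) compares each unit's output spike train with
the same unit's reference train by a coincidence F-score (spikes matched
one-to-one within a tolerance window) and triggers when the worst per-unit
disagreement exceeds the threshold; spike timing, not just rate, carries the
coordination, because an oscillating membrane can keep its firing rate while
completely losing its lock to the input.  Pluggable alternatives:
``rate_deviation`` (worst per-unit relative spike-count deviation) and
``correlation_below`` (smoothed-rate zero-lag correlation of network input
vs output); raw per-step binary-train correlation is degenerate at
sub-millisecond steps and is not offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .engine import EngineConfig, TraceSet, simulate
from .presynaptic import PreSynParams
from .postsynaptic import PostSynParams
from .scenarios import ScenarioSpec
from .stimulus import SpikeTrain

__all__ = ["NetworkSpec", "NetworkResult", "build_and_run", "min_failure_fraction"]


@dataclass(frozen=True)
class NetworkSpec:
    """Topology, scenario assignment and failure criterion of a network run."""

    n_units: int = 3
    topology: str = "chain"          # or "parallel_converge"
    affected_fraction: float = 0.0
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    failure_criterion: str = "train_agreement"  # or rate_deviation / correlation_below
    criterion_threshold: float = 0.5
    seed: int = 0
    vpost_threshold: float = 1.0     # spike hand-off level on Vpost
    refractory_samples: int = 2
    match_tolerance: float = 0.02    # coincidence window (s) for train agreement
    smoothing_tau: float = 0.1       # smoothed-rate kernel for the correlation criterion

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must be in [0, 1]")
        if self.topology not in ("chain", "parallel_converge"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.failure_criterion not in ("train_agreement", "rate_deviation",
                                          "correlation_below"):
            raise ValueError(f"unknown failure criterion {self.failure_criterion!r}")

    def replace(self, **kw) -> "NetworkSpec":
        return replace(self, **kw)


@dataclass
class NetworkResult:
    traces: list
    output_train: SpikeTrain
    unit_output_counts: list
    coordination: float
    failed: bool
    dead_paths: list
    affected_units: list


def spike_times_from_vpost(trace: TraceSet, threshold: float,
                           refractory: int = 2) -> SpikeTrain:
    """Upward threshold crossings of the membrane potential as a spike train."""
    v = np.asarray(trace.series["Vpost"])
    above = v > threshold
    idxs = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    keep = []
    last = -(refractory + 1)
    for i in idxs:
        if i - last > refractory:
            keep.append(i)
            last = int(i)
    horizon = float(trace.time[-1]) if trace.time.size else 0.0
    times = trace.time[keep]
    times = times[times < horizon] if horizon > 0 else times[:0]
    return SpikeTrain(times=times, horizon=horizon)


def _smoothed_rate(train: SpikeTrain, grid: np.ndarray, tau: float) -> np.ndarray:
    out = np.zeros_like(grid)
    for t in train.times:
        m = grid >= t
        out[m] += np.exp(-(grid[m] - t) / tau)
    return out


def coordination_correlation(inp: SpikeTrain, out: SpikeTrain,
                             tau: float = 0.1, dt: float = 0.01) -> float:
    """Zero-lag Pearson correlation of exponentially smoothed spike rates."""
    horizon = max(inp.horizon, out.horizon)
    if horizon <= 0:
        return 0.0
    grid = np.arange(0.0, horizon, dt)
    a = _smoothed_rate(inp, grid, tau)
    b = _smoothed_rate(out, grid, tau)
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def train_agreement(test: SpikeTrain, reference: SpikeTrain,
                    tolerance: float = 0.02) -> float:
    """Coincidence F-score between two spike trains in [0, 1].

    Spikes are matched greedily one-to-one within ``tolerance`` seconds;
    the score is 2*matches/(n_test + n_ref).  Two empty trains agree fully.
    """
    a, b = np.asarray(test.times), np.asarray(reference.times)
    if a.size == 0 and b.size == 0:
        return 1.0
    if a.size == 0 or b.size == 0:
        return 0.0
    i = j = matches = 0
    while i < a.size and j < b.size:
        d = a[i] - b[j]
        if abs(d) <= tolerance:
            matches += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return 2.0 * matches / (a.size + b.size)


def _affected_units(spec: NetworkSpec) -> list[int]:
    k = int(math.floor(spec.affected_fraction * spec.n_units))
    if k == 0:
        return []
    rng = np.random.default_rng(spec.seed)
    return sorted(rng.choice(spec.n_units, size=k, replace=False).tolist())


def build_and_run(
    spec: NetworkSpec,
    stimulus: SpikeTrain,
    config: EngineConfig,
    presyn: PreSynParams | None = None,
    postsyn: PostSynParams | None = None,
    reference_trains: list | None = None,
) -> NetworkResult:
    """Run the network and evaluate the coordination/failure criterion.

    ``reference_trains`` are the per-unit output spike trains of the
    all-healthy chain under the same stimulus; when omitted and needed by
    the per-unit criteria they are computed internally.
    """
    presyn = presyn or PreSynParams()
    postsyn = postsyn or PostSynParams()
    affected = set(_affected_units(spec))
    healthy = ScenarioSpec()

    def run_chain(affected_set):
        traces, dead, trains = [], [], []
        train = stimulus
        for i in range(spec.n_units):
            scen = spec.scenario if i in affected_set else healthy
            if scen.mechanism != "none":
                # independent, derived sub-seed per unit so unit noise sources
                # are separately reproducible
                scen = scen.replace(noise_seed=(scen.noise_seed * 1000003 + i) % (2**31))
            tr = simulate(presyn, postsyn, scen, train, config)
            traces.append(tr)
            out_train = spike_times_from_vpost(
                tr, spec.vpost_threshold, spec.refractory_samples)
            trains.append(out_train)
            if len(out_train) == 0 and i < spec.n_units - 1:
                dead.append(i)
            train = out_train
        return traces, train, dead, trains

    traces, out_train, dead, trains = run_chain(affected)
    counts = [len(t) for t in trains]

    if spec.failure_criterion in ("train_agreement", "rate_deviation"):
        if reference_trains is None:
            if affected:
                _, _, _, reference_trains = run_chain(set())
            else:
                reference_trains = trains
        if spec.failure_criterion == "train_agreement":
            coordination = min(
                train_agreement(t, r, spec.match_tolerance)
                for t, r in zip(trains, reference_trains)
            )
            failed = (1.0 - coordination) > spec.criterion_threshold
        else:
            dev = max(
                abs(len(t) - len(r)) / max(1, len(r))
                for t, r in zip(trains, reference_trains)
            )
            coordination = 1.0 / (1.0 + dev)
            failed = dev > spec.criterion_threshold
    else:
        coordination = coordination_correlation(stimulus, out_train,
                                                tau=spec.smoothing_tau)
        failed = coordination < spec.criterion_threshold
    return NetworkResult(
        traces=traces,
        output_train=out_train,
        unit_output_counts=counts,
        coordination=coordination,
        failed=failed,
        dead_paths=dead,
        affected_units=sorted(affected),
    )


def min_failure_fraction(
    spec_template: NetworkSpec,
    stimulus: SpikeTrain,
    config: EngineConfig,
    resolution: float = 1.0 / 3.0,
    n_seeds: int = 5,
    presyn: PreSynParams | None = None,
    postsyn: PostSynParams | None = None,
) -> tuple[float | None, dict]:
    """Smallest affected fraction (on the resolution grid) that triggers failure.

    The failure indicator is averaged over ``n_seeds`` seeded draws of the
    affected-unit subset (and scenario noise); a grid fraction counts as
    failing when the mean indicator exceeds 0.5.  Returns ``(fraction, sweep)``
    with ``fraction=None`` if no grid point fails.
    """
    if not 0.0 < resolution <= 0.5:
        raise ValueError("resolution must be in (0, 0.5]")
    presyn = presyn or PreSynParams()
    postsyn = postsyn or PostSynParams()
    healthy_spec = spec_template.replace(affected_fraction=0.0)
    healthy_trains = None
    if spec_template.failure_criterion in ("train_agreement", "rate_deviation"):
        healthy = build_and_run(healthy_spec, stimulus, config, presyn, postsyn)
        healthy_trains = [spike_times_from_vpost(tr, spec_template.vpost_threshold,
                                                 spec_template.refractory_samples)
                          for tr in healthy.traces]
    fractions = np.arange(0.0, 1.0 + 1e-9, resolution)
    fractions = np.minimum(fractions, 1.0)
    sweep = {}
    answer = None
    for frac in fractions:
        fails = []
        for s in range(n_seeds):
            sp = spec_template.replace(
                affected_fraction=float(frac),
                seed=spec_template.seed * 7919 + s,
                scenario=spec_template.scenario.replace(
                    noise_seed=(spec_template.scenario.noise_seed * 104729 + s)
                    % (2**31)),
            )
            res = build_and_run(sp, stimulus, config, presyn, postsyn,
                                reference_trains=healthy_trains)
            fails.append(1.0 if res.failed else 0.0)
        sweep[float(frac)] = float(np.mean(fails))
        if answer is None and np.mean(fails) > 0.5:
            answer = float(frac)
    return answer, sweep
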