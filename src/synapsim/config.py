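"""Run configuration: strict parsing, resolution and artifact writing.

A run is fully described by nested blocks mirroring the parameter
dataclasses (``presyn``, ``postsyn``, ``scenario``, ``engine``, ``network``,
``metrics``, ``stimulus``).  Unknown keys are rejected with the offending key
path; every report embeds the fully resolved configuration (defaults
included), so any artifact can be reproduced from its own snapshot.

The default-constructed :class:`RunConfig` is the canonical protocol: a
10 Hz periodic spike train over a 10 s horizon driving the synapse under a
constant retrograde-messenger input just above the plasticity threshold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .engine import EngineConfig, TraceSet, simulate
from .metrics import (DEFAULT_THRESHOLDS, DEFAULT_WEIGHTS, distortion_report)
from .network import NetworkSpec
from .presynaptic import PreSynParams
from .postsynaptic import PostSynParams
from .scenarios import ScenarioSpec
from .stimulus import SpikeTrain, periodic_spike_train, poisson_spike_train

__all__ = ["StimulusSpec", "MetricParams", "RunConfig", "run_config"]

log = logging.getLogger("synapsim")


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative spike-train specification resolved at run time."""

    kind: str = "periodic"      # or "poisson"
    rate: float = 10.0
    phase: float = 0.0
    seed: int = 0
    horizon: float | None = None  # None -> engine horizon

    def __post_init__(self):
        if self.kind not in ("periodic", "poisson"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")

    def replace(self, **kw) -> "StimulusSpec":
        return replace(self, **kw)

    def build(self, horizon: float) -> SpikeTrain:
        h = self.horizon if self.horizon is not None else horizon
        if self.kind == "periodic":
            return periodic_spike_train(self.rate, h, self.phase)
        return poisson_spike_train(self.rate, h, self.seed)


@dataclass(frozen=True)
class MetricParams:
    weights: tuple = DEFAULT_WEIGHTS
    thresholds: tuple = DEFAULT_THRESHOLDS
    refractory: int = 2

    def __post_init__(self):
        if len(self.weights) != 3:
            raise ValueError("weights must have three entries (rms, gain, spikes)")
        if len(self.thresholds) != 2 or not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must be an increasing pair")


_BLOCKS = {
    "presyn": PreSynParams,
    "postsyn": PostSynParams,
    "scenario": ScenarioSpec,
    "engine": EngineConfig,
    "network": NetworkSpec,
    "metrics": MetricParams,
    "stimulus": StimulusSpec,
}


def _build_block(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown configuration key {path}.{key}")
    kw = dict(data)
    # YAML lists -> tuples where the dataclass expects tuples
    for f in dataclasses.fields(cls):
        if f.name in kw and isinstance(kw[f.name], list):
            kw[f.name] = tuple(kw[f.name])
        if f.name in kw and f.name == "scenario" and isinstance(kw[f.name], dict):
            kw[f.name] = _build_block(ScenarioSpec, kw[f.name], f"{path}.scenario")
    return cls(**kw)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of a single run (or network run)."""

    presyn: PreSynParams = field(default_factory=PreSynParams)
    postsyn: PostSynParams = field(default_factory=PostSynParams)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    engine: EngineConfig = field(default_factory=EngineConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    metrics: MetricParams = field(default_factory=MetricParams)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_BLOCKS)
        if unknown:
            raise ValueError(f"unknown configuration key {sorted(unknown)[0]}")
        kw = {}
        for name, block_cls in _BLOCKS.items():
            if name in data:
                block = data[name] or {}
                if not isinstance(block, dict):
                    raise ValueError(f"configuration block {name} must be a mapping")
                kw[name] = _build_block(block_cls, block, name)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {name: asdict(getattr(self, name)) for name in _BLOCKS}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)

    # -- execution helpers --------------------------------------------
    def build_stimulus(self) -> SpikeTrain:
        return self.stimulus.build(self.engine.horizon)

    def run(self, mode: str | None = None) -> TraceSet:
        cfg = self.engine if mode is None else self.engine.replace(mode=mode)
        return simulate(self.presyn, self.postsyn, self.scenario,
                        self.build_stimulus(), cfg)


def run_config(config: RunConfig, output_dir) -> dict:
    """Execute a single run and write its artifact set.

    Writes the trace CSV/JSON, a distortion report of the run against itself
    (score exactly 1 by construction — the self-comparison baseline), the
    resolved configuration snapshot, and returns the artifact paths.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    trace = config.run()
    trace.to_csv(outdir / "trace.csv")
    trace.to_json(outdir / "trace.json")
    report = distortion_report(trace, trace, config.metrics.weights,
                               config.metrics.thresholds,
                               config.metrics.refractory)
    report.to_json(outdir / "report.json")
    config.to_yaml(outdir / "config.yaml")
    events = trace.metadata.get("events", {})
    for name, count in events.items():
        if count:
            log.info("run event %s: %d occurrences", name, count)
    with open(outdir / "events.json", "w") as fh:
        json.dump(events, fh, indent=2)
    return {
        "trace_csv": str(outdir / "trace.csv"),
        "trace_json": str(outdir / "trace.json"),
        "report": str(outdir / "report.json"),
        "config": str(outdir / "config.yaml"),
        "events": events,
    }
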