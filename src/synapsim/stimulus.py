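"""Stimulus generation: spike trains and noise series.

Every input that drives the synapse model is generated here so that all
downstream stages are testable without external data.  Generators are pure
functions of their arguments (including the seed): re-running with identical
arguments is bit-identical.

Spike events are timestamps in seconds, not per-step flags; binning onto the
fixed-step engine grid is the engine's job, which keeps the stimulus
independent of the engine step size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "NoiseSeries",
    "periodic_spike_train",
    "poisson_spike_train",
    "noise_series",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered impulse times driving the pre-synaptic bouton.

    Parameters
    ----------
    times : ndarray of float
        Strictly increasing event times, all within ``[0, horizon]`` (s).
    horizon : float
        Total duration of the stimulus window (s).
    """

    times: np.ndarray
    horizon: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.horizon < 0:
            raise ValueError(f"horizon must be >= 0, got {self.horizon}")
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.horizon:
                raise ValueError("spike times must lie in [0, horizon]")

    def __len__(self) -> int:
        return int(self.times.size)

    # -- serialization -------------------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time": self.times}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, horizon: float) -> "SpikeTrain":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(times=df["time"].to_numpy(), horizon=horizon)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"horizon": self.horizon, "times": self.times.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "SpikeTrain":
        with open(path) as fh:
            d = json.load(fh)
        return cls(times=np.asarray(d["times"], dtype=float), horizon=d["horizon"])


@dataclass(frozen=True)
class NoiseSeries:
    """Zero-mean noise samples with scale ``sigma``, reproducible from ``seed``."""

    values: np.ndarray
    sigma: float
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return int(self.values.size)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"value": self.values}).to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"sigma": self.sigma, "seed": self.seed, "values": self.values.tolist()},
                fh,
            )


def periodic_spike_train(rate: float, horizon: float, phase: float = 0.0) -> SpikeTrain:
    """Regular spike train with events at ``phase + k/rate`` for all ``k >= 0``.

    Parameters
    ----------
    rate : float
        Event rate in events/second (>= 0; 0 yields an empty train).
    horizon : float
        Duration of the window (s); events at ``t >= horizon`` are excluded.
    phase : float
        Offset of the first event, ``0 <= phase < 1/rate`` when ``rate > 0``.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon}")
    if rate == 0 or horizon == 0:
        return SpikeTrain(times=np.empty(0), horizon=horizon)
    period = 1.0 / rate
    if not (0 <= phase < period):
        raise ValueError(f"phase must be in [0, 1/rate), got {phase}")
    n = int(np.ceil((horizon - phase) / period))
    times = phase + np.arange(n) * period
    return SpikeTrain(times=times[times < horizon], horizon=horizon)


def poisson_spike_train(rate: float, horizon: float, seed: int) -> SpikeTrain:
    """Homogeneous Poisson process realization, deterministic given ``seed``."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon}")
    if rate == 0 or horizon == 0:
        return SpikeTrain(times=np.empty(0), horizon=horizon)
    rng = np.random.default_rng(seed)
    # draw gaps in blocks until the horizon is covered
    times = []
    t = 0.0
    block = max(16, int(rate * horizon * 1.5))
    while True:
        gaps = rng.exponential(1.0 / rate, size=block)
        cum = t + np.cumsum(gaps)
        inside = cum[cum < horizon]
        times.append(inside)
        if inside.size < block:
            break
        t = cum[-1]
    return SpikeTrain(times=np.concatenate(times), horizon=horizon)


def noise_series(
    sigma: float, n: int, seed: int, distribution: str = "gaussian"
) -> NoiseSeries:
    """``n`` zero-mean samples with scale ``sigma``.

    The distribution is a pluggable strategy (``"gaussian"`` default,
    ``"uniform"`` = uniform on [-sigma*sqrt(3), sigma*sqrt(3)] so the standard
    deviation matches sigma).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    if distribution == "gaussian":
        values = sigma * rng.standard_normal(n)
    elif distribution == "uniform":
        half = sigma * np.sqrt(3.0)
        values = rng.uniform(-half, half, size=n)
    else:
        raise ValueError(f"unknown noise distribution {distribution!r}")
    if sigma == 0:
        values = np.zeros(n)
    return NoiseSeries(values=values, sigma=sigma, seed=seed)
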