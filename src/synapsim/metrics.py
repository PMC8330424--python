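"""Deviation metrics, distortion scoring and classification.

Two per-series error measures are used throughout: the relative RMS error
(shape-sensitive) and the Area Average Error (AAE), the relative difference
in area under the curve.  AAE ignores latency — a time-shifted pulse with
preserved area scores 0 — which makes it the biologically meaningful measure
once RMS error is small, since what a synapse conserves is the transferred
quantity (calcium influx), not the exact waveform.

The distortion score condenses a run's deviation from the ideal trace into a
single number normalized so the ideal trace scores exactly 1: a weighted
combination of relative RMS, peak-amplitude gain deviation, and excess
supra-threshold spike count (the two axes that matter for plasticity are the
gain in potential strength and the number of threshold-crossing spikes).
Scores are classified into Type A (least distortion, unobservable at a
single synapse), Type B (considerable, observable with high-precision
methods) and Type C (abrupt, observable at a single synapse).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "DistortionReport",
    "rms_error",
    "aae",
    "count_suprathreshold",
    "peak_gain",
    "distortion_score",
    "distortion_report",
    "classify_distortion",
    "filter_class",
    "DEFAULT_WEIGHTS",
    "DEFAULT_THRESHOLDS",
]

#: weights of (relative RMS, gain deviation, excess spike count)
DEFAULT_WEIGHTS = (0.5, 0.25, 0.25)
#: Type A/B boundary and Type B/C boundary on the normalized score (ideal = 1)
DEFAULT_THRESHOLDS = (1.5, 3.0)


@dataclass
class DistortionReport:
    """Summary of one run's deviation from the ideal trace."""

    rms_pct: float
    aae_pct: float
    score: float
    dtype: str
    gain: float
    spike_count: int
    ref_spike_count: int
    clip_events: int = 0
    noise_sigma: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def csv_row(self) -> str:
        d = asdict(self)
        return ",".join(str(d[k]) for k in d)


def _as_series(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def rms_error(test, reference) -> float:
    """Relative RMS deviation in percent: 100*RMS(test-ref)/RMS(ref)."""
    test, reference = _as_series(test), _as_series(reference)
    if test.shape != reference.shape:
        raise ValueError("series must have equal length")
    denom = float(np.sqrt(np.mean(reference**2)))
    if denom == 0.0:
        raise ValueError("reference series is identically zero; RMS error undefined")
    return 100.0 * float(np.sqrt(np.mean((test - reference) ** 2))) / denom


def aae(test, reference, dt: float = 1.0, method: str = "rectangle") -> float:
    """Area Average Error in percent.

    ``100 * |area(test) - area(reference)| / area(|reference|)`` with areas by
    rectangle (default) or trapezoid rule.  Insensitive to latency: equal
    discrete areas give 0 regardless of shape.
    """
    test, reference = _as_series(test), _as_series(reference)
    if test.shape != reference.shape:
        raise ValueError("series must have equal length")
    if method == "rectangle":
        a_t, a_r = np.sum(test) * dt, np.sum(reference) * dt
        norm = np.sum(np.abs(reference)) * dt
    elif method == "trapezoid":
        a_t, a_r = np.trapezoid(test, dx=dt), np.trapezoid(reference, dx=dt)
        norm = np.trapezoid(np.abs(reference), dx=dt)
    else:
        raise ValueError(f"unknown AAE method {method!r}")
    if norm == 0.0:
        raise ValueError("reference area is zero; AAE undefined")
    return 100.0 * float(abs(a_t - a_r)) / float(norm)


def count_suprathreshold(series, threshold, refractory: int = 2) -> int:
    """Supra-threshold activation events with a refractory window.

    An event is a local maximum of the series (plateaus count once, at their
    first sample) lying strictly above the activation threshold, which may be
    a scalar or a per-sample series (the effective, scenario-modified level).
    Counting peaks rather than threshold crossings keeps the count meaningful
    when successive pulses merge above the threshold.
    """
    s = _as_series(series)
    thr = np.broadcast_to(_as_series(threshold), s.shape)
    if s.size < 3:
        return 0
    is_peak = (s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:]) & (s[1:-1] > thr[1:-1])
    idxs = np.nonzero(is_peak)[0] + 1
    count = 0
    last = -(refractory + 1)
    for i in idxs:
        if i - last > refractory:
            count += 1
            last = int(i)
    return count


def peak_gain(test, reference) -> float:
    """Peak-amplitude ratio max|test| / max|reference| (1.0 if both flat)."""
    t, r = np.max(np.abs(_as_series(test))), np.max(np.abs(_as_series(reference)))
    if r == 0.0:
        return 1.0 if t == 0.0 else np.inf
    return float(t / r)


def distortion_score(
    test,
    ideal,
    weights=DEFAULT_WEIGHTS,
    threshold=None,
    refractory: int = 2,
) -> float:
    """Normalized distortion of a run against the ideal run (ideal = 1).

    Accepts TraceSets (compared on the synaptic output potential series,
    after warm-up, with the ideal run's effective activation threshold) or
    plain arrays plus an explicit ``threshold``.
    """
    w_rms, w_gain, w_spk = weights
    if hasattr(test, "series"):
        if hasattr(ideal, "series"):
            if test.time.size != ideal.time.size or not np.allclose(
                test.time, ideal.time
            ):
                raise ValueError("TraceSets must share the sample grid")
        t = test.output(after_warmup=True)
        r = ideal.output(after_warmup=True)
        if threshold is None:
            threshold = ideal.series["I_Sm_eff"][~ideal.warmup_mask]
    else:
        t, r = _as_series(test), _as_series(ideal)
        if t.shape != r.shape:
            raise ValueError("series must have equal length")
        if threshold is None:
            raise ValueError("threshold required for plain-array scoring")
    rms = rms_error(t, r)
    gain = peak_gain(t, r)
    n_t = count_suprathreshold(t, threshold, refractory)
    n_r = count_suprathreshold(r, threshold, refractory)
    excess = max(0, n_t - n_r) / max(1, n_r)
    return 1.0 + w_rms * rms / 100.0 + w_gain * abs(gain - 1.0) + w_spk * excess


def distortion_report(
    test,
    ideal,
    weights=DEFAULT_WEIGHTS,
    thresholds=DEFAULT_THRESHOLDS,
    refractory: int = 2,
) -> DistortionReport:
    """Full distortion summary of a TraceSet against the ideal TraceSet."""
    t = test.output(after_warmup=True)
    r = ideal.output(after_warmup=True)
    thr_t = test.series["I_Sm_eff"][~test.warmup_mask]
    thr_r = ideal.series["I_Sm_eff"][~ideal.warmup_mask]
    dt = float(test.time[1] - test.time[0]) if test.time.size > 1 else 1.0
    score = distortion_score(test, ideal, weights, refractory=refractory)
    events = test.metadata.get("events", {})
    return DistortionReport(
        rms_pct=rms_error(t, r),
        aae_pct=aae(t, r, dt),
        score=score,
        dtype=classify_distortion(score, thresholds),
        gain=peak_gain(t, r),
        spike_count=count_suprathreshold(t, thr_t, refractory),
        ref_spike_count=count_suprathreshold(r, thr_r, refractory),
        clip_events=int(events.get("ks_clipped", 0)),
        noise_sigma=float(test.metadata.get("scenario", {}).get("noise_sigma", 0.0)),
    )


def classify_distortion(score: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Map a normalized score onto Type A/B/C (half-open boundaries).

    ``score < theta1`` is A, ``theta1 <= score < theta2`` is B, else C.
    """
    th1, th2 = thresholds
    if not th1 < th2:
        raise ValueError(f"thresholds must satisfy theta1 < theta2, got {thresholds}")
    if score < 0:
        raise ValueError("score must be >= 0")
    if score < th1:
        return "A"
    if score < th2:
        return "B"
    return "C"


def filter_class(P_init: float) -> str:
    """Filter class of a synapse from its initial release probability.

    Below 0.3 the synapse is a high-pass filter, above 0.7 a low-pass
    filter, and intermediate release probabilities give a band-pass filter.
    """
    if not 0.0 <= P_init <= 1.0:
        raise ValueError(f"P_init must be in [0, 1], got {P_init}")
    if P_init < 0.3:
        return "high_pass"
    if P_init > 0.7:
        return "low_pass"
    return "band_pass"
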