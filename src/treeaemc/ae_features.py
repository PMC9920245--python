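"""Acoustic-emission hit detection and per-record feature vectors.

AE practice summarizes a burst ("hit") by a handful of waveform parameters:
peak amplitude, rise time (first threshold crossing to peak), duration,
ring count (number of upward threshold crossings of the rectified signal)
and energy.  A hit opens at the first sample whose absolute value reaches
the detection threshold and closes once the signal stays below threshold
for the hit-definition time (HDT).

For regression, each record is summarized by a fixed-length feature vector
combining per-mode summaries of its ACMD components (energy share, mean
instantaneous frequency, envelope peak, envelope decay rate) with
per-record hit statistics (mean amplitude, mean ring count, mean energy).
Modes are ordered by energy so the vector is invariant to component
ordering; absent modes are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .acmd import ModeComponent
from .signal_sim import Waveform

__all__ = ["AEHit", "detect_hits", "features_from_modes", "raw_features",
           "feature_names", "raw_feature_names"]


@dataclass
class AEHit:
    """One detected AE hit and its standard parameters."""

    start: float        # s, first threshold crossing
    end: float          # s, last above-threshold sample
    amplitude: float    # peak |x| within the hit
    rise_time: float    # s, start -> peak
    duration: float     # s, start -> end (inclusive of the end sample)
    ring_count: int     # upward crossings of |x| through the threshold
    energy: float       # sum of squared samples * dt over the hit


def detect_hits(w: Waveform, threshold: float, hdt: float) -> list[AEHit]:
    """Threshold-based hit detection with a hit-definition time.

    A hit opens at the first sample with ``|x| >= threshold`` and closes when
    ``|x|`` stays below threshold for ``hdt`` seconds; the hit extent runs to
    the last above-threshold sample.  Returns an empty list if the signal
    never crosses the threshold.
    """
    if threshold <= 0 or hdt <= 0:
        raise ValueError("threshold and hdt must be positive")
    x = np.abs(w.samples)
    above = x >= threshold
    if not above.any():
        return []
    gap = max(int(round(hdt * w.rate)), 1)
    idx = np.flatnonzero(above)
    # segment indices whose gaps exceed the HDT
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])

    hits: list[AEHit] = []
    dt = 1.0 / w.rate
    for s, e in zip(starts, ends):
        seg = x[s : e + 1]
        peak = s + int(np.argmax(seg))
        crossings = int(np.count_nonzero(
            (seg >= threshold) & np.concatenate([[True], seg[:-1] < threshold])
        ))
        hits.append(AEHit(
            start=w.t0 + s * dt,
            end=w.t0 + e * dt,
            amplitude=float(x[peak]),
            rise_time=(peak - s) * dt,
            duration=(e - s + 1) * dt,
            ring_count=max(crossings, 1),
            energy=float(np.sum(w.samples[s : e + 1] ** 2) * dt),
        ))
    return hits


def _decay_rate(ia: np.ndarray, rate: float) -> float:
    """Ring-down rate of an envelope, 1/s.

    Median of the negative log-envelope slope over samples above 10% of the
    peak: the rising edges of a periodic burst train are a minority of those
    samples, so the median lands on the exponential ring-down slope.
    """
    peak = float(ia.max())
    if peak <= 0:
        return 0.0
    mask = ia > 0.1 * peak
    if np.count_nonzero(mask) < 3:
        return 0.0
    slope = np.gradient(np.log(np.maximum(ia, 1e-300))) * rate
    return float(-np.median(slope[mask]))


def _hit_stats(hits: Sequence[AEHit]) -> list[float]:
    if not hits:
        return [0.0, 0.0, 0.0]
    return [
        float(np.mean([h.amplitude for h in hits])),
        float(np.mean([h.ring_count for h in hits])),
        float(np.mean([h.energy for h in hits])),
    ]


_PER_MODE = ("energy_share", "mean_if", "ia_peak", "ia_decay")
_PER_RECORD = ("hit_mean_amplitude", "hit_mean_ring_count", "hit_mean_energy")


def feature_names(max_modes: int) -> list[str]:
    names = [f"mode{i}_{s}" for i in range(max_modes) for s in _PER_MODE]
    return names + list(_PER_RECORD)


def features_from_modes(
    components: Sequence[ModeComponent],
    hits: Sequence[AEHit],
    max_modes: int,
    rate: float,
) -> np.ndarray:
    """Fixed-length feature vector from ACMD components plus hit statistics.

    Per mode (energy-descending order, zero-padded to ``max_modes``):
    energy share of the reconstructed mode, envelope-weighted mean
    instantaneous frequency, envelope peak, and envelope decay rate.
    Followed by the three per-record hit statistics.
    """
    comps = sorted(components, key=lambda c: c.energy(), reverse=True)[:max_modes]
    total = sum(c.energy() for c in components)
    feats: list[float] = []
    for c in comps:
        w = c.ia**2
        wsum = float(w.sum())
        mean_if = float((c.freq * w).sum() / wsum) if wsum > 0 else 0.0
        feats += [
            c.energy() / total if total > 0 else 0.0,
            mean_if,
            float(c.ia.max()),
            _decay_rate(c.ia, rate),
        ]
    feats += [0.0] * (4 * (max_modes - len(comps)))
    feats += _hit_stats(hits)
    return np.asarray(feats)


_RAW = ("hit_mean_amplitude", "hit_mean_rise_time", "hit_mean_duration",
        "hit_mean_ring_count", "hit_mean_energy")


def raw_feature_names() -> list[str]:
    return list(_RAW)


def raw_features(w: Waveform, hits: Sequence[AEHit]) -> np.ndarray:
    """Decomposition-free baseline: the five standard AE hit parameters.

    Record-level means of amplitude, rise time, duration, ring count and
    energy over the detected hits — the characteristic parameters an AE
    acquisition front end reports without any waveform decomposition.
    """
    if not hits:
        return np.zeros(5)
    return np.asarray([
        float(np.mean([h.amplitude for h in hits])),
        float(np.mean([h.rise_time for h in hits])),
        float(np.mean([h.duration for h in hits])),
        float(np.mean([h.ring_count for h in hits])),
        float(np.mean([h.energy for h in hits])),
    ])
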