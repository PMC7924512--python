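"""RR-interval dynamic features.

Four timing features describe each beat's rhythm context: the previous RR
interval (R peak to the preceding R peak), the post RR interval (to the
following R peak), their ratio, and the local RR interval (mean of the 10
intervals immediately preceding the beat).  Because resting heart rate
differs between patients, the record-wide mean RR interval is subtracted
from the three interval-valued features (never the ratio) — each record is
normalized against itself only, so no timing information leaks between
patients or between training and test splits.

All intervals are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RRFeatureVector",
    "compute_rr_intervals",
    "extract_rr_features",
    "normalize_rr_features",
    "record_rr_features",
    "LOCAL_RR_WINDOW",
]

#: Number of preceding intervals averaged into the local RR feature.
LOCAL_RR_WINDOW = 10


@dataclass(frozen=True)
class RRFeatureVector:
    prev_rr_s: float
    post_rr_s: float
    ratio_rr: float
    local_rr_s: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.prev_rr_s, self.post_rr_s, self.ratio_rr, self.local_rr_s]
        )


def compute_rr_intervals(r_indices: np.ndarray, fs: float) -> np.ndarray:
    """Consecutive R-peak intervals in seconds; length = len(r_indices) - 1."""
    r = np.asarray(r_indices, dtype=np.int64)
    if r.size < 2:
        raise ValueError("need at least two R peaks to form an interval")
    if np.any(np.diff(r) <= 0):
        raise ValueError("R-peak indices must be strictly increasing")
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    return np.diff(r) / fs


def extract_rr_features(
    r_indices: np.ndarray, beat_position: int, fs: float
) -> RRFeatureVector:
    """Raw (un-normalized) RR features for the beat at ``beat_position``.

    Edge policy: the record's first beat has no previous interval and the
    last has no post interval; both fall back to the record mean RR, as does
    the local RR when no preceding interval exists.  With fewer than 10
    preceding intervals the local RR averages those available.
    """
    intervals = compute_rr_intervals(r_indices, fs)
    n_beats = len(r_indices)
    if not 0 <= beat_position < n_beats:
        raise IndexError(f"beat_position {beat_position} out of range [0, {n_beats})")
    mean_rr = float(np.mean(intervals))
    prev_rr = float(intervals[beat_position - 1]) if beat_position > 0 else mean_rr
    post_rr = float(intervals[beat_position]) if beat_position < n_beats - 1 else mean_rr
    preceding = intervals[max(0, beat_position - LOCAL_RR_WINDOW) : beat_position]
    local_rr = float(np.mean(preceding)) if preceding.size else mean_rr
    return RRFeatureVector(prev_rr, post_rr, prev_rr / post_rr, local_rr)


def normalize_rr_features(
    features: RRFeatureVector, record_mean_rr_s: float
) -> RRFeatureVector:
    """Subtract the record-wide mean RR from the interval features.

    The ratio feature is dimensionless and left untouched.
    """
    if record_mean_rr_s <= 0:
        raise ValueError(f"record mean RR must be > 0, got {record_mean_rr_s}")
    return replace(
        features,
        prev_rr_s=features.prev_rr_s - record_mean_rr_s,
        post_rr_s=features.post_rr_s - record_mean_rr_s,
        local_rr_s=features.local_rr_s - record_mean_rr_s,
    )


def record_rr_features(r_indices: np.ndarray, fs: float) -> np.ndarray:
    """Normalized RR feature matrix for a whole record, shape (n_beats, 4).

    Row i holds (prev, post, ratio, local) for beat i after subtraction of
    the record's mean RR interval (computed over all of its intervals).
    """
    intervals = compute_rr_intervals(r_indices, fs)
    mean_rr = float(np.mean(intervals))
    out = np.empty((len(r_indices), 4), dtype=float)
    for pos in range(len(r_indices)):
        feat = normalize_rr_features(extract_rr_features(r_indices, pos, fs), mean_rr)
        out[pos] = feat.as_array()
    return out
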