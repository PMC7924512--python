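"""Baseline-wander removal and fixed-width heartbeat segmentation.

Baseline wander (respiration / electrode drift) is estimated by two cascaded
median filters: a 200-ms window first suppresses QRS complexes and P waves,
then a 600-ms window suppresses T waves; what survives is the baseline,
which is subtracted from the raw signal.  No other filtering is applied —
high-frequency content is deliberately preserved for the convolutional
feature extractor.

Beats are cut as 200-sample windows anchored on the labeled R peak: 90
samples before and 110 after (0-based, half-open ``[r-90, r+110)``).  Beats
whose window would cross a record edge are dropped, never padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter

from .mitdb_io import AAMIClass

__all__ = [
    "BeatSegment",
    "median_window_samples",
    "estimate_baseline",
    "remove_baseline",
    "segment_heartbeats",
    "SEGMENT_PRE",
    "SEGMENT_POST",
    "SEGMENT_LENGTH",
]

SEGMENT_PRE = 90
SEGMENT_POST = 110
SEGMENT_LENGTH = SEGMENT_PRE + SEGMENT_POST

#: Median-filter widths in milliseconds (QRS/P pass, then T pass).
BASELINE_WINDOW_MS = (200.0, 600.0)


@dataclass
class BeatSegment:
    """A 200-sample baseline-corrected heartbeat with its label."""

    record_id: str
    r_index: int
    samples: np.ndarray
    label: AAMIClass

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (SEGMENT_LENGTH,):
            raise ValueError(
                f"segment must have exactly {SEGMENT_LENGTH} samples, "
                f"got {self.samples.shape}"
            )


def median_window_samples(width_ms: float, fs: float) -> int:
    """Window width in samples for a median filter of ``width_ms``.

    Rounded to the nearest sample count, then incremented by one if even so
    the median is always an actual signal sample (odd window).  At 360 Hz
    this gives 73 samples for 200 ms and 217 for 600 ms.
    """
    w = int(round(width_ms * fs / 1000.0))
    return w + 1 if w % 2 == 0 else w


def estimate_baseline(signal: np.ndarray, fs: float) -> np.ndarray:
    """Estimate baseline wander with cascaded 200-ms / 600-ms median filters.

    Each pass uses reflect (mirror) padding of half the window at both ends,
    avoiding the edge dips zero padding would produce.  Output has the same
    length as the input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    windows = [median_window_samples(ms, fs) for ms in BASELINE_WINDOW_MS]
    if signal.size < max(windows):
        raise ValueError(
            f"signal of length {signal.size} is shorter than the "
            f"{max(windows)}-sample median window"
        )
    baseline = signal
    for w in windows:
        baseline = median_filter(baseline, size=w, mode="reflect")
    return baseline


def remove_baseline(signal: np.ndarray, fs: float) -> np.ndarray:
    """Return ``signal - estimate_baseline(signal, fs)``."""
    signal = np.asarray(signal, dtype=float)
    return signal - estimate_baseline(signal, fs)


def segment_heartbeats(
    signal: np.ndarray,
    annotations: Sequence[tuple[int, AAMIClass]],
    pre: int = SEGMENT_PRE,
    post: int = SEGMENT_POST,
    record_id: str = "",
) -> tuple[list[BeatSegment], int]:
    """Cut one fixed-width segment per annotated beat.

    Parameters
    ----------
    signal
        Baseline-corrected single-lead signal.
    annotations
        (r_index, AAMIClass) pairs; excluded beats must already be removed.
    pre, post
        Samples kept before / after (and including) the R peak; must sum to
        the fixed network input length of 200.
    record_id
        Carried through onto each :class:`BeatSegment`.

    Returns
    -------
    (segments, n_dropped) where segments hold ``signal[r-pre : r+post)`` for
    every beat fully inside the record, and ``n_dropped`` counts beats too
    close to an edge.  ``len(segments) + n_dropped == len(annotations)``.
    """
    if pre + post != SEGMENT_LENGTH:
        raise ValueError(
            f"pre + post must equal {SEGMENT_LENGTH} (the network input "
            f"length); got {pre} + {post}"
        )
    signal = np.asarray(signal, dtype=float)
    segments: list[BeatSegment] = []
    n_dropped = 0
    for r, label in annotations:
        r = int(r)
        if r - pre < 0 or r + post > signal.size:
            n_dropped += 1
            continue
        segments.append(
            BeatSegment(record_id, r, signal[r - pre : r + post].copy(), AAMIClass(label))
        )
    return segments, n_dropped
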