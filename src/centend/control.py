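"""Control-task metrics: pointing execution error and rhythm variability.

Both control tasks check that group differences in the main tasks are not
motor in origin.  Pointing error is the Euclidean distance between target
and touch; rhythm variability is the population standard deviation (N
denominator) of the inter-keypress intervals produced while following a
paced visual rhythm.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pointing_error",
    "pointing_errors",
    "summarize_pointing",
    "rhythm_variability",
    "intervals_from_timestamps",
]


def pointing_error(target_xy, touch_xy) -> float:
    """Euclidean distance (cm) between the dot centre and the touch point."""
    tx, ty = (float(v) for v in target_xy)
    rx, ry = (float(v) for v in touch_xy)
    if not all(np.isfinite([tx, ty, rx, ry])):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(rx - tx, ry - ty))


def pointing_errors(targets, touches) -> np.ndarray:
    """Per-trial pointing errors for arrays of shape (n, 2)."""
    targets = np.asarray(targets, dtype=float)
    touches = np.asarray(touches, dtype=float)
    if targets.shape != touches.shape or targets.ndim != 2 or targets.shape[1] != 2:
        raise ValueError("targets and touches must both have shape (n, 2)")
    if not (np.isfinite(targets).all() and np.isfinite(touches).all()):
        raise ValueError("coordinates must be finite")
    d = touches - targets
    return np.hypot(d[:, 0], d[:, 1])


def summarize_pointing(targets, touches) -> float:
    """Participant-level pointing summary: the median trial error.

    The median is used (rather than the mean) because group comparisons of
    this metric are rank-based (Mann-Whitney).
    """
    return float(np.median(pointing_errors(targets, touches)))


def intervals_from_timestamps(timestamps) -> np.ndarray:
    """Inter-keypress intervals from a sorted series of press times (s)."""
    t = np.asarray(timestamps, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need at least 3 timestamps to form 2 intervals")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return np.diff(t)


def rhythm_variability(intervals) -> float:
    """Population SD (N denominator) of the inter-keypress intervals (s)."""
    x = np.asarray(intervals, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 intervals")
    if np.any(x <= 0):
        raise ValueError("intervals must be positive")
    return float(np.std(x))  # ddof=0: the N-denominator form
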