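"""Temporal filtering of extent series: moving median + cubic-spline smoothing."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import DIRECTIONS, ExtentSeries

__all__ = ["SmoothedSeries", "moving_median", "spline_smooth", "smooth_series"]


def moving_median(values, window: int = 30) -> np.ndarray:
    """Centered moving median with symmetrically shrinking boundary windows.

    An even window uses the mean of the two central order statistics.  The
    window around index ``i`` nominally spans ``[i - (window-1)//2,
    i + window//2]``; where that would leave the series, both arms shrink to
    the largest centered window that fits, so the output has the input's
    length, no padding is invented, and boundary samples stay close to the
    input (the first and last samples are returned unchanged).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty 1-D series")
    left = (window - 1) // 2
    right = window // 2
    n = x.size
    out = np.empty(n)
    for i in range(n):
        if i >= left and i + right < n:
            lo, hi = i - left, i + right + 1
        else:
            arm = min(i, n - 1 - i, max(left, right))
            lo, hi = i - arm, i + arm + 1
        out[i] = np.median(x[lo:hi])
    return out


def spline_smooth(
    values,
    knot_stride: int = 5,
    time_s=None,
    clamp_nonnegative: bool = True,
) -> np.ndarray:
    """Cubic-spline smoothing through every ``knot_stride``-th point.

    Knots are the subsampled grid points (endpoints always included); the
    spline interpolates the knots exactly, is C2-continuous between them and
    is evaluated back on the full grid.  Not-a-knot end conditions are used so
    polynomials up to cubic are reproduced exactly.  Values are clamped at 0
    unless ``clamp_nonnegative`` is disabled.
    """
    if knot_stride < 1:
        raise ValueError(f"knot_stride must be >= 1, got {knot_stride}")
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1-D series")
    t = np.arange(y.size, dtype=float) if time_s is None else np.asarray(time_s, float)
    if t.shape != y.shape:
        raise ValueError("time axis and values must have equal length")
    idx = np.arange(0, y.size, knot_stride)
    if idx[-1] != y.size - 1:
        idx = np.append(idx, y.size - 1)
    if idx.size < 4:
        raise ValueError(
            f"only {idx.size} knots at stride {knot_stride}; use a smaller stride"
        )
    spline = CubicSpline(t[idx], y[idx])  # not-a-knot ends: exact on cubics
    out = spline(t)
    if clamp_nonnegative:
        out = np.maximum(out, 0.0)
    return out


@dataclass
class SmoothedSeries(ExtentSeries):
    """An extent series after median filtering and spline smoothing."""

    median_window: int = 30
    knot_stride: int = 5


def smooth_series(
    series: ExtentSeries,
    window: int = 30,
    knot_stride: int = 5,
) -> SmoothedSeries:
    """Apply the moving median then the spline to every present direction."""
    fields = {}
    for d in DIRECTIONS:
        arr = getattr(series, d)
        if arr is None:
            fields[d] = None
            continue
        med = moving_median(arr, window=window)
        fields[d] = spline_smooth(med, knot_stride=knot_stride, time_s=series.time_s)
    return SmoothedSeries(
        time_s=series.time_s,
        fps=series.fps,
        subject_id=series.subject_id,
        task_id=series.task_id,
        median_window=window,
        knot_stride=knot_stride,
        **fields,
    )
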