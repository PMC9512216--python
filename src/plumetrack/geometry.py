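"""Pixel-to-metric calibration and directional extent extraction.

Axis convention (0-based pixel coordinates, row 0 at the top):

* ``C1_side``  — columns carry the frontal x direction (increasing col =
  away from the subject), rows carry the vertical z direction (up =
  decreasing row).
* ``C3_top``   — columns carry x, rows carry the lateral y direction,
  symmetric about the mouth row; y is reported as a total diameter.

Frontal and vertical extents are one-sided distances from the mouth origin;
pixels behind the mouth are ignored (clamped at 0).  Diameters use inclusive
pixel spans (+1 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .segmentation import CloudMask

__all__ = [
    "ViewCalibration",
    "ExtentSeries",
    "calibrate_view",
    "extract_extents",
    "align_to_task_end",
    "merge_views",
    "save_extents_csv",
    "load_extents_csv",
]

#: physical directions measured by each view
VIEW_DIRECTIONS = {
    "C1_side": ("x_front", "z_up", "z_down"),
    "C3_top": ("y_diameter",),
}

DIRECTIONS = ("x_front", "y_diameter", "z_up", "z_down")


@dataclass(frozen=True)
class ViewCalibration:
    """Metric scale and mouth origin for one camera view."""

    view_id: str
    metres_per_pixel_h: float  # along columns
    metres_per_pixel_v: float  # along rows
    origin_px: Tuple[int, int]  # (row, col) of the mouth

    def __post_init__(self) -> None:
        if self.view_id not in VIEW_DIRECTIONS:
            raise ValueError(f"unknown view_id {self.view_id!r}")
        if self.metres_per_pixel_h <= 0 or self.metres_per_pixel_v <= 0:
            raise ValueError("metres-per-pixel values must be > 0")


@dataclass
class ExtentSeries:
    """Per-frame metric cloud extents; directions a view does not carry are None."""

    time_s: np.ndarray
    fps: float
    x_front: Optional[np.ndarray] = None
    y_diameter: Optional[np.ndarray] = None
    z_up: Optional[np.ndarray] = None
    z_down: Optional[np.ndarray] = None
    subject_id: str = "S1"
    task_id: str = "T1"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        n = len(self.time_s)
        for name in DIRECTIONS:
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != time axis {n}")
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} contains negative extents")
            setattr(self, name, arr)
        if n > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, 1.0 / self.fps, atol=1e-9):
                raise ValueError("time axis must be uniform at 1/fps")

    def __len__(self) -> int:
        return len(self.time_s)

    def directions(self) -> List[str]:
        return [d for d in DIRECTIONS if getattr(self, d) is not None]

    def value_at(self, direction: str, t: float) -> float:
        """Nearest-grid-sample lookup (within half a frame)."""
        arr = getattr(self, direction)
        if arr is None:
            raise ValueError(f"direction {direction!r} absent from this series")
        i = int(np.argmin(np.abs(self.time_s - t)))
        if abs(self.time_s[i] - t) > 0.5 / self.fps + 1e-9:
            raise ValueError(
                f"timepoint {t} s outside series range for subject "
                f"{self.subject_id!r} task {self.task_id!r}"
            )
        return float(arr[i])

    def to_frame(self):
        import pandas as pd

        data = {"subject": self.subject_id, "task": self.task_id, "time_s": self.time_s}
        for d in DIRECTIONS:
            arr = getattr(self, d)
            data[f"{d}_m"] = arr if arr is not None else np.nan
        return pd.DataFrame(data)


def _bar_axis(p1: Tuple[float, float], p2: Tuple[float, float], tol_deg: float = 10.0):
    """Classify a bar as 'h' (along columns) or 'v' (along rows), else None."""
    dr = p2[0] - p1[0]
    dc = p2[1] - p1[1]
    length = math.hypot(dr, dc)
    if length == 0:
        raise ValueError(f"scale bar with coincident endpoints {p1}")
    angle = math.degrees(math.atan2(abs(dr), abs(dc)))
    if angle <= tol_deg:
        return "h", length
    if angle >= 90.0 - tol_deg:
        return "v", length
    return None, length


def calibrate_view(
    scale_bars: Sequence[Tuple[Tuple[float, float], Tuple[float, float], float]],
    view_id: str,
    origin_px: Tuple[int, int],
) -> ViewCalibration:
    """Derive metres-per-pixel per image axis from scale bars.

    Each bar is ``((r1, c1), (r2, c2), known_length_m)``.  Bars aligned within
    10 degrees of an image axis contribute ``known_length / pixel_length`` to
    that axis; multiple bars per axis are averaged.
    """
    per_axis = {"h": [], "v": []}
    for p1, p2, length_m in scale_bars:
        if length_m <= 0:
            raise ValueError(f"scale bar length must be > 0, got {length_m}")
        axis, px = _bar_axis(tuple(p1), tuple(p2))
        if axis is not None:
            per_axis[axis].append(length_m / px)
    missing = [a for a in ("h", "v") if not per_axis[a]]
    if missing:
        raise ValueError(
            f"no usable scale bar for image axis/axes {missing} in view {view_id!r}"
        )
    return ViewCalibration(
        view_id=view_id,
        metres_per_pixel_h=float(np.mean(per_axis["h"])),
        metres_per_pixel_v=float(np.mean(per_axis["v"])),
        origin_px=tuple(origin_px),
    )


def extract_extents(masks: CloudMask, cal: ViewCalibration) -> ExtentSeries:
    """Per-frame maximum metric extents from the mouth origin.

    Fills only the directions the view carries; empty masks give 0.
    """
    if masks.view_id != cal.view_id:
        raise ValueError(
            f"mask view {masks.view_id!r} does not match calibration {cal.view_id!r}"
        )
    o_r, o_c = cal.origin_px
    n = len(masks)
    time_s = np.arange(n) / masks.fps
    fields = {d: np.zeros(n) for d in VIEW_DIRECTIONS[cal.view_id]}
    for k in range(n):
        rows, cols = np.nonzero(masks.masks[k])
        if rows.size == 0:
            continue
        if cal.view_id == "C1_side":
            fields["x_front"][k] = max(int(cols.max()) - o_c, 0) * cal.metres_per_pixel_h
            fields["z_up"][k] = max(o_r - int(rows.min()), 0) * cal.metres_per_pixel_v
            fields["z_down"][k] = max(int(rows.max()) - o_r, 0) * cal.metres_per_pixel_v
        else:  # C3_top: inclusive lateral span
            fields["y_diameter"][k] = (
                int(rows.max()) - int(rows.min()) + 1
            ) * cal.metres_per_pixel_v
    return ExtentSeries(
        time_s=time_s,
        fps=masks.fps,
        subject_id=masks.subject_id,
        task_id=masks.task_id,
        **fields,
    )


def align_to_task_end(series: ExtentSeries, task_end_frame: int) -> ExtentSeries:
    """Re-index time so that t = 0 is the task-end frame (idempotent)."""
    n = len(series)
    if not 0 <= task_end_frame < n:
        raise ValueError(f"task_end_frame {task_end_frame} outside [0, {n})")
    time_s = (np.arange(n) - task_end_frame) / series.fps
    return replace(series, time_s=time_s)


def merge_views(
    side: Optional[ExtentSeries], top: Optional[ExtentSeries]
) -> ExtentSeries:
    """Combine x/z from the side view with the y diameter from the top view.

    Works on the intersected time range; a missing view leaves its directions
    absent (None), matching a camera dropped from analysis.
    """
    present = [s for s in (side, top) if s is not None]
    if not present:
        raise ValueError("at least one view is required")
    if len(present) == 2:
        if side.fps != top.fps:
            raise ValueError(f"fps mismatch: side {side.fps} vs top {top.fps}")
        if (side.subject_id, side.task_id) != (top.subject_id, top.task_id):
            raise ValueError("views belong to different subject/task")
        t0 = max(side.time_s[0], top.time_s[0])
        t1 = min(side.time_s[-1], top.time_s[-1])
        if t1 < t0 - 1e-9:
            raise ValueError("views have no overlapping time range")

        def window(s: ExtentSeries) -> slice:
            k0 = int(round((t0 - s.time_s[0]) * s.fps))
            k1 = int(round((t1 - s.time_s[0]) * s.fps))
            return slice(k0, k1 + 1)

        ws, wt = window(side), window(top)
        return ExtentSeries(
            time_s=side.time_s[ws],
            fps=side.fps,
            x_front=None if side.x_front is None else side.x_front[ws],
            z_up=None if side.z_up is None else side.z_up[ws],
            z_down=None if side.z_down is None else side.z_down[ws],
            y_diameter=None if top.y_diameter is None else top.y_diameter[wt],
            subject_id=side.subject_id,
            task_id=side.task_id,
        )
    only = present[0]
    keep = ("x_front", "z_up", "z_down") if only is side else ("y_diameter",)
    return ExtentSeries(
        time_s=only.time_s,
        fps=only.fps,
        subject_id=only.subject_id,
        task_id=only.task_id,
        **{d: getattr(only, d) for d in keep},
    )


def save_extents_csv(series: Sequence[ExtentSeries], path) -> None:
    """Write one or more extent series to a tidy CSV."""
    import pandas as pd

    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, index=False
    )


def load_extents_csv(path) -> List[ExtentSeries]:
    """Read a tidy extents CSV back into per-(subject, task) series."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for (subject, task), grp in df.groupby(["subject", "task"], sort=True):
        grp = grp.sort_values("time_s")
        time = grp["time_s"].to_numpy()
        dt = np.diff(time)
        if len(time) > 1 and not np.allclose(dt, dt[0]):
            raise ValueError(f"non-uniform time axis for {subject}/{task}")
        fps = 1.0 / dt[0] if len(time) > 1 else 25.0
        fields = {}
        for d in DIRECTIONS:
            col = grp[f"{d}_m"].to_numpy()
            fields[d] = None if np.all(np.isnan(col)) else col
        out.append(
            ExtentSeries(
                time_s=time,
                fps=fps,
                subject_id=str(subject),
                task_id=str(task),
                **fields,
            )
        )
    return out
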