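"""Per-frame binary segmentation of the bright vapor cloud."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _label

from .frames import FrameSequence

__all__ = ["CloudMask", "segment_cloud"]


@dataclass
class CloudMask:
    """Binary cloud masks aligned with a frame sequence."""

    masks: np.ndarray  # (n, rows, cols) bool
    threshold_used: np.ndarray  # per-frame intensity threshold
    min_component_area_px: int
    fps: float
    view_id: str
    task_end_frame: int
    subject_id: str = "S1"
    task_id: str = "T1"

    def __len__(self) -> int:
        return len(self.masks)

    def area_px(self) -> np.ndarray:
        return self.masks.sum(axis=(1, 2))


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components smaller than min_area; keep the rest.

    All surviving components are treated as one cloud.
    """
    if min_area <= 1 or not mask.any():
        return mask
    labels = _label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def segment_cloud(
    seq: FrameSequence,
    threshold: Union[float, str] = "otsu",
    min_component_area_px: int = 20,
    min_threshold: int = 64,
    polarity: str = "bright",
) -> CloudMask:
    """Threshold every frame and remove small connected components.

    A pixel belongs to the cloud iff its intensity is >= threshold (polarity
    ``"bright"``; for negative footage use ``"dark"``, i.e. <= threshold) and
    its 8-connected component covers at least ``min_component_area_px``
    pixels.  ``threshold="otsu"`` picks a per-frame Otsu threshold clamped
    below at ``min_threshold`` so near-empty frames stay empty.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    use_otsu = isinstance(threshold, str)
    if use_otsu:
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
    else:
        if not 0 <= threshold <= 255:
            raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    if min_component_area_px < 0:
        raise ValueError("min_component_area_px must be >= 0")

    n = len(seq)
    out = np.empty_like(seq.frames, dtype=bool)
    used = np.empty(n, dtype=float)
    for k in range(n):
        frame = seq.frames[k]
        if use_otsu:
            if frame.min() == frame.max():
                # uniform frame: no contrast, treat as background
                t = 256.0 if polarity == "bright" else -1.0
            else:
                t = float(threshold_otsu(frame))
                if polarity == "bright":
                    t = max(t, float(min_threshold))
                else:
                    t = min(t, 255.0 - float(min_threshold))
        else:
            t = float(threshold)
        raw = frame >= t if polarity == "bright" else frame <= t
        out[k] = _remove_small(raw, min_component_area_px)
        used[k] = t
    return CloudMask(
        masks=out,
        threshold_used=used,
        min_component_area_px=min_component_area_px,
        fps=seq.fps,
        view_id=seq.view_id,
        task_end_frame=seq.task_end_frame,
        subject_id=seq.subject_id,
        task_id=seq.task_id,
    )
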