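"""Frame-stack I/O, negative conversion and exclusion masking."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import polygon as _draw_polygon
from skimage.draw import polygon_perimeter as _draw_perimeter

__all__ = [
    "FrameSequence",
    "ExclusionMask",
    "load_frames",
    "write_frames",
    "to_negative_bw",
    "rasterize_masks",
    "apply_exclusion_masks",
    "mask_sequence",
    "estimate_background_fill",
    "load_masks_json",
    "save_masks_json",
]

VIEW_IDS = ("C1_side", "C3_top")
_IMAGE_EXTS = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


@dataclass
class FrameSequence:
    """Ordered 8-bit grayscale frames for one view of one task."""

    frames: np.ndarray  # (n, rows, cols) uint8
    fps: float
    view_id: str
    task_end_frame: int
    subject_id: str = "S1"
    task_id: str = "T1"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) stack")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("frame intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not 0 <= self.task_end_frame < len(self.frames):
            raise ValueError(
                f"task_end_frame {self.task_end_frame} outside [0, {len(self.frames)})"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.fps

    def replace_frames(self, frames: np.ndarray) -> "FrameSequence":
        return FrameSequence(
            frames=frames,
            fps=self.fps,
            view_id=self.view_id,
            task_end_frame=self.task_end_frame,
            subject_id=self.subject_id,
            task_id=self.task_id,
        )


@dataclass
class ExclusionMask:
    """Pixel polygons to exclude from segmentation for one view.

    Polygons are closed rings of (x, y) = (col, row) vertices; the even-odd
    rule decides interior membership and boundary pixels count as inside.
    """

    view_id: str
    polygons: List[Sequence[Tuple[float, float]]]
    role: str = "body"  # body | funnel_release | reflection

    def __post_init__(self) -> None:
        for poly in self.polygons:
            if len(poly) < 3:
                raise ValueError("each polygon needs at least 3 vertices")


def _to_luma(img: np.ndarray) -> np.ndarray:
    """Rec.601 luma, rounded to uint8."""
    if img.ndim == 2:
        return img.astype(np.uint8)
    rgb = img[..., :3].astype(float)
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def load_frames(
    path,
    fps: float = 25.0,
    view_id: str = "C1_side",
    task_end_frame: int = 0,
    subject_id: str = "S1",
    task_id: str = "T1",
) -> FrameSequence:
    """Load a frame stack from a directory of images or an AVI file.

    Directory frames are taken in filename-lexicographic order; colour input
    is converted to Rec.601 luma.  All frames must share one size.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise ValueError(f"no image frames found in {path}")
        frames = []
        shape = None
        for f in files:
            img = _to_luma(iio.imread(f))
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"frame {f.name} has shape {img.shape}, expected {shape}"
                )
            frames.append(img)
        stack = np.stack(frames)
    elif path.suffix.lower() == ".avi":
        try:
            raw = iio.imread(path, plugin="pyav")
        except Exception:
            try:
                raw = iio.imread(path)
            except Exception as exc:  # pragma: no cover - depends on codecs
                raise ValueError(
                    f"could not decode {path}; install an imageio ffmpeg/pyav plugin"
                ) from exc
        stack = np.stack([_to_luma(fr) for fr in raw])
    else:
        raise ValueError(f"{path} is neither a frame directory nor an .avi file")
    return FrameSequence(
        frames=stack,
        fps=fps,
        view_id=view_id,
        task_end_frame=task_end_frame,
        subject_id=subject_id,
        task_id=task_id,
    )


def write_frames(seq: FrameSequence, out_dir) -> List[Path]:
    """Write frames as PNG files named frame_000001.png, ..."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq.frames, start=1):
        p = out_dir / f"frame_{i:06d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def to_negative_bw(frame: np.ndarray) -> np.ndarray:
    """Photographic negative: i' = 255 - i (involution)."""
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise ValueError("expected an 8-bit grayscale frame")
    return (255 - frame).astype(np.uint8)


def rasterize_masks(
    masks: Sequence[ExclusionMask], frame_shape: Tuple[int, int]
) -> np.ndarray:
    """Boolean raster of the union of all polygons (boundary pixels inside)."""
    rows, cols = frame_shape
    out = np.zeros(frame_shape, dtype=bool)
    for mask in masks:
        for poly in mask.polygons:
            xs = np.asarray([p[0] for p in poly], dtype=float)
            ys = np.asarray([p[1] for p in poly], dtype=float)
            if (xs < 0).any() or (xs > cols - 1).any() or (ys < 0).any() or (ys > rows - 1).any():
                raise ValueError(
                    f"polygon vertex outside frame bounds {frame_shape} "
                    f"(role={mask.role!r}, view={mask.view_id!r})"
                )
            rr, cc = _draw_polygon(ys, xs, shape=frame_shape)
            out[rr, cc] = True
            rr, cc = _draw_perimeter(
                np.rint(ys).astype(int), np.rint(xs).astype(int), shape=frame_shape
            )
            out[rr, cc] = True
    return out


def estimate_background_fill(frame: np.ndarray, patch: int = 10) -> int:
    """Modal intensity over the four corner patches of a frame."""
    rows, cols = frame.shape
    p = min(patch, rows, cols)
    corners = np.concatenate(
        [
            frame[:p, :p].ravel(),
            frame[:p, -p:].ravel(),
            frame[-p:, :p].ravel(),
            frame[-p:, -p:].ravel(),
        ]
    )
    return int(np.bincount(corners, minlength=256).argmax())


def apply_exclusion_masks(
    frame: np.ndarray,
    masks: Sequence[ExclusionMask],
    fill: Optional[int] = None,
) -> np.ndarray:
    """Set pixels inside any exclusion polygon to ``fill``.

    With ``fill=None`` the modal corner background of the frame is used, which
    guarantees masked regions never segment as cloud.
    """
    frame = np.asarray(frame)
    if not masks:
        return frame.copy()
    if fill is None:
        fill = estimate_background_fill(frame)
    raster = rasterize_masks(masks, frame.shape)
    out = frame.copy()
    out[raster] = fill
    return out


def mask_sequence(
    seq: FrameSequence,
    masks: Sequence[ExclusionMask],
    fill: Optional[int] = None,
) -> FrameSequence:
    """Apply exclusion masks to every frame of a sequence."""
    relevant = [m for m in masks if m.view_id == seq.view_id]
    if not relevant:
        return seq.replace_frames(seq.frames.copy())
    if fill is None:
        fill = estimate_background_fill(seq.frames[0])
    raster = rasterize_masks(relevant, seq.frame_shape)
    frames = seq.frames.copy()
    frames[:, raster] = fill
    return seq.replace_frames(frames)


def save_masks_json(masks: Sequence[ExclusionMask], path) -> None:
    payload = [
        {
            "view": m.view_id,
            "role": m.role,
            "polygons": [[[float(x), float(y)] for x, y in poly] for poly in m.polygons],
        }
        for m in masks
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_masks_json(path) -> List[ExclusionMask]:
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, dict):
        payload = [payload]
    return [
        ExclusionMask(
            view_id=entry["view"],
            role=entry.get("role", "body"),
            polygons=[[(x, y) for x, y in poly] for poly in entry["polygons"]],
        )
        for entry in payload
    ]
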