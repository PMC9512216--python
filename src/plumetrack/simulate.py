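"""Synthetic two-view plume footage with analytic ground truth.

Renders an expanding bright blob emitted from a fixed mouth origin: the side
view carries columns -> frontal x and rows -> vertical z (up = decreasing
row), the top view carries columns -> frontal x and rows -> lateral y
(symmetric about the origin row).  Directional extents follow an
exponential-rise-then-drift curve, so every downstream measurement can be
checked against a closed form.  Optional artifacts (body silhouette, floor
reflection, funnel-released cloud) are placed strictly inside declared
exclusion polygons so that masking restores the clean measurement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .frames import ExclusionMask, FrameSequence

__all__ = [
    "ExpansionParams",
    "PlumeScenario",
    "GroundTruth",
    "generate_plume_scenario",
    "generate_tone_audio",
]

#: one-sided physical directions parameterised by the truth curves
PARAM_DIRECTIONS = ("x_front", "y_half", "z_up", "z_down")


@dataclass(frozen=True)
class ExpansionParams:
    """Parameters of one directional extent curve.

    The extent in metres at time ``t`` (seconds relative to task end) is

        d(t) = A * (1 - exp(-(t + task_duration) / tau))   for t <= 0
        d(t) = d(0) + drift * t                            for t > 0
    """

    A: float = 0.0
    tau: float = 2.0
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"asymptote A must be >= 0, got {self.A}")
        if self.tau <= 0:
            raise ValueError(f"time constant tau must be > 0, got {self.tau}")

    def extent(self, t: np.ndarray, task_duration_s: float) -> np.ndarray:
        """Evaluate the extent curve in metres on a time grid."""
        t = np.asarray(t, dtype=float)
        rise = self.A * (1.0 - np.exp(-(t + task_duration_s) / self.tau))
        d0 = self.A * (1.0 - np.exp(-task_duration_s / self.tau))
        return np.where(t <= 0.0, np.maximum(rise, 0.0), d0 + self.drift * t)


@dataclass
class PlumeScenario:
    """Full description of one synthetic recording (both views + audio-free)."""

    expansion_params: Dict[str, ExpansionParams] = field(default_factory=dict)
    task_duration_s: float = 8.0
    post_task_s: float = 10.0
    fps: float = 25.0
    frame_size_px: Tuple[int, int] = (180, 320)  # (rows, cols), both views
    side_origin_px: Tuple[int, int] = (90, 40)  # (row, col) of the mouth
    top_origin_px: Tuple[int, int] = (90, 40)
    metres_per_pixel: float = 0.01
    noise_sd: float = 0.0
    reflection_artifacts: bool = False
    body_silhouette: bool = False
    funnel_release: bool = False
    background: int = 20
    plume_intensity: int = 220
    subject_id: str = "S1"
    task_id: str = "T3"
    seed: int = 0

    # -- derived quantities ------------------------------------------------

    @property
    def task_end_frame(self) -> int:
        return int(round(self.task_duration_s * self.fps))

    @property
    def n_frames(self) -> int:
        return self.task_end_frame + int(round(self.post_task_s * self.fps)) + 1

    def time_grid(self) -> np.ndarray:
        """Frame times in seconds, t = 0 at the task-end frame."""
        return (np.arange(self.n_frames) - self.task_end_frame) / self.fps

    def params(self, direction: str) -> ExpansionParams:
        return self.expansion_params.get(direction, ExpansionParams())

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.metres_per_pixel <= 0:
            raise ValueError("metres_per_pixel must be > 0")
        if self.task_duration_s <= 0 or self.post_task_s < 0:
            raise ValueError("task_duration_s must be > 0 and post_task_s >= 0")
        rows, cols = self.frame_size_px
        for origin, label in ((self.side_origin_px, "side"), (self.top_origin_px, "top")):
            if not (0 <= origin[0] < rows and 0 <= origin[1] < cols):
                raise ValueError(f"{label} origin {origin} outside frame {self.frame_size_px}")
        for key in self.expansion_params:
            if key not in PARAM_DIRECTIONS:
                raise ValueError(
                    f"unknown direction {key!r}; expected one of {PARAM_DIRECTIONS}"
                )
        self._check_bounds()

    def _check_bounds(self) -> None:
        """Reject scenarios whose physical extents map outside the frame."""
        t = self.time_grid()
        mpp = self.metres_per_pixel
        rows, cols = self.frame_size_px
        limits = {
            "x_front": cols - 1 - self.side_origin_px[1],
            "z_up": self.side_origin_px[0],
            "z_down": rows - 1 - self.side_origin_px[0],
            "y_half": min(self.top_origin_px[0], rows - 1 - self.top_origin_px[0]),
        }
        if self.funnel_release or self.reflection_artifacts:
            # keep the plume clear of the fixed artifact bands (see _artifacts)
            limits["z_up"] = min(limits["z_up"], self.side_origin_px[0] - 22)
            limits["z_down"] = min(limits["z_down"], rows - 1 - self.side_origin_px[0] - 22)
            limits["y_half"] = min(limits["y_half"], rows - 1 - self.top_origin_px[0] - 22)
        for direction in PARAM_DIRECTIONS:
            extent_px = self.params(direction).extent(t, self.task_duration_s) / mpp
            over = np.nonzero(extent_px > limits[direction])[0]
            if over.size:
                raise ValueError(
                    f"extent in direction {direction!r} leaves the frame at "
                    f"frame {over[0]} ({extent_px[over[0]]:.1f} px > {limits[direction]} px)"
                )

    # -- declared artifact geometry ---------------------------------------

    def _artifacts(self, view_id: str) -> List[dict]:
        """Ellipse artifacts for a view: (role, center, semi_r, semi_c, value)."""
        rows, cols = self.frame_size_px
        out: List[dict] = []
        if view_id == "C1_side":
            o_r, o_c = self.side_origin_px
            if self.body_silhouette:
                c = max(12, o_c - 28)
                if c + 10 >= o_c:
                    raise ValueError("no room for body silhouette behind the origin")
                out.append(dict(role="body", center=(o_r, c), semi=(18, 10), value=200))
            if self.reflection_artifacts:
                out.append(
                    dict(
                        role="reflection",
                        center=(rows - 10, min(o_c + 40, cols - 30)),
                        semi=(6, 24),
                        value=160,
                    )
                )
            if self.funnel_release:
                out.append(
                    dict(
                        role="funnel_release",
                        center=(10, min(o_c + 60, cols - 30)),
                        semi=(6, 24),
                        value=200,
                    )
                )
        elif view_id == "C3_top":
            o_r, o_c = self.top_origin_px
            if self.body_silhouette:
                c = max(12, o_c - 28)
                if c + 10 >= o_c:
                    raise ValueError("no room for body silhouette behind the origin")
                out.append(dict(role="body", center=(o_r, c), semi=(18, 10), value=200))
            if self.funnel_release:
                out.append(
                    dict(
                        role="funnel_release",
                        center=(rows - 10, min(o_c + 60, cols - 30)),
                        semi=(6, 24),
                        value=200,
                    )
                )
        else:
            raise ValueError(f"unknown view_id {view_id!r}")
        return out

    def exclusion_masks(self, view_id: str) -> List[ExclusionMask]:
        """Rectangular exclusion polygons enclosing every artifact (3 px margin)."""
        masks = []
        rows, cols = self.frame_size_px
        for art in self._artifacts(view_id):
            r, c = art["center"]
            sr, sc = art["semi"]
            x0, x1 = max(c - sc - 3, 0), min(c + sc + 3, cols - 1)
            y0, y1 = max(r - sr - 3, 0), min(r + sr + 3, rows - 1)
            masks.append(
                ExclusionMask(
                    view_id=view_id,
                    role=art["role"],
                    polygons=[[(x0, y0), (x1, y0), (x1, y1), (x0, y1)]],
                )
            )
        return masks

    def scale_bars(self, view_id: str) -> List[Tuple[Tuple[int, int], Tuple[int, int], float]]:
        """Synthetic calibration bars: ((r1, c1), (r2, c2), known_length_m)."""
        rows, cols = self.frame_size_px
        h_len = min(100, cols - 20)
        v_len = min(100, rows - 20)
        if h_len < 2 or v_len < 2:
            raise ValueError("frame too small for scale bars")
        return [
            ((5, 10), (5, 10 + h_len), h_len * self.metres_per_pixel),
            ((10, cols - 6), (10 + v_len, cols - 6), v_len * self.metres_per_pixel),
        ]


@dataclass
class GroundTruth:
    """Analytic extent curves on the frame time grid (t = 0 at task end)."""

    time_s: np.ndarray
    x_front_m: np.ndarray
    y_diameter_m: np.ndarray
    z_up_m: np.ndarray
    z_down_m: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("x_front_m", "y_diameter_m", "z_up_m", "z_down_m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length mismatch")
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative extents")
            setattr(self, name, arr)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.any(np.isclose(self.time_s, 0.0)):
            raise ValueError("time axis must contain t = 0")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "x_front_m": self.x_front_m,
                "y_diameter_m": self.y_diameter_m,
                "z_up_m": self.z_up_m,
                "z_down_m": self.z_down_m,
            }
        )

    def at(self, t: float) -> Dict[str, float]:
        i = int(np.argmin(np.abs(self.time_s - t)))
        return {
            "x_front": float(self.x_front_m[i]),
            "y_diameter": float(self.y_diameter_m[i]),
            "z_up": float(self.z_up_m[i]),
            "z_down": float(self.z_down_m[i]),
        }


def _axis_term(delta: np.ndarray, semi_px: float) -> np.ndarray:
    """Normalised squared coordinate for an ellipse test; semi 0 => degenerate."""
    if semi_px <= 0:
        return np.where(delta == 0, 0.0, np.inf)
    return (delta / semi_px) ** 2


def _ellipse(shape, center, semi) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return (
        _axis_term(rows - center[0], semi[0]) + _axis_term(cols - center[1], semi[1])
    ) <= 1.0


def generate_plume_scenario(
    scenario: PlumeScenario,
) -> Tuple[FrameSequence, FrameSequence, GroundTruth]:
    """Render both views of a scenario and return them with the ground truth.

    The rendered maximal pixel extent from the origin along each mapped axis
    equals the truth curve to within one pixel at every frame; with the same
    seed the output is bit-identical across runs.
    """
    scenario.validate()
    t = scenario.time_grid()
    mpp = scenario.metres_per_pixel
    dur = scenario.task_duration_s

    d = {k: scenario.params(k).extent(t, dur) for k in PARAM_DIRECTIONS}
    truth = GroundTruth(
        time_s=t,
        x_front_m=d["x_front"],
        y_diameter_m=2.0 * d["y_half"],
        z_up_m=d["z_up"],
        z_down_m=d["z_down"],
    )

    rows, cols = scenario.frame_size_px
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    rng = np.random.default_rng(scenario.seed)

    def render_view(view_id: str, origin: Tuple[int, int]) -> FrameSequence:
        o_r, o_c = origin
        artifacts = scenario._artifacts(view_id)
        frames = np.empty((scenario.n_frames, rows, cols), dtype=np.uint8)
        forward = cc >= o_c
        for k in range(scenario.n_frames):
            img = np.full((rows, cols), float(scenario.background))
            ax = d["x_front"][k] / mpp
            if view_id == "C1_side":
                az_up = d["z_up"][k] / mpp
                az_dn = d["z_down"][k] / mpp
                any_extent = max(ax, az_up, az_dn) > 0
                if any_extent:
                    dz = rr - o_r
                    vert = np.where(
                        dz <= 0, _axis_term(dz, az_up), _axis_term(dz, az_dn)
                    )
                    inside = forward & (_axis_term(cc - o_c, ax) + vert <= 1.0)
                    img[inside] = scenario.plume_intensity
            else:  # C3_top
                ay = d["y_half"][k] / mpp
                if max(ax, ay) > 0:
                    inside = forward & (
                        _axis_term(cc - o_c, ax) + _axis_term(rr - o_r, ay) <= 1.0
                    )
                    img[inside] = scenario.plume_intensity
            for art in artifacts:
                img[_ellipse((rows, cols), art["center"], art["semi"])] = art["value"]
            if scenario.noise_sd > 0:
                img = img + rng.normal(0.0, scenario.noise_sd, size=img.shape)
            frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        return FrameSequence(
            frames=frames,
            fps=scenario.fps,
            view_id=view_id,
            subject_id=scenario.subject_id,
            task_id=scenario.task_id,
            task_end_frame=scenario.task_end_frame,
        )

    side = render_view("C1_side", scenario.side_origin_px)
    top = render_view("C3_top", scenario.top_origin_px)
    return side, top, truth


def generate_tone_audio(
    f0: float,
    harmonic_amplitudes,
    duration_s: float,
    fs: float = 44100.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Harmonic complex at k*f0 plus optional white noise, peak <= 1.

    ``harmonic_amplitudes[k-1]`` is the linear amplitude of the k-th harmonic.
    Harmonics with non-zero amplitude must satisfy k*f0 < fs/2.
    """
    if not 0 < f0 < fs / 2:
        raise ValueError(f"f0 must lie in (0, fs/2), got {f0}")
    if duration_s < 1.0:
        raise ValueError("duration must be >= 1 s")
    amps = np.asarray(list(harmonic_amplitudes), dtype=float)
    n = int(round(duration_s * fs))
    tt = np.arange(n) / fs
    audio = np.zeros(n)
    for k, a in enumerate(amps, start=1):
        if a == 0:
            continue
        if k * f0 >= fs / 2:
            raise ValueError(f"harmonic {k} at {k * f0:.1f} Hz aliases (fs={fs})")
        audio += a * np.sin(2 * np.pi * k * f0 * tt)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        audio = audio + rng.normal(0.0, noise_sd, size=n)
    peak = np.max(np.abs(audio)) if n else 0.0
    if peak > 1.0:
        audio = audio / peak
    return audio


def scenario_to_dict(scenario: PlumeScenario) -> dict:
    """JSON/YAML-serialisable form of a scenario."""
    out = dataclasses.asdict(scenario)
    out["expansion_params"] = {
        k: dataclasses.asdict(v) for k, v in scenario.expansion_params.items()
    }
    out["frame_size_px"] = list(scenario.frame_size_px)
    out["side_origin_px"] = list(scenario.side_origin_px)
    out["top_origin_px"] = list(scenario.top_origin_px)
    return out


def scenario_from_dict(cfg: dict) -> PlumeScenario:
    cfg = dict(cfg)
    cfg["expansion_params"] = {
        k: ExpansionParams(**v) for k, v in cfg.get("expansion_params", {}).items()
    }
    for key in ("frame_size_px", "side_origin_px", "top_origin_px"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return PlumeScenario(**cfg)
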