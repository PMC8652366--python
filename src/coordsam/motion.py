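"""Per-ROI motion-magnitude time series from video frames.

The first stage of Correlation Map Analysis: quantify how much each region
of a frame moved between consecutive frames.  The default estimator is
absolute frame differencing — per-pixel ``|I[t+1] - I[t]|`` — whose sum over
a region of interest (ROI) gives the region's total motion in pixels/frame.
A dense optical-flow estimator is available as an alternative for videos
where large coherent displacements make raw intensity change a poor proxy.

ROI coordinates are 0-based, half-open rectangles ``[x0, x1) x [y0, y1)``
with ``y`` indexing rows (row-major), fixed for the whole recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameStack",
    "ROISpec",
    "MotionSeries",
    "compute_motion_magnitude",
    "extract_roi_motion",
    "read_video",
    "write_motion_csv",
    "read_motion_csv",
]

#: Rec. 601 luminance weights used to collapse RGB frames to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStack:
    """An in-memory grayscale video: ``frames[t]`` is a 2-D intensity grid."""

    frames: np.ndarray  # (n_frames, rows, cols) float array
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 4 and self.frames.shape[-1] in (3, 4):
            self.frames = self.frames[..., :3] @ _LUMA
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, rows, cols), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a FrameStack needs at least 2 frames")
        if not np.isfinite(self.frame_rate) or self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be finite and > 0, got {self.frame_rate}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ROISpec:
    """A static rectangular region of interest, half-open in both axes."""

    label: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.label not in ("head", "body"):
            raise ValueError(f"ROI label must be 'head' or 'body', got {self.label!r}")
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"empty ROI: {self}")
        if min(self.x0, self.y0) < 0:
            raise ValueError(f"negative ROI coordinates: {self}")

    def validate_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.y1 > rows or self.x1 > cols:
            raise ValueError(f"ROI {self} exceeds frame bounds {rows}x{cols}")

    def overlaps(self, other: "ROISpec") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass
class MotionSeries:
    """Total motion inside one ROI per frame transition (pixels/frame)."""

    values: np.ndarray
    roi: ROISpec
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("MotionSeries values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MotionSeries values must be finite")
        if np.any(self.values < -1e-12):
            raise ValueError("motion magnitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def compute_motion_magnitude(
    stack: FrameStack, method: str = "framediff"
) -> np.ndarray:
    """Per-pixel motion magnitude between consecutive frames.

    Parameters
    ----------
    stack
        Grayscale frames.
    method
        ``"framediff"`` — absolute intensity difference ``|I[t+1] - I[t]|``
        (the default; exactly reproducible and oracle-checkable).
        ``"denseflow"`` — per-pixel Euclidean norm of the dense displacement
        field from iterative Lucas-Kanade optical flow (scikit-image).

    Returns
    -------
    ndarray of shape ``(n_frames - 1, rows, cols)``, all entries >= 0.
    """
    frames = stack.frames
    if method == "framediff":
        return np.abs(np.diff(frames, axis=0))
    if method == "denseflow":
        from skimage.registration import optical_flow_ilk

        out = np.empty((stack.n_frames - 1,) + stack.shape)
        for t in range(stack.n_frames - 1):
            v, u = optical_flow_ilk(frames[t], frames[t + 1])
            out[t] = np.hypot(u, v)
        return out
    raise ValueError(f"unknown motion method {method!r}")


def extract_roi_motion(
    magnitude_grids: np.ndarray,
    roi: ROISpec,
    frame_rate: float,
    detrend_mean: bool = False,
) -> MotionSeries:
    """Sum per-pixel motion magnitude over a static ROI for every transition.

    ``detrend_mean`` subtracts each grid's global mean intensity change from
    the ROI pixels before summing (rectified at zero) — a guard against
    whole-frame lighting flicker; off by default.
    """
    grids = np.asarray(magnitude_grids, dtype=float)
    if grids.ndim != 3:
        raise ValueError("magnitude_grids must be (n_transitions, rows, cols)")
    roi.validate_within(grids.shape[1:])
    patch = grids[:, roi.y0 : roi.y1, roi.x0 : roi.x1]
    if detrend_mean:
        global_mean = grids.mean(axis=(1, 2), keepdims=True)
        patch = np.clip(patch - global_mean, 0.0, None)
    values = patch.sum(axis=(1, 2))
    return MotionSeries(values=values, roi=roi, frame_rate=frame_rate)


def read_video(path: str | Path, frame_rate: float | None = None) -> FrameStack:
    """Read a video file or a directory of image frames into a FrameStack.

    A directory is read as an alphabetically sorted image sequence (useful
    for codec-free round-tripping); anything else is handed to imageio.
    Color input is collapsed to grayscale by Rec. 601 luminance weighting.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff", ".pgm"))
        if len(files) < 2:
            raise ValueError(f"frame directory {path} holds fewer than 2 frames")
        frames = np.stack([np.asarray(iio.imread(f), dtype=float) for f in files])
        if frame_rate is None:
            raise ValueError("frame_rate is required when reading an image sequence")
        return FrameStack(frames=frames, frame_rate=frame_rate)
    frames = np.asarray(iio.imread(path, index=None), dtype=float)
    if frame_rate is None:
        try:
            meta = iio.immeta(path)
            frame_rate = float(meta.get("fps", 0.0)) or None
        except Exception:
            frame_rate = None
    if frame_rate is None:
        raise ValueError(f"could not determine frame rate for {path}; pass frame_rate")
    return FrameStack(frames=frames, frame_rate=frame_rate)


def write_motion_csv(series: Iterable[MotionSeries], prefix: str | Path) -> None:
    """Write MotionSeries to ``<prefix>.csv`` with a JSON metadata sidecar."""
    prefix = Path(prefix)
    rows, meta = [], {}
    for s in series:
        for t, v in enumerate(s.values):
            rows.append({"frame_index": t, "label": s.roi.label, "value": v})
        meta[s.roi.label] = {
            "frame_rate": s.frame_rate,
            "roi": [s.roi.x0, s.roi.y0, s.roi.x1, s.roi.y1],
        }
    # %.17g guarantees exact float round-trip through text
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".csv"), index=False, float_format="%.17g")
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_motion_csv(prefix: str | Path) -> dict[str, MotionSeries]:
    """Inverse of :func:`write_motion_csv`; returns series keyed by ROI label."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    out = {}
    for label, m in meta.items():
        sub = df[df["label"] == label].sort_values("frame_index")
        roi = ROISpec(label, *(int(c) for c in m["roi"]))
        out[label] = MotionSeries(
            values=sub["value"].to_numpy(), roi=roi, frame_rate=float(m["frame_rate"])
        )
    return out
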