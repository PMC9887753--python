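"""Reading image stacks and traces; ROI extraction with background subtraction.

Conventions used throughout the package:

* pixel coordinates are 0-based;
* rectangles are half-open, ``[x0, x1) x [y0, y1)`` with x = column, y = row;
* the background is estimated and subtracted *per frame* (this also cancels
  slow illumination drift), never as a single global constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import GeometryError, TraceFormatError

__all__ = [
    "ImageStack",
    "Roi",
    "FluorescenceTrace",
    "read_stack",
    "write_stack",
    "extract_trace",
    "read_trace_csv",
    "write_trace_csv",
    "roi_from_json",
    "roi_to_json",
]


@dataclass
class ImageStack:
    """An ordered stack of single-channel frames with a fixed frame interval.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``.
    frame_interval
        Seconds between consecutive frames (> 0).
    metadata
        Free-form key/value pairs (acquisition info, provenance).
    """

    frames: np.ndarray
    frame_interval: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise GeometryError(
                f"frames must be a 3-D (n, h, w) array, got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise GeometryError("an image stack requires at least 2 frames")
        if not self.frame_interval > 0:
            raise TraceFormatError(f"frame_interval must be > 0, got {self.frame_interval}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Roi:
    """A region of interest: a half-open rectangle or an explicit pixel mask."""

    label: str
    kind: str = "rect"  # "rect" | "mask"
    coords: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1), half-open
    mask_array: np.ndarray | None = None

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this ROI on a frame of the given (height, width)."""
        h, w = frame_shape
        if self.kind == "rect":
            if self.coords is None:
                raise GeometryError(f"ROI '{self.label}': rect ROI requires coords")
            x0, y0, x1, y1 = self.coords
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise GeometryError(
                    f"ROI '{self.label}': rectangle ({x0},{y0})-({x1},{y1}) empty or "
                    f"outside {w}x{h} frame"
                )
            m = np.zeros((h, w), dtype=bool)
            m[y0:y1, x0:x1] = True
            return m
        if self.kind == "mask":
            if self.mask_array is None:
                raise GeometryError(f"ROI '{self.label}': mask ROI requires mask_array")
            m = np.asarray(self.mask_array, dtype=bool)
            if m.shape != (h, w):
                raise GeometryError(
                    f"ROI '{self.label}': mask shape {m.shape} != frame shape {(h, w)}"
                )
            if not m.any():
                raise GeometryError(f"ROI '{self.label}': empty mask")
            return m
        raise GeometryError(f"ROI '{self.label}': unknown kind {self.kind!r}")


@dataclass
class FluorescenceTrace:
    """Per-frame (background-subtracted) ROI mean intensity versus time."""

    time: np.ndarray
    value: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape or self.time.ndim != 1:
            raise TraceFormatError("time and value must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise TraceFormatError("a trace requires at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise TraceFormatError(f"time must be strictly increasing (violation at sample {i + 1})")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise TraceFormatError("time must be uniformly spaced (1e-6 relative tolerance)")

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return self.time.size


def read_stack(path: str | Path, frame_interval_override: float | None = None) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    The frame interval is taken from ImageJ-style metadata (``finterval``);
    if absent, ``frame_interval_override`` is used; if neither exists an
    error is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = dict(tif.imagej_metadata or {})
    if frames.ndim == 2:
        raise GeometryError(f"{path}: single-frame file; an image stack requires at least 2 frames")
    interval = meta.get("finterval")
    if interval is None:
        interval = frame_interval_override
    if interval is None:
        raise TraceFormatError(
            f"{path}: no frame interval in metadata and no override supplied"
        )
    return ImageStack(frames=frames, frame_interval=float(interval), metadata=meta)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as unsigned 16-bit multi-page TIFF with the frame interval
    in ImageJ metadata."""
    data = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path, data, imagej=True, metadata={"finterval": stack.frame_interval, "axes": "TYX"}
    )


def extract_trace(
    stack: ImageStack,
    cell: Roi,
    background: Roi,
    *,
    background_trim_fraction: float = 0.0,
) -> FluorescenceTrace:
    """Per-frame background-subtracted ROI mean trace.

    ``value[i] = mean(cell pixels of frame i) - mean(background pixels of frame i)``;
    ``time[i] = i * frame_interval``.

    ``background_trim_fraction`` optionally discards that top fraction of the
    brightest background pixels per frame (guards against bright debris in
    the background region); 0 disables the trim.
    """
    cmask = cell.mask(stack.frame_shape)
    bmask = background.mask(stack.frame_shape)
    if np.any(cmask & bmask):
        raise GeometryError(
            f"cell ROI '{cell.label}' and background ROI '{background.label}' overlap"
        )
    flat = stack.frames.reshape(stack.n_frames, -1)
    cell_mean = flat[:, cmask.ravel()].mean(axis=1)
    bpix = flat[:, bmask.ravel()].astype(float)
    if background_trim_fraction > 0:
        k = int(np.ceil(bpix.shape[1] * (1.0 - background_trim_fraction)))
        k = max(k, 1)
        bpix = np.sort(bpix, axis=1)[:, :k]
    bg_mean = bpix.mean(axis=1)
    time = np.arange(stack.n_frames) * stack.frame_interval
    meta = {"cell_roi": cell.label, "background_roi": background.label, **stack.metadata}
    return FluorescenceTrace(time=time, value=cell_mean - bg_mean, meta=meta)


def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    """Write a trace as CSV with header ``time_s,intensity`` at full precision."""
    # default float formatting is the shortest exact repr: lossless round trip
    df = pd.DataFrame({"time_s": trace.time, "intensity": trace.value})
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> FluorescenceTrace:
    """Read a ``time_s,intensity`` CSV back into a :class:`FluorescenceTrace`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "intensity"):
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing required column '{col}'")
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any() and not df[col].isna().any():
            row = int(numeric.isna().idxmax())
            raise TraceFormatError(
                f"{path}: non-numeric value in column '{col}' at data row {row} "
                f"({df[col].iloc[row]!r}); note decimal commas are not supported"
            )
        df[col] = numeric
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(), value=df["intensity"].to_numpy(), meta={"path": str(path)}
    )


def roi_to_json(roi: Roi) -> dict:
    d: dict = {"label": roi.label, "type": roi.kind}
    if roi.kind == "rect":
        d["coords"] = list(roi.coords)
    else:
        d["coords"] = np.argwhere(np.asarray(roi.mask_array, dtype=bool)).tolist()
        d["shape"] = list(np.asarray(roi.mask_array).shape)
    return d


def roi_from_json(obj: dict | str) -> Roi:
    """Build an ROI from the small JSON schema {label, type: rect|mask, coords}."""
    if isinstance(obj, str):
        obj = json.loads(obj)
    kind = obj["type"]
    if kind == "rect":
        return Roi(label=obj["label"], kind="rect", coords=tuple(obj["coords"]))
    if kind == "mask":
        mask = np.zeros(tuple(obj["shape"]), dtype=bool)
        yx = np.asarray(obj["coords"], dtype=int)
        mask[yx[:, 0], yx[:, 1]] = True
        return Roi(label=obj["label"], kind="mask", mask_array=mask)
    raise GeometryError(f"unknown ROI type {kind!r}")
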