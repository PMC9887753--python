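"""dF/F0 normalization of background-subtracted fluorescence traces.

F0, the resting (diastolic) fluorescence, is estimated by averaging a window
of 10-40 frames immediately preceding the first Ca2+ rise; the trace is then
expressed as (F - F0) / F0, which cancels dye-loading and cell-thickness
differences between recordings (a pure gain). Because an additive offset is
*not* cancelled, background subtraction must precede normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, TraceFormatError
from .io import FluorescenceTrace

__all__ = [
    "F0Estimate",
    "NormalizedTrace",
    "estimate_f0",
    "find_first_rise",
    "to_df_f0",
    "normalize_trace",
]

#: permissible F0-window length range, frames
F0_FRAMES_MIN, F0_FRAMES_MAX = 10, 40
DEFAULT_F0_FRAMES = 30
DEFAULT_RISE_THRESHOLD = 5.0


@dataclass
class F0Estimate:
    f0: float
    window_start: int     # half-open sample window [window_start, window_end)
    window_end: int
    n_frames: int


@dataclass
class NormalizedTrace:
    """A dF/F0 series with its F0 estimate and the source trace's time base."""

    time: np.ndarray
    value: np.ndarray
    f0_estimate: F0Estimate
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise TraceFormatError("time and value must have equal length")

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return self.time.size


def estimate_f0(
    trace: FluorescenceTrace, rise_index: int, n_frames: int = DEFAULT_F0_FRAMES
) -> F0Estimate:
    """Average the ``n_frames`` samples immediately preceding the first rise.

    ``n_frames`` must lie in [10, 40]; the window is
    ``[rise_index - n_frames, rise_index)``.
    """
    if not (F0_FRAMES_MIN <= n_frames <= F0_FRAMES_MAX):
        raise ConfigError(
            f"n_frames must be in [{F0_FRAMES_MIN}, {F0_FRAMES_MAX}], got {n_frames}"
        )
    if rise_index < n_frames:
        raise ConfigError(
            f"rise at sample {rise_index} leaves fewer than n_frames={n_frames} "
            "preceding samples for the F0 window"
        )
    window = trace.value[rise_index - n_frames: rise_index]
    f0 = float(window.mean())
    if f0 <= 0:
        raise ConfigError(f"estimated F0 must be > 0, got {f0} (background over-subtracted?)")
    return F0Estimate(f0=f0, window_start=rise_index - n_frames,
                      window_end=rise_index, n_frames=n_frames)


def find_first_rise(
    trace: FluorescenceTrace,
    threshold: float = DEFAULT_RISE_THRESHOLD,
    smooth_samples: int = 3,
) -> int | None:
    """Index of the first sample where fluorescence starts to rise.

    The first difference is boxcar-smoothed and compared against
    ``threshold`` times a robust (MAD-based) noise scale. Returns ``None``
    when no rise is found (flat trace); the caller must then supply a rise
    index manually. Deterministic.
    """
    d = np.diff(trace.value)
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        ds = np.convolve(d, kernel, mode="same")
    else:
        ds = d
    scale = 1.4826 * np.median(np.abs(ds - np.median(ds)))
    # noiseless trace: zero scale, so any strictly positive derivative is a rise
    above = ds > threshold * scale if scale > 0 else ds > 0
    if not above.any():
        return None
    i = int(np.argmax(above))
    # refine to the first raw-difference exceedance near the smoothed crossing,
    # so smoothing does not shift the reported onset
    raw_scale = 1.4826 * np.median(np.abs(d - np.median(d)))
    raw_thr = threshold * raw_scale
    lo = max(0, i - smooth_samples)
    hi = min(d.size, i + smooth_samples + 1)
    local = np.nonzero(d[lo:hi] > raw_thr)[0] if raw_scale > 0 else np.nonzero(d[lo:hi] > 0)[0]
    j = lo + int(local[0]) if local.size else i
    return j + 1  # d[j] = value[j+1] - value[j]: the rise is at sample j+1


def to_df_f0(trace: FluorescenceTrace, f0: F0Estimate) -> NormalizedTrace:
    """Convert a background-subtracted trace to dF/F0."""
    if f0.f0 <= 0:
        raise ConfigError(f"F0 must be > 0, got {f0.f0}")
    return NormalizedTrace(
        time=trace.time.copy(),
        value=(trace.value - f0.f0) / f0.f0,
        f0_estimate=f0,
        meta=dict(trace.meta),
    )


def normalize_trace(
    trace: FluorescenceTrace,
    n_frames: int = DEFAULT_F0_FRAMES,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
    rise_index: int | None = None,
) -> NormalizedTrace:
    """Find the first rise, estimate F0 before it, and return dF/F0.

    ``rise_index`` overrides automatic rise detection when provided.
    """
    if rise_index is None:
        rise_index = find_first_rise(trace, threshold=rise_threshold)
        if rise_index is None:
            raise TraceFormatError(
                "no Ca2+ rise found; supply rise_index manually to normalize this trace"
            )
    f0 = estimate_f0(trace, rise_index, n_frames=n_frames)
    return to_df_f0(trace, f0)
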