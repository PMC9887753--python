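"""Single-exponential decay kinetics and the caffeine-protocol decomposition.

During pacing, cytosolic Ca2+ removal is the sum of SR reuptake (SERCA2) and
sarcolemmal extrusion (NCX), so the systolic transient decays at
``k_sys = k_serca + k_ncx``. Caffeine locks RyR channels open, preventing
net SR reuptake, so the caffeine-induced transient decays at ``k_caf ~ k_ncx``
alone. SERCA2 function is the difference of the two fitted decay rates, and
fractional release is the ratio of the electrically stimulated amplitude to
the caffeine amplitude (the fraction of SR content released per beat).

Decay segments are fit to ``y(t) = A exp(-k (t - t_peak)) + C`` by bounded
nonlinear least squares with A, k > 0 and a free offset C. Rates are
reported as rate constants k (s^-1); the time constant tau = 1/k is emitted
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import CaffeineNotFoundError, FitError
from .normalize import NormalizedTrace
from .protocol import ProtocolDescriptor, ProtocolPhases
from .spikes import (
    DEFAULT_ONSET_FRACTION,
    CellQc,
    Spike,
    _onset_and_baseline,
    paced_spikes,
)

__all__ = [
    "DecayFit",
    "CellSummary",
    "CaffeineResult",
    "fit_decay",
    "fit_exponential_decay",
    "select_systolic_spike",
    "segment_protocol",
    "caffeine_analysis",
    "serca_function",
    "fractional_release",
    "summarize_cell",
]

MIN_FIT_POINTS = 5
#: fits whose rmse exceeds this fraction of the amplitude are not converged
RMSE_AMPLITUDE_FRACTION = 0.2
_K_LOWER = 1e-6
#: cap on a paced decay-segment length, s (the tail is flat long before this)
MAX_SEGMENT_S = 5.0


@dataclass
class DecayFit:
    amplitude: float          # A, dF/F0
    k: float                  # decay rate constant, s^-1
    offset: float             # C, dF/F0
    rmse: float
    n_points: int
    converged: bool
    segment: tuple[int, int]  # [start, end) sample indices in the source trace

    @property
    def tau(self) -> float:
        """Decay time constant 1/k, s."""
        return 1.0 / self.k if self.k > 0 else np.inf


@dataclass
class CaffeineResult:
    stim_fit: DecayFit        # final electrically stimulated transient
    caf_fit: DecayFit         # caffeine-induced transient
    amplitude_stim: float
    amplitude_caffeine: float


@dataclass
class CellSummary:
    """Per-cell aggregate row; kinetic fields are None for ineligible cells."""

    cell_id: str
    animal_id: str | None
    group: str | None
    n_spikes: int
    mean_amplitude: float | None
    amplitude_caffeine: float | None
    k_sys: float | None            # from the final paced transient (caffeine protocol)
    k_sys_random: float | None     # from one randomly chosen paced spike
    k_caf: float | None
    serca_function: float | None   # k_sys - k_caf
    fractional_release: float | None
    qc: CellQc


def fit_exponential_decay(t: np.ndarray, y: np.ndarray,
                          segment: tuple[int, int] = (0, 0)) -> DecayFit:
    """Fit ``y = A exp(-k (t - t[0])) + C`` with A, k > 0 and C free.

    Initialization: A0 from the drop over the segment, C0 from its minimum,
    k0 = ln 2 / t_half from the first crossing of (A0/2 + C0). The fit is
    flagged unconverged when the optimizer fails, k sticks at its lower
    bound, or the residual rmse exceeds 20% of the fitted amplitude.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < MIN_FIT_POINTS:
        raise FitError(f"decay segment needs >= {MIN_FIT_POINTS} points, got {t.size}")
    ts = t - t[0]
    a0 = float(y[0] - y.min())
    c0 = float(y.min())
    if a0 <= 0:  # flat or rising segment: nothing to fit
        return DecayFit(amplitude=0.0, k=np.nan, offset=c0, rmse=float(y.std()),
                        n_points=t.size, converged=False, segment=segment)
    half = c0 + a0 / 2.0
    below = np.nonzero(y <= half)[0]
    t_half = ts[below[0]] if below.size and ts[below[0]] > 0 else ts[-1] / 4.0
    k0 = np.log(2.0) / max(t_half, ts[1])

    def model(tt, a, k, c):
        return a * np.exp(-k * tt) + c

    try:
        popt, _ = curve_fit(
            model, ts, y,
            p0=[a0, k0, c0],
            bounds=([np.finfo(float).tiny, _K_LOWER, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        ok = True
    except RuntimeError:
        popt, ok = (a0, k0, c0), False
    a, k, c = map(float, popt)
    rmse = float(np.sqrt(np.mean((model(ts, a, k, c) - y) ** 2)))
    converged = ok and k > 10 * _K_LOWER and rmse < RMSE_AMPLITUDE_FRACTION * a
    return DecayFit(amplitude=a, k=k, offset=c, rmse=rmse,
                    n_points=t.size, converged=converged, segment=segment)


def fit_decay(ntrace: NormalizedTrace, start: int, end: int) -> DecayFit:
    """Fit a single-exponential decay to ``ntrace`` samples [start, end).

    ``start`` should be a transient's peak sample.
    """
    if end - start < MIN_FIT_POINTS:
        raise FitError(f"decay segment [{start},{end}) shorter than {MIN_FIT_POINTS} samples")
    return fit_exponential_decay(ntrace.time[start:end], ntrace.value[start:end],
                                 segment=(start, end))


def select_systolic_spike(spikes: Sequence[Spike], rng_seed: int) -> Spike:
    """Uniform random choice of one paced spike, reproducible under the seed."""
    pool = paced_spikes(spikes)
    if not pool:
        raise FitError("no eligible paced spikes to choose from")
    rng = np.random.default_rng(rng_seed)
    return pool[int(rng.integers(len(pool)))]


def decay_segment(ntrace: NormalizedTrace, spikes: Sequence[Spike], which: Spike,
                  hard_end: int | None = None) -> tuple[int, int]:
    """Decay window for one spike: its peak to the next spike's onset.

    Capped at ``MAX_SEGMENT_S`` (the exponential is flat long before) and at
    ``hard_end`` when given.
    """
    later = [s.onset_index for s in spikes if s.onset_index > which.peak_index]
    end = min(later) if later else ntrace.n_samples
    cap = which.peak_index + int(round(MAX_SEGMENT_S / ntrace.frame_interval))
    end = min(end, cap)
    if hard_end is not None:
        end = min(end, hard_end)
    return which.peak_index, end


def segment_protocol(
    ntrace: NormalizedTrace,
    protocol: ProtocolDescriptor,
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
) -> ProtocolPhases:
    """Split a recording into paced / pause / caffeine phases.

    When the descriptor does not give the caffeine time, it is detected as
    the onset of the largest-prominence peak after the pacing stop.
    """
    t_end = float(ntrace.time[-1]) + ntrace.frame_interval
    if protocol.caffeine_s is not None:
        caffeine_t = protocol.caffeine_s
        if caffeine_t >= t_end:
            raise CaffeineNotFoundError(
                f"descriptor caffeine time {caffeine_t} s beyond end of trace ({t_end:.2f} s)"
            )
    else:
        stop_i = int(np.searchsorted(ntrace.time, protocol.pacing_stop_s))
        tail = ntrace.value[stop_i:]
        if tail.size < MIN_FIT_POINTS:
            raise CaffeineNotFoundError("caffeine transient not found: trace ends at pacing stop")
        peaks, props = find_peaks(tail, prominence=np.finfo(float).tiny)
        if peaks.size == 0:
            raise CaffeineNotFoundError("caffeine transient not found after pacing stop")
        best = int(peaks[np.argmax(props["prominences"])]) + stop_i
        onset, _ = _onset_and_baseline(ntrace.value, best, stop_i, onset_fraction)
        caffeine_t = float(ntrace.time[onset])
    return ProtocolPhases(
        paced=(float(ntrace.time[0]), protocol.pacing_stop_s),
        pause=(protocol.pacing_stop_s, caffeine_t),
        caffeine=(caffeine_t, t_end),
    )


def caffeine_analysis(
    ntrace: NormalizedTrace,
    phases: ProtocolPhases,
    spikes: Sequence[Spike],
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
) -> CaffeineResult:
    """Fit the final paced and the caffeine-induced transients.

    The systolic fit runs from the last paced spike's peak to the next onset
    (or pacing stop); the caffeine fit runs from the caffeine peak to the end
    of the trace. Amplitudes are peak minus local baseline, as in spike
    detection.
    """
    paced = paced_spikes(spikes)
    if not paced:
        raise FitError("caffeine analysis requires at least one paced spike")
    last = max(paced, key=lambda s: s.peak_index)
    start, end = decay_segment(ntrace, spikes, last)
    stim_fit = fit_decay(ntrace, start, end)

    caf_i0 = int(np.searchsorted(ntrace.time, phases.caffeine[0]))
    if ntrace.n_samples - caf_i0 < MIN_FIT_POINTS:
        raise CaffeineNotFoundError("caffeine phase missing or too short")
    caf_spike = next((s for s in spikes if s.stimulus_index == "caffeine"), None)
    if caf_spike is not None:
        caf_peak, caf_baseline = caf_spike.peak_index, caf_spike.baseline
        amp_caf = caf_spike.amplitude
    else:
        caf_peak = caf_i0 + int(np.argmax(ntrace.value[caf_i0:]))
        pause_i0 = int(np.searchsorted(ntrace.time, phases.pause[0]))
        _, caf_baseline = _onset_and_baseline(ntrace.value, caf_peak, pause_i0, onset_fraction)
        amp_caf = float(ntrace.value[caf_peak] - caf_baseline)
    if amp_caf <= 0:
        raise CaffeineNotFoundError("caffeine transient not found (no positive excursion)")
    caf_fit = fit_decay(ntrace, caf_peak, ntrace.n_samples)
    return CaffeineResult(
        stim_fit=stim_fit,
        caf_fit=caf_fit,
        amplitude_stim=last.amplitude,
        amplitude_caffeine=amp_caf,
    )


def serca_function(k_sys: float, k_caf: float) -> float:
    """SERCA2's contribution to Ca2+ removal: systolic minus caffeine decay rate.

    A negative value is physiologically suspect but is returned as computed
    (callers flag it); pass only converged fit rates.
    """
    for name, v in (("k_sys", k_sys), ("k_caf", k_caf)):
        if not np.isfinite(v):
            raise FitError(f"{name} is not a finite converged rate: {v}")
    return k_sys - k_caf


def fractional_release(amplitude_stim: float, amplitude_caffeine: float) -> float:
    """Fraction of SR content released per beat: stim / caffeine amplitude ratio."""
    if not amplitude_stim > 0:
        raise FitError(f"amplitude_stim must be > 0, got {amplitude_stim}")
    if not amplitude_caffeine > 0:
        raise FitError(f"amplitude_caffeine must be > 0, got {amplitude_caffeine}")
    return amplitude_stim / amplitude_caffeine


def summarize_cell(
    cell_id: str,
    spikes: Sequence[Spike],
    qc: CellQc,
    caffeine: CaffeineResult | None,
    random_fit: DecayFit | None,
    animal_id: str | None = None,
    group: str | None = None,
) -> CellSummary:
    """Assemble one per-cell summary row.

    Ineligible cells (or cells with unconverged fits) carry None kinetic
    fields plus the QC reasons; they are excluded from group statistics
    rather than imputed. Fractional release uses the mean paced amplitude
    over the caffeine amplitude.
    """
    paced = paced_spikes(spikes)
    mean_amp = float(np.mean([s.amplitude for s in paced])) if paced else None
    row = CellSummary(
        cell_id=cell_id, animal_id=animal_id, group=group,
        n_spikes=qc.n_spikes, mean_amplitude=mean_amp,
        amplitude_caffeine=None, k_sys=None, k_sys_random=None, k_caf=None,
        serca_function=None, fractional_release=None, qc=qc,
    )
    if not qc.eligible or caffeine is None:
        return row
    row.amplitude_caffeine = caffeine.amplitude_caffeine
    if random_fit is not None and random_fit.converged:
        row.k_sys_random = random_fit.k
    if caffeine.stim_fit.converged and caffeine.caf_fit.converged:
        row.k_sys = caffeine.stim_fit.k
        row.k_caf = caffeine.caf_fit.k
        row.serca_function = serca_function(row.k_sys, row.k_caf)
    if mean_amp is not None and caffeine.amplitude_caffeine > 0:
        row.fractional_release = fractional_release(mean_amp, caffeine.amplitude_caffeine)
    return row
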