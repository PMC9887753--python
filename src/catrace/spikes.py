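"""Transient (spike) detection on dF/F0 traces, per-spike kinetics, and cell QC.

A spike is a local maximum with topographic prominence above threshold.
Its onset is the last pre-peak sample below 10% (configurable) of the local
rise; the amplitude is measured peak minus local diastolic baseline (median
of the 10 samples before onset), which is robust to incomplete decay between
beats and coincides with the raw peak on fully decayed traces. The rate of
rise is amplitude / time-to-peak by definition.

Cell eligibility follows the acquisition rules: at least 30 paced spikes, no
automaticity (ectopic spikes), and regular amplitude (coefficient of
variation below threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigError
from .normalize import NormalizedTrace
from .protocol import ProtocolDescriptor

__all__ = [
    "Spike",
    "CellQc",
    "detect_spikes",
    "assign_stimuli",
    "qc_cell",
    "robust_noise_scale",
    "ECTOPIC",
    "CAFFEINE",
]

ECTOPIC = "ectopic"
CAFFEINE = "caffeine"

DEFAULT_ONSET_FRACTION = 0.10
DEFAULT_LATENCY_MAX = 0.2          # s: stimulus-to-onset latency beyond which a spike is ectopic
DEFAULT_CV_THRESHOLD = 0.25
DEFAULT_MIN_SPIKES = 30
PROMINENCE_NOISE_FACTOR = 5.0
_BASELINE_SAMPLES = 10


@dataclass
class Spike:
    peak_index: int
    peak_time: float
    onset_index: int
    onset_time: float
    amplitude: float          # dF/F0, peak minus local baseline
    time_to_peak: float       # s, onset to peak
    rate_of_rise: float       # s^-1, amplitude / time_to_peak
    baseline: float           # local diastolic dF/F0
    prominence: float
    stimulus_index: int | str | None = None  # pacing stimulus number, ECTOPIC or CAFFEINE


@dataclass
class CellQc:
    n_spikes: int
    amplitude_cv: float
    n_ectopic: int
    eligible: bool
    reasons: list[str]


def robust_noise_scale(values: np.ndarray) -> float:
    """MAD-based estimate of the per-sample noise sd of a trace.

    Uses first differences so slow signal components do not inflate the
    estimate; the sqrt(2) undoes the variance doubling of differencing.
    """
    d = np.diff(np.asarray(values, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _onset_and_baseline(
    value: np.ndarray, peak: int, search_start: int, onset_fraction: float
) -> tuple[int, float]:
    """Locate a spike's onset and local baseline in [search_start, peak).

    Two passes: a provisional onset against the window minimum, then the
    final onset against the median-of-10-pre-onset baseline.
    """
    window = value[search_start:peak]
    if window.size == 0:
        return max(search_start, peak - 1), float(value[max(search_start, peak - 1)])
    base0 = float(window.min())

    def last_below(baseline: float) -> int:
        thr = baseline + onset_fraction * (value[peak] - baseline)
        below = np.nonzero(window < thr)[0]
        return search_start + int(below[-1]) if below.size else search_start

    onset = last_below(base0)
    pre = value[max(search_start, onset - _BASELINE_SAMPLES): onset]
    baseline = float(np.median(pre)) if pre.size else float(value[onset])
    onset = last_below(baseline)
    pre = value[max(search_start, onset - _BASELINE_SAMPLES): onset]
    if pre.size:
        baseline = float(np.median(pre))
    if baseline >= value[peak]:
        # dense activity: the pre-onset median is not diastolic; fall back to
        # the window minimum, which is always strictly below the peak
        baseline = base0
        onset = last_below(base0)
    if onset >= peak:
        onset = peak - 1
    return onset, baseline


def detect_spikes(
    ntrace: NormalizedTrace,
    min_prominence: float | None = None,
    min_separation: float = 1.0,
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
) -> list[Spike]:
    """Detect transients as prominent local maxima on a dF/F0 trace.

    Parameters
    ----------
    min_prominence
        Topographic prominence threshold in dF/F0 units. ``None`` uses
        5x the robust noise scale of the trace.
    min_separation
        Minimum peak-to-peak spacing in seconds (>= 2 frame intervals);
        half a pacing interval is a good choice for paced recordings.
    onset_fraction
        Fraction of the local rise that defines the onset sample.

    Local maxima are first pruned by spacing (taller peaks win) and the
    survivors filtered by prominence. Deterministic; plateau ties resolve to
    the earlier sample. An empty list is a valid result.
    """
    dt = ntrace.frame_interval
    if min_separation < 2 * dt:
        raise ConfigError(f"min_separation must be >= 2 frame intervals ({2 * dt:.4g} s)")
    value = ntrace.value
    if min_prominence is None:
        min_prominence = PROMINENCE_NOISE_FACTOR * robust_noise_scale(value)
        if min_prominence <= 0:
            min_prominence = np.finfo(float).tiny
    if min_prominence <= 0:
        raise ConfigError(f"min_prominence must be > 0, got {min_prominence}")

    distance = max(2, int(round(min_separation / dt)))
    peaks, props = find_peaks(value, prominence=min_prominence, distance=distance)

    spikes: list[Spike] = []
    prev_peak = 0
    for peak, prom in zip(peaks, props["prominences"]):
        peak = int(peak)
        while peak > 0 and value[peak - 1] == value[peak]:  # plateau -> earlier sample
            peak -= 1
        search_start = prev_peak if spikes else 0
        onset, baseline = _onset_and_baseline(value, peak, search_start, onset_fraction)
        amplitude = float(value[peak] - baseline)
        if amplitude <= 0:
            continue
        time_to_peak = float(ntrace.time[peak] - ntrace.time[onset])
        spikes.append(Spike(
            peak_index=peak,
            peak_time=float(ntrace.time[peak]),
            onset_index=onset,
            onset_time=float(ntrace.time[onset]),
            amplitude=amplitude,
            time_to_peak=time_to_peak,
            rate_of_rise=amplitude / time_to_peak,
            baseline=baseline,
            prominence=float(prom),
        ))
        prev_peak = peak
    return spikes


def assign_stimuli(
    spikes: Sequence[Spike],
    protocol: ProtocolDescriptor,
    latency_max: float = DEFAULT_LATENCY_MAX,
) -> list[Spike]:
    """Map each spike to the pacing stimulus it follows, or label it ectopic.

    A paced-phase spike is assigned to the nearest preceding stimulus when
    its peak latency is within ``latency_max``; late spikes, extra spikes on
    an already-taken stimulus, and any spike during the pacing-stop pause are
    ectopic. The first spike peaking at/after the caffeine time is the
    caffeine transient. Returns annotated copies in time order.

    Assignment uses the peak time, not the onset time: the peak always
    follows its stimulus, whereas noise can push the detected onset a sample
    before it.
    """
    period = 1.0 / protocol.pacing_freq_hz
    caffeine_t = protocol.caffeine_s if protocol.caffeine_s is not None else np.inf
    taken: set[int] = set()
    out: list[Spike] = []
    caffeine_seen = False
    for s in sorted(spikes, key=lambda s: s.peak_time):
        t = s.peak_time
        if t >= caffeine_t:
            if not caffeine_seen:
                label: int | str = CAFFEINE
                caffeine_seen = True
            else:
                label = ECTOPIC
        elif t >= protocol.pacing_stop_s:
            label = ECTOPIC
        elif t < protocol.pacing_start_s:
            label = ECTOPIC
        else:
            idx = int(np.floor((t - protocol.pacing_start_s) / period + 1e-9))
            latency = t - (protocol.pacing_start_s + idx * period)
            if latency > latency_max or idx in taken:
                label = ECTOPIC
            else:
                label = idx
                taken.add(idx)
        out.append(replace(s, stimulus_index=label))
    return out


def paced_spikes(spikes: Sequence[Spike]) -> list[Spike]:
    """Spikes assigned to a pacing stimulus (excludes ectopic and caffeine)."""
    return [s for s in spikes if isinstance(s.stimulus_index, (int, np.integer))]


#: ectopic events below this fraction of the median paced amplitude are treated
#: as noise detections, not automaticity
ECTOPIC_AMPLITUDE_FRACTION = 0.5


def qc_cell(
    spikes: Sequence[Spike],
    protocol: ProtocolDescriptor,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    ectopic_amplitude_fraction: float = ECTOPIC_AMPLITUDE_FRACTION,
) -> CellQc:
    """Cell-eligibility QC: spike count, automaticity, amplitude regularity.

    Automaticity (``n_ectopic``) counts ectopic-labeled events whose amplitude
    is at least ``ectopic_amplitude_fraction`` of the median paced amplitude:
    a spontaneous beat releases a near-full transient, whereas small ectopic
    labels are noise excursions that merely cleared the prominence threshold.
    """
    del protocol  # annotation already encodes the phase structure
    paced = paced_spikes(spikes)
    med_amp = float(np.median([s.amplitude for s in paced])) if paced else 0.0
    amp_floor = ectopic_amplitude_fraction * med_amp
    n_ectopic = sum(
        1 for s in spikes
        if s.stimulus_index == ECTOPIC and s.amplitude >= amp_floor
    )
    amps = np.array([s.amplitude for s in paced])
    cv = float(amps.std(ddof=1) / amps.mean()) if amps.size >= 2 and amps.mean() > 0 else 0.0
    reasons: list[str] = []
    if len(paced) < min_spikes:
        reasons.append(f"n_spikes<{min_spikes}")
    if n_ectopic > 0:
        reasons.append("automaticity")
    if cv > cv_threshold:
        reasons.append(f"amplitude_cv>{cv_threshold}")
    return CellQc(
        n_spikes=len(paced),
        amplitude_cv=cv,
        n_ectopic=n_ectopic,
        eligible=not reasons,
        reasons=reasons,
    )
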