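"""Ground-truth simulator for paced Fluo-4 Ca2+ recordings.

The generator emulates the caffeine protocol: a cell field-stimulated at
``pacing_freq`` for ``paced_duration`` seconds, a pacing-free pause, then a
rapid caffeine application that dumps the entire SR Ca2+ store. Each evoked
transient rises linearly over ``time_to_peak`` to a drawn amplitude and then
decays as a single exponential. During pacing the decay rate is
``k_serca + k_ncx`` (both removal pathways active); the caffeine transient
decays at ``k_ncx`` alone, because caffeine holds RyR channels open and the
SR cannot re-sequester Ca2+. Overlapping transients superpose linearly.

The raw signal on the camera is::

    F(t) = background_level + f0_baseline * (1 + s(t)) + noise(t)

with ``s(t)`` the summed transients on the dF/F0 scale, so downstream
background subtraction and dF/F0 normalization recover ``s(t)`` exactly in
the noiseless limit. Every drawn value is recorded in :class:`GroundTruth`
so each pipeline stage is testable by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, GeometryError
from .io import FluorescenceTrace, ImageStack, Roi
from .protocol import ProtocolDescriptor

__all__ = [
    "SimConfig",
    "GroundTruth",
    "StackGeometry",
    "CellRecord",
    "simulate_trace",
    "simulate_stack",
    "simulate_cohort",
    "write_ground_truth_json",
]


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the baseline acquisition conditions.

    Units: rates in s^-1, durations in s, amplitudes in dF/F0 units,
    intensities in camera counts.
    """

    frame_rate: float = 97.0          # frames per second
    pacing_freq: float = 0.5          # Hz field stimulation
    paced_duration: float = 180.0     # s of paced acquisition
    pause_duration: float = 60.0      # s pacing-stop before caffeine
    caffeine_duration: float = 20.0   # s acquired after caffeine addition
    onset_delay: float = 1.0          # s from acquisition start to first stimulus
    amplitude_mean: float = 1.0       # peak dF/F0 of paced transients
    amplitude_cv: float = 0.05        # spike-to-spike fractional variability
    time_to_peak: float = 0.05        # s, linear rise duration
    k_serca: float = 3.5              # s^-1 SR reuptake component
    k_ncx: float = 1.5                # s^-1 sarcolemmal extrusion component
    caffeine_amplitude: float = 1.25  # peak dF/F0 of the caffeine transient
    caffeine_onset_jitter_sd: float = 0.0  # s, jitter of caffeine addition
    f0_baseline: float = 400.0        # resting fluorescence, counts
    background_level: float = 100.0   # camera/ambient background, counts
    noise_sd: float = 20.0            # additive noise sd, counts
    noise_model: str = "gaussian"     # "gaussian" | "poisson"
    ectopic_rate: float = 0.0         # spikes/s of spontaneous automaticity
    seed: int = 0

    def validate(self) -> None:
        positive = ("frame_rate", "paced_duration", "pause_duration",
                    "caffeine_duration", "k_serca", "k_ncx", "f0_baseline",
                    "pacing_freq", "time_to_peak", "amplitude_mean")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        nonneg = ("amplitude_cv", "ectopic_rate", "noise_sd", "background_level",
                  "onset_delay", "caffeine_onset_jitter_sd")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.caffeine_amplitude < self.amplitude_mean:
            raise ConfigError(
                "caffeine_amplitude must be >= amplitude_mean (the caffeine "
                f"transient releases total SR content), got {self.caffeine_amplitude} "
                f"< {self.amplitude_mean}"
            )
        if self.noise_model not in ("gaussian", "poisson"):
            raise ConfigError(f"noise_model must be 'gaussian' or 'poisson', got {self.noise_model}")
        if self.onset_delay >= self.paced_duration:
            raise ConfigError("onset_delay must fall inside paced_duration")

    @property
    def k_sys(self) -> float:
        """Systolic decay rate: both removal pathways act in series."""
        return self.k_serca + self.k_ncx

    def protocol(self) -> ProtocolDescriptor:
        return ProtocolDescriptor(
            pacing_freq_hz=self.pacing_freq,
            pacing_start_s=self.onset_delay,
            pacing_stop_s=self.paced_duration,
            caffeine_s=self.paced_duration + self.pause_duration,
        )


@dataclass
class GroundTruth:
    """Everything the simulator drew, for parameter-recovery tests."""

    spike_times: list[float]          # stimulus-evoked transient onsets, s
    spike_amplitudes: list[float]     # drawn peak dF/F0 per evoked transient
    ectopic_times: list[float]        # spontaneous transient onsets, s
    k_sys_true: float                 # = k_serca + k_ncx
    k_caf_true: float                 # = k_ncx
    serca_function_true: float        # = k_serca
    fractional_release_true: float    # = amplitude_mean / caffeine_amplitude
    caffeine_onset: float             # s
    caffeine_amplitude: float         # dF/F0

    def __post_init__(self) -> None:
        assert self.k_sys_true - self.k_caf_true == self.serca_function_true
        assert 0 < self.fractional_release_true <= 1


def _add_transient(s: np.ndarray, t: np.ndarray, t0: float, amp: float,
                   ttp: float, k: float) -> None:
    """Add one linear-rise / exponential-decay transient to s(t) in place.

    Contributions below exp(-30) of the peak are truncated for speed.
    """
    i0 = int(np.searchsorted(t, t0 - 1e-12))
    i_end = int(np.searchsorted(t, t0 + ttp + 30.0 / k))
    seg = t[i0:i_end] - t0
    out = np.where(
        seg <= ttp,
        amp * seg / ttp,
        amp * np.exp(-k * (seg - ttp)),
    )
    out[seg < 0] = 0.0
    s[i0:i_end] += out


def simulate_trace(config: SimConfig) -> tuple[FluorescenceTrace, GroundTruth]:
    """Simulate one raw (not background-subtracted) fluorescence trace.

    Returns the trace and the ground truth of every drawn quantity.
    Identical ``config.seed`` gives byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    total = config.paced_duration + config.pause_duration + config.caffeine_duration
    n = int(round(total * config.frame_rate))
    t = np.arange(n) / config.frame_rate

    stim_times = config.protocol().stimulus_times()
    n_spk = len(stim_times)
    if config.amplitude_cv > 0:
        # lognormal with the requested mean and CV keeps amplitudes positive
        sigma2 = np.log1p(config.amplitude_cv**2)
        mu = np.log(config.amplitude_mean) - sigma2 / 2.0
        amps = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_spk)
    else:
        amps = np.full(n_spk, config.amplitude_mean)

    ectopic_times: list[float] = []
    ectopic_amps: list[float] = []
    if config.ectopic_rate > 0:
        n_ect = rng.poisson(config.ectopic_rate * config.paced_duration)
        ectopic_times = sorted(rng.uniform(0.0, config.paced_duration, size=n_ect).tolist())
        ectopic_amps = np.full(n_ect, config.amplitude_mean).tolist()

    caffeine_onset = config.paced_duration + config.pause_duration
    if config.caffeine_onset_jitter_sd > 0:
        caffeine_onset += float(rng.normal(0.0, config.caffeine_onset_jitter_sd))

    s = np.zeros(n)
    for t0, a in zip(stim_times, amps):
        _add_transient(s, t, t0, a, config.time_to_peak, config.k_sys)
    for t0, a in zip(ectopic_times, ectopic_amps):
        _add_transient(s, t, t0, a, config.time_to_peak, config.k_sys)
    _add_transient(s, t, caffeine_onset, config.caffeine_amplitude,
                   config.time_to_peak, config.k_ncx)

    clean = config.background_level + config.f0_baseline * (1.0 + s)
    if config.noise_model == "poisson":
        raw = rng.poisson(np.maximum(clean, 0.0)).astype(float)
    elif config.noise_sd > 0:
        raw = clean + rng.normal(0.0, config.noise_sd, size=n)
    else:
        raw = clean

    truth = GroundTruth(
        spike_times=list(stim_times),
        spike_amplitudes=list(map(float, amps)),
        ectopic_times=list(map(float, ectopic_times)),
        k_sys_true=config.k_sys,
        k_caf_true=config.k_ncx,
        # defined by subtraction so the conservation identity is bit-exact
        serca_function_true=config.k_sys - config.k_ncx,
        fractional_release_true=config.amplitude_mean / config.caffeine_amplitude,
        caffeine_onset=float(caffeine_onset),
        caffeine_amplitude=config.caffeine_amplitude,
    )
    trace = FluorescenceTrace(time=t, value=raw, meta={"seed": config.seed})
    return trace, truth


@dataclass
class StackGeometry:
    """Frame size plus disjoint cell and background rectangles."""

    frame_shape: tuple[int, int]       # (height, width)
    cell: Roi
    background: Roi

    def validate(self) -> None:
        cmask = self.cell.mask(self.frame_shape)       # raises if empty/out of bounds
        bmask = self.background.mask(self.frame_shape)
        if np.any(cmask & bmask):
            raise GeometryError("cell and background regions overlap")


def simulate_stack(config: SimConfig, geometry: StackGeometry) -> tuple[ImageStack, GroundTruth]:
    """Simulate a time-lapse image stack realizing the trace model per pixel.

    Cell-region pixels follow the clean F(t) with independent per-pixel noise;
    all other pixels carry ``background_level`` plus noise.
    """
    config.validate()
    geometry.validate()
    clean_cfg = replace(config, noise_sd=0.0, noise_model="gaussian")
    trace, truth = simulate_trace(clean_cfg)
    n = trace.n_samples
    h, w = geometry.frame_shape
    cmask = geometry.cell.mask((h, w))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x57ACC]))
    frames = np.full((n, h, w), config.background_level, dtype=float)
    frames[:, cmask] = trace.value[:, None]
    if config.noise_model == "poisson":
        frames = rng.poisson(np.maximum(frames, 0.0)).astype(float)
    elif config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape)

    stack = ImageStack(frames=frames, frame_interval=1.0 / config.frame_rate,
                       metadata={"seed": config.seed})
    return stack, truth


@dataclass
class CellRecord:
    """One simulated cell of a cohort."""

    cell_id: str
    group: str
    trace: FluorescenceTrace
    truth: GroundTruth
    config: SimConfig = field(repr=False, default=None)


# parameters that receive per-cell lognormal jitter in cohorts
_JITTERED = ("amplitude_mean", "k_serca", "k_ncx", "caffeine_amplitude")


def simulate_cohort(
    base: SimConfig,
    n_cells_per_group: int,
    effect: dict[str, float] | None = None,
    seed: int = 0,
    jitter_cv: float = 0.10,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> list[CellRecord]:
    """Simulate a two-group cohort of cells around a base parameter set.

    Group 2 parameters are multiplied by ``effect`` (parameter name ->
    multiplier, all > 0); both groups receive independent per-cell lognormal
    jitter of coefficient of variation ``jitter_cv`` on amplitude and rate
    parameters. Deterministic under ``seed``.
    """
    if n_cells_per_group < 1:
        raise ConfigError(f"n_cells_per_group must be >= 1, got {n_cells_per_group}")
    effect = dict(effect or {})
    for name, mult in effect.items():
        if name not in _JITTERED and not hasattr(base, name):
            raise ConfigError(f"unknown effect parameter '{name}'")
        if not mult > 0:
            raise ConfigError(f"effect multiplier for '{name}' must be > 0, got {mult}")
    base.validate()

    root = np.random.SeedSequence(seed)
    cell_seeds = root.generate_state(2 * n_cells_per_group * 2).reshape(2, n_cells_per_group, 2)
    records: list[CellRecord] = []
    sigma = np.sqrt(np.log1p(jitter_cv**2)) if jitter_cv > 0 else 0.0
    for g, label in enumerate(group_labels):
        for c in range(n_cells_per_group):
            jitter_rng = np.random.default_rng(int(cell_seeds[g, c, 0]))
            params: dict[str, float] = {}
            for name in _JITTERED:
                v = getattr(base, name)
                if g == 1 and name in effect:
                    v *= effect[name]
                if sigma > 0:
                    v *= jitter_rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma)
                params[name] = v
            for name, mult in effect.items():
                if name not in _JITTERED and g == 1:
                    params[name] = getattr(base, name) * mult
            # caffeine amplitude may not fall below the paced mean after jitter
            params["caffeine_amplitude"] = max(
                params.get("caffeine_amplitude", base.caffeine_amplitude),
                params["amplitude_mean"],
            )
            cfg = replace(base, seed=int(cell_seeds[g, c, 1]) % (2**31), **params)
            trace, truth = simulate_trace(cfg)
            records.append(CellRecord(
                cell_id=f"{label}_cell{c:03d}", group=label,
                trace=trace, truth=truth, config=cfg,
            ))
    return records


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2))
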