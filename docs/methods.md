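# Methods

## The measurement and the model

`catrace` analyses whole-cell Ca²⁺ transients recorded from field-stimulated
cardiomyocytes loaded with a fluorescent Ca²⁺ indicator (e.g. Fluo-4), imaged
as a single-channel time-lapse at a fixed frame rate (nominally 97 frames/s).
The protocol it targets is the standard caffeine protocol: a period of pacing
(0.5 Hz by default), a pacing-free pause (1 min), then rapid application of
caffeine (10 mM), which locks RyR channels open and dumps the entire SR Ca²⁺
store into the cytosol.

The analysis rests on a two-pathway removal model. During a paced beat,
cytosolic Ca²⁺ is removed by SR reuptake (SERCA2) and sarcolemmal extrusion
(dominated by NCX) acting in parallel, so the systolic transient decays
approximately as a single exponential with rate constant

    k_sys ≈ k_SERCA + k_NCX .

During the caffeine transient the SR cannot re-sequester Ca²⁺, so the decay
reflects extrusion alone:

    k_caf ≈ k_NCX .

Two derived quantities follow:

* **SERCA2 function** = `k_sys − k_caf`, SERCA2's contribution to cytosolic
  Ca²⁺ removal, in s⁻¹. It may come out negative on pathological fits; it is
  then reported as computed and flagged rather than clipped.
* **Fractional release** = (paced transient amplitude) / (caffeine transient
  amplitude) — the fraction of the SR content released per beat, since the
  caffeine amplitude proxies total SR content. The package uses the mean
  paced amplitude in the numerator; the amplitude of the final paced beat is
  also available from `caffeine_analysis`.

## Processing pipeline

1. **Extraction** (`io.extract_trace`): per-frame mean over a cell ROI minus
   the per-frame mean over a cell-free background ROI. Background is
   subtracted frame by frame (not as one global constant) so slow lamp drift
   cancels. Coordinates are 0-based; rectangles half-open. An optional
   percentile trim (off by default) discards the brightest background pixels
   to guard against debris reflections.
2. **ΔF/F₀** (`normalize`): F₀ is the mean of a 10–40-frame window (default
   30) immediately preceding the first Ca²⁺ rise; the trace becomes
   `(F − F₀)/F₀`. The 10–40 range is read as a permissible window-length
   range; 30 frames ≈ 0.31 s at 97 fps sits comfortably inside the diastolic
   interval at 0.5 Hz. Normalization cancels gain (dye load, cell thickness)
   but not additive offsets — hence background subtraction must precede it.
   The rise is found where the 3-sample-smoothed first difference exceeds 5×
   a MAD-based noise scale; on a noiseless trace any positive derivative
   counts. If no rise is found the caller must supply the index.
3. **Spike detection** (`spikes.detect_spikes`): local maxima pruned by
   spacing (taller peaks win) then filtered by topographic prominence.
   The default prominence threshold is 5× the robust per-sample noise scale
   (MAD of first differences / √2); the default spacing is half a pacing
   interval. The onset is the last pre-peak sample below 10% of the local
   rise; the local baseline is the median of the 10 samples before onset
   (falling back to the window minimum when activity is too dense for a
   meaningful diastolic median). Amplitude = peak − baseline, which equals
   the raw ΔF/F₀ peak on fully decayed traces but tolerates incomplete decay.
   Rate of rise = amplitude / time-to-peak by definition (bit-exact in the
   stored record). Time-to-peak is measured from fluorescence onset, not from
   the stimulus, since stimulus timestamps are usually not recorded.
4. **Stimulus assignment and QC** (`spikes.assign_stimuli`, `spikes.qc_cell`):
   each spike maps to the pacing stimulus preceding its *peak* (the peak
   always follows its stimulus, whereas noise can push the detected onset one
   sample before it). Late (> 0.2 s) or duplicate spikes, and any spike in the
   pacing-stop pause, are labeled ectopic; the first spike after the caffeine
   time is the caffeine transient. A cell is eligible when it has ≥ 30 paced
   spikes, no automaticity, and amplitude CV ≤ 0.25. Automaticity counts only
   ectopic events of spike-like size (≥ 50% of the median paced amplitude):
   a spontaneous beat releases a near-full transient, whereas smaller ectopic
   labels are noise excursions over the prominence threshold and would
   otherwise disqualify every noisy recording.
5. **Decay fits** (`kinetics.fit_decay`): bounded nonlinear least squares of
   `A·exp(−k(t − t_peak)) + C` with A, k > 0 and C free. A free offset is
   kept because diastolic ΔF/F₀ need not return to the pre-recording
   baseline; on offset-free simulations C fits to ~0, so no bias enters.
   Initialization: A and C from the segment's drop and minimum, k from the
   half-crossing time. A fit is unconverged when the optimizer fails, k
   sticks at its lower bound, or rmse ≥ 0.2·A (which also rejects flat and
   rising segments). Rates are reported as rate constants k (s⁻¹) with
   τ = 1/k emitted alongside. A paced spike's decay segment runs from its
   peak to the next spike's onset, capped at 5 s (the exponential is flat
   long before that; the cap keeps fits O(hundreds) of points).
6. **Caffeine decomposition** (`kinetics`): the systolic rate comes from the
   final paced transient; a second systolic estimate from one uniformly
   randomly chosen paced spike (seeded) is reported alongside, since both
   conventions are in circulation. The caffeine fit runs from the caffeine
   peak to the end of the trace. When the caffeine-addition time is not in
   the protocol descriptor it is detected as the onset of the
   largest-prominence peak after the pacing stop. Cells with unconverged fits
   are excluded from group statistics (with logged reasons), never imputed.
7. **Statistics** (`stats`): unpaired two-tailed t tests for two groups;
   one-way ANOVA with Sidak-adjusted pairwise post hocs (`1−(1−p)^m`) or
   Tukey HSD; two-way ANOVA (statsmodels OLS, type-II) for factorial designs,
   with post hocs across the factorial cells. Values are summarized as
   mean ± SEM. Tests run at the cell level by default (per-animal aggregation
   is a caller-side option), mirroring common practice in this literature.
   `stratify_quartiles` implements the expression-stratification rule:
   type-7 (linear-interpolation) quartiles on the full vector; values ≤ Q1
   form the low group and ≥ Q3 the high group; afterwards, values outside
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` (full-vector IQR) are moved to the excluded
   list. Applying the outlier screen after group assignment, with full-vector
   fences, is one of two defensible readings of "stratify, then remove
   outliers"; it is the documented, switchable choice here.

## The simulator

`simulate.simulate_trace` generates the raw camera signal

    F(t) = background_level + f0_baseline · (1 + s(t)) + ε(t)

where `s(t)` sums one transient per stimulus: a linear rise over
`time_to_peak` to a drawn amplitude, then exponential decay at
`k_serca + k_ncx`; after the pause, a caffeine transient of amplitude
≥ the paced mean decays at `k_ncx` alone. Overlapping transients superpose
linearly. Defaults are the acquisition conditions above: 97 fps, 0.5 Hz,
180 s paced, 60 s pause, then 20 s of caffeine acquisition (the caffeine
decay at 1.5 s⁻¹ is flat well before 20 s). The first stimulus fires at
`onset_delay` = 1 s so a full F₀ window precedes the first rise.

Parameter choices without a published value, fixed once as plausible for
room-temperature Fluo-4 recordings of adult mouse cardiomyocytes:

| parameter | default | note |
|---|---|---|
| `time_to_peak` | 0.05 s | linear rise; makes rate-of-rise = amplitude/time_to_peak exact by construction |
| `amplitude_mean` | 1.0 ΔF/F₀ | typical paced transient |
| `amplitude_cv` | 0.05 | spike-to-spike variability (lognormal, positive) |
| `caffeine_amplitude` | 1.25 ΔF/F₀ | SR content ≥ per-beat release (fractional release 0.8) |
| `k_serca`, `k_ncx` | 3.5, 1.5 s⁻¹ | systolic ≈ 5 s⁻¹ (τ ≈ 0.2 s), caffeine ≈ 1.5 s⁻¹ |
| `f0_baseline`, `background_level` | 400, 100 counts | mid-range 16-bit camera levels |
| `noise_sd` | 20 counts | ΔF/F₀ noise 0.05 → amplitude SNR 20 |

Noise is additive Gaussian by default (camera-dominated regime); a Poisson
option exists because the downstream operators are noise-model-agnostic.
`simulate_stack` realizes the same F(t) per pixel in a cell region of a
synthetic image stack (independent pixel noise; everything else at
background), so the extraction stage is testable by round trip.
`simulate_cohort` draws two groups of cells around a base configuration,
multiplies group-2 parameters by configurable effect sizes, and jitters
per-cell amplitude and rate parameters with a lognormal of CV 0.10 —
enough between-cell spread to make group tests honest without drowning a
1.5× effect at n = 12 per group.

What the simulator does *not* emulate: SR/cytosol flux biophysics (buffering,
RyR gating, dye kinetics), photobleaching, movement artifacts, cell-shape
heterogeneity, β-adrenergic pharmacodynamics (an isoproterenol condition is
just an alternative parameter set), and Ca²⁺ sparks. Passing recovery tests
therefore demonstrates that the pipeline measures what the two-pathway model
defines, not that the model captures every feature of real recordings.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical traces and analysis outputs. Cohorts and batch
  analyses derive per-cell seeds from a root `SeedSequence`.
* Peak ties on plateaus resolve to the earlier sample; the detector is
  equivariant under time translation and under adding a constant to ΔF/F₀.
* `GroundTruth.serca_function_true` is stored as `k_sys − k_caf` so the
  conservation identity is bit-exact despite floating-point addition.
* Trace CSVs round-trip losslessly (shortest-repr floats, `round_trip`
  parsing); decimal commas are rejected with the offending row named.
* Degenerate inputs fail loudly and specifically: rise too early for an F₀
  window, F₀ ≤ 0, empty or overlapping ROIs, single-frame stacks, missing
  caffeine phase, constant groups in a t test, degenerate quartiles.
* Problem sizes in the test-suite and acceptance-script simulations (500
  decay segments; 50-cell recovery cohorts; 200 spike-count runs; 100
  effect replicates of 12 + 12 cells; 1,000 null simulations) were chosen as
  the smallest sizes at which Monte-Carlo error is comfortably below the
  properties being checked.

## Known limitations

* Single-exponential decay is an approximation; there is no third (slow,
  mitochondrial) removal component and no absolute SR content in
  concentration units — the caffeine amplitude is a relative proxy only.
* Rate subtraction `k_sys − k_caf` is taken literally on fitted rate
  constants; conventions that subtract 1/τ of other fit forms would differ.
* No sub-frame peak interpolation: at 97 fps a peak can land up to one frame
  off the true maximum, biasing single-spike amplitudes by up to ~k·Δt
  (≈ 0.5% at default rates). Cohort means inherit a same-order bias.
* ROIs are user-provided; there is no automated segmentation.
* The cell-eligibility thresholds (30 spikes, CV ≤ 0.25, 50% automaticity
  amplitude floor, 0.2 s latency) are operational defaults, exposed in
  `AnalysisParams`, not measured constants.
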