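# catrace

Analysis of whole-cell Ca²⁺ transients in paced cardiomyocytes, with a
ground-truth simulator that makes every stage verifiable by parameter
recovery.

Cardiomyocytes loaded with a Ca²⁺ indicator (Fluo-4) and field-stimulated at
0.5 Hz produce one fluorescence transient per beat. `catrace` turns raw
time-lapse recordings (multi-frame TIFF, ~97 frames/s) or pre-extracted
traces (CSV) into per-cell Ca²⁺-handling readouts:

* background-subtracted ROI traces and **ΔF/F₀** normalization (F₀ from a
  10–40-frame window preceding the first Ca²⁺ rise);
* spike detection with amplitude, time-to-peak and **rate of rise**
  (= amplitude / time-to-peak), plus cell-eligibility QC (≥ 30 spikes, no
  automaticity, regular amplitudes);
* single-exponential decay fits `A·e^(−k t) + C` of the systolic and the
  caffeine-induced transient;
* the caffeine-protocol decomposition: the systolic decay rate reflects
  SERCA2 + NCX removal, the caffeine transient decays via NCX alone, so

  **SERCA2 function** `= k_sys − k_caf`  and
  **fractional release** `= amplitude_paced / amplitude_caffeine`;

* group statistics (unpaired two-tailed t test; one-/two-way ANOVA with
  Sidak or Tukey post hocs; mean ± SEM summaries) and quartile
  stratification of expression vectors with 1.5×IQR outlier removal.

The `simtrace` side (`catrace.simulate`) generates synthetic recordings —
traces or full image stacks — with known spike times, amplitudes and decay
rates, which is how the pipeline is tested: simulate with known
`k_SERCA`/`k_NCX`, run the analysis blind, compare. See `docs/methods.md`
for the model, defaults and limitations.

## Worked example

Simulate a two-group cohort (group 2 with 1.5× SERCA2 reuptake), analyze it,
and compare the groups — from Python:

```python
from catrace import AnalysisParams, SimConfig, compare_two_groups
from catrace.pipeline import analyze_cohort, summaries_frame
from catrace.simulate import simulate_cohort

base = SimConfig()            # 97 fps, 0.5 Hz, 3-min paced + 1-min pause + caffeine
recs = simulate_cohort(base, n_cells_per_group=12,
                       effect={"k_serca": 1.5}, seed=101, jitter_cv=0.10)
df = summaries_frame(analyze_cohort(recs, AnalysisParams(rng_seed=7)))
el = df[df.eligible]
for metric in ("k_sys", "k_caf", "serca_function"):
    g1 = el[el.group == "group1"][metric]
    g2 = el[el.group == "group2"][metric]
    print(metric, compare_two_groups(g1, g2, metric=metric).summary_string())
```

prints (seed 101/7):

```
k_sys A: 4.96 ± 0.11 (n=12); B: 7.06 ± 0.207 (n=12); unpaired two-tailed t test, P = 8.42e-09
k_caf A: 1.51 ± 0.0375 (n=12); B: 1.53 ± 0.043 (n=12); unpaired two-tailed t test, P = 0.828
serca_function A: 3.44 ± 0.0942 (n=12); B: 5.53 ± 0.188 (n=12); unpaired two-tailed t test, P = 1.4e-09
```

i.e. the configured SERCA2 gain shows up in the systolic decay rate and in
SERCA2 function while the caffeine (NCX) rate is unchanged — the signature
the caffeine protocol is designed to isolate. The same flow is available
from the shell:

```bash
catrace simulate --config sim.yaml --n-cells 12 --seed 101 --out runs/sim
catrace analyze  --traces runs/sim --protocol runs/sim/protocol.yaml \
                 --seed 7 --out runs/out
catrace compare  --summary runs/out/cell_summary.tsv --out runs/cmp
```

Every subcommand writes a `manifest.json` (config echo, version, seeds) from
which its outputs are reproducible; reruns with the same seed are
byte-identical.

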