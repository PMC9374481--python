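# visent

Visual-entrainment MEG analysis on synthetic two-group cohorts.

When the visual cortex is driven by a stimulus flickering at 15 Hz, its
population activity locks to the flicker frequency (a steady-state
visual evoked response).  Comparing how strongly, how consistently and
against what baseline different groups entrain — for example patients on
the Alzheimer's disease spectrum versus healthy controls — requires a
fairly long analysis chain, and `visent` implements all of it as a
tested, reproducible pipeline:

1. **Artifact rejection** with per-subject thresholds
   (mean + k·SD of trial-peak amplitude and gradient distributions).
2. **Complex demodulation** time–frequency decomposition
   (4–50 Hz × 0.5 Hz, 100 ms frames, zero-phase 1 Hz lowpass FIR),
   calibrated so a unit sinusoid returns envelope 1.
3. **Cluster-based sign-flip permutation statistics** on sensor-level
   baseline-relative spectrograms to locate the entrainment response in
   the time–frequency plane.
4. **DICS beamforming**: per-voxel unit-gain spatial filters
   `w = (C_r+λI)⁻¹l / (lᵀ(C_r+λI)⁻¹l)` from the band-limited
   cross-spectral density, baseline-normalized pseudo-t maps
   `(P_act − P_base)/P_base`, grand-average peak voxel and
   virtual-sensor extraction.
5. **Entrainment metrics** at the peak voxel: absolute and
   baseline-relative 14.5–15.5 Hz amplitude, inter-trial phase locking
   ITPL = |⟨e^{iφ}⟩|, cross-trial coefficient of variation, and
   per-frequency relative responses.
6. **Spectral parameterization** of the baseline PSD into aperiodic
   (log₁₀P = b − χ·log₁₀f) and periodic (Gaussian peak) components.
7. **Group statistics**: per-group 2.5 SD outlier exclusion, pooled
   Student t, Cohen's d = |t|·√(1/n₁+1/n₂), JZS Bayes factors with a
   Cauchy(0, 0.707) effect-size prior, and brain–behavior regression.

Because no public recordings accompany the study design this package
targets, inputs come from a first-class synthetic cohort generator
(`visent.synth`) that emulates the signal structure — a phase-locked
15 Hz source with 30/45 Hz harmonics and a 200–2000 ms envelope, a
non-phase-locked baseline 15 Hz rhythm, 1/f background, lognormal trial
amplitude variability, sensor noise, transient artifacts, and cognitive
scores linked to entrainment amplitude — with every generated quantity
stored as ground truth for recovery testing.

## Worked example

```bash
visent run-all --out runs/demo --seed 1
```

runs the full chain on the default demo cohort (8 ADS + 8 HC subjects,
40 trials, 24 sensors, 64 voxels; ~30 s on one CPU) and writes subject
containers, the significance mask, source maps, metrics and statistics
into `runs/demo/`.  The group contrasts land in `stats.csv`:

```
metric          t        p        cohen_d   bf01
rel_amp         1.179    0.258    0.589     1.478
abs_amp         0.425    0.677    0.212     2.199
itpl            1.540    0.146    0.770     1.088
cv             -4.777    0.000295 2.388     0.0129
base_full      -1.910    0.0768   0.955     0.746
base_aperiodic -2.199    0.0452   1.100     0.534
base_periodic  -1.683    0.114    0.842     0.947
r_squared       2.058    0.0587   1.029     0.631
```

Reading the table (ADS minus HC): the patient-like group shows a larger
*relative* entrainment response (positive t for `rel_amp`) without any
difference in *absolute* amplitude, markedly more consistent trial
amplitudes (strongly negative t for `cv`, BF₀₁ ≪ 1), and lower baseline
15 Hz periodic activity — the compensation pattern the generator plants.
`stats.json` additionally holds the within-ADS regression of the
MMSE-like score on absolute amplitude (positive slope 9.29, F₁,₆ = 2.94
at this demo size).  The same pipeline scales to study-sized cohorts by
configuration (`n_group: {ADS: 38, HC: 20}`, 120 trials, denser grids).

Python API equivalent:

```python
from visent import load_config, run_pipeline
config = load_config(overrides={"master_seed": 1})
run_pipeline(config, "runs/demo")
```

## Layout

```
src/visent/
  synth.py       synthetic cohorts, lead fields, subject containers
  preprocess.py  epochs container + artifact rejection
  tfr.py         complex demodulation, baseline normalization, window selection
  beamform.py    CSD, DICS filters, pseudo-t maps, virtual sensors
  metrics.py     entrainment read-outs (amplitude, ITPL, CV, per-frequency)
  specparam.py   baseline PSD + periodic/aperiodic parameterization
  stats.py       outlier exclusion, t/d/BF01, regression, cohort report
  pipeline.py    stage orchestration, config, manifests
  cli.py         `visent` command (one subcommand per stage)
```

See `docs/methods.md` for the model details, parameter defaults and
numerical choices.
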