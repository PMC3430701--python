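# dielcycle

Analysis pipeline for paired mRNA–protein expression dynamics over a
synchronized 24-h light–dark (diel) cycle, as measured in a marine
cyanobacterium sampled every 2 h over 26 h: ¹⁵N-metabolic-labeling protein
quantification rolled up from peptide isotope-ratio peaks, strand-specific
transcript quantification from per-base coverage, rhythmicity detection
against simulated AR(1) null backgrounds with q-value FDR control, and
per-gene comparison of phase, amplitude and lag between the transcript and
protein levels. A ground-truthed synthetic-data generator reproduces the
statistical structure of such an experiment so every stage is testable
without the original deposited data.

## The model

Each log2 abundance timecourse *y(t)* is fit by fixed-period harmonic
(cosinor) regression,

    y(t) = m + a·cos(2πt/24) + b·sin(2πt/24) + e(t)

by ordinary least squares. The half-amplitude is H = √(a² + b²) (log2 units;
peak-to-trough fold change 2^2H) and the phase φ = (24/2π)·atan2(b, a) mod 24
is the clock time of peak abundance. Rhythmicity is scored by the Fourier
score F = √(a² + b²) and tested against a per-series null of 1000 simulated
first-order autoregressive (AR(1)) timecourses with noise parameters
estimated from the cohort's harmonic residuals; the empirical p-value is
(1 + #{F_null ≥ F_obs})/(n_sims + 1), and q-values (π₀ by the polynomial
method, robust modifier) control the FDR across the cohort.

Protein abundances come from peptide peakgroup isotope ratios: peaks are
CV-filtered at the 80th percentile of the pooled CV ranking, log2-transformed,
median-centred per timepoint to absorb isotope mixing biases, cleaned of
inconsistent peaks (scale-invariant IIR score, cutoff 1.81), and summarized
per protein × timepoint as the mean of a lognormal fit with a 95% CI of
±1.96·c_N·s/√N, where c_N is the Gurland small-sample bias correction of the
standard deviation. Timecourses are kept when ≥4 peaks occur at ≥8 timepoints
(threshold lowered 4→3→2→1 until 8 timepoints qualify), and whole timepoints
are dropped when their summed nearest-neighbor distance exceeds 4.15× the
series mean. Paired genes are classified by the protein–transcript lag
(wrapped into (−2, 22] h): in phase (|lag| ≤ 2 h), lagged 2–8 h, antiphase
(11–13 h), or other.

## Worked example

```python
import numpy as np
from dielcycle import Cosinor24, SimConfig, generate_diel_truth, simulate_timecourses
from dielcycle.rhythm import detect_cycling
from dielcycle.compare import pair_cycling, summarize_cohort

cfg = SimConfig(n_genes=60, seed=42)
truth = generate_diel_truth(cfg)
mrna, protein = simulate_timecourses(truth, cfg)

res = Cosinor24(mrna[0].times, mrna[0].values).fit()
print(res.summary())
```

```
Cosinor24 fit (period 24.0 h, n=14)
  mesor             -0.9568  log2 units
  half-amplitude     1.3669  log2 units
  fold change         6.652  peak:trough
  phase               18.92  h (time of fitted max)
  residual sd        0.2093  log2 units
```

The gene was generated with phase 18.57 h and half-amplitude 1.24: the fit
recovers the peak time to ~20 min and the amplitude to ~10% under AR(1)
noise of 0.25 log2 units. Cohort-level detection and pairing:

```python
cyc_m, _ = detect_cycling(mrna, n_sims=1000, seed=42)
cyc_p, _ = detect_cycling(protein, n_sims=1000, seed=42)
report = summarize_cohort(pair_cycling(cyc_m, cyc_p))
```

which for this cohort prints 34 genes cycling significantly at both levels,
classes `{'in_phase': 7, 'lagged_2_8': 20, 'antiphase': 0, 'other': 7}`, a
median protein–transcript lag of 5.43 h, protein amplitude damped relative
to the transcript for 33 of 34 genes, and a median transcript:protein
amplitude ratio of 3.15 in log2 units — the damped-and-lagged structure the
generator encodes.

The same chain runs from the shell:

```
dielcycle run --config config.yaml --seed 7 --out results/
```

writing peak tables, abundance tables, cycling calls and the paired cohort
report (JSON/TSV, every table stamped with units and the config hash) into
`results/`. Individual stages are available as `dielcycle simulate`,
`quant-protein`, `quant-transcript`, `detect-cycling`, and `compare`.

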