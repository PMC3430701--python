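# Methods

## Scope and data model

The pipeline analyzes paired log2-abundance timecourses of transcripts and
proteins sampled on a common grid — by default 14 samples every 2 h over a
26-h span, with t = 0 at local midnight so the span covers midnight twice;
clock labels are taken mod 24 for reporting. Three input layers are
consumed: (i) peptide peakgroup isotope-ratio tables (one row per quantified
peak: protein id, timepoint, linear heavy:light ratio, reported CV), (ii)
strand-specific per-base coverage with gene models (bedGraph + GFF3,
converted internally to 0-based half-open coordinates), and (iii) gene-level
log2 timecourse tables. The synthetic generator produces all three with
known ground truth.

## Harmonic regression and the cycling test

Each series is fit by OLS to y(t) = m + a·cos(ωt) + b·sin(ωt), ω = 2π/24 h⁻¹.
Half-amplitude H = √(a²+b²) (log2 units), phase φ = atan2(b,a)/ω mod 24
(hours, time of fitted maximum), peak-to-trough fold change 2^2H. Series
with fewer than 8 retained points are reported unresolvable and excluded
from testing. A numerically flat fit (H below 1e-10 of the data scale) has
an undefined phase (NaN). An optional weighted fit takes inverse squared CI
half-widths as weights; the default is unweighted, since the null
simulation assumes a common noise process and per-point weights would break
the exchangeability between observed and simulated series.

The test statistic is the Fourier score F = √(a²+b²), the magnitude of the
24-h harmonic. Because each series' null is simulated from its own noise
scale, any scale-equivariant statistic yields identical empirical p-values;
the amplitude itself is the transparent choice. Significance comes from
1000 AR(1) series simulated on the observed time grid (index-wise recursion
e_t = φ·e_{t−1} + N(0, σ²), stationary initialization N(0, σ²/(1−φ²)) to
avoid burn-in artifacts on 14-point series), each scored by the same
harmonic fit. The p-value is add-one: p = (1 + #{F_null ≥ F_obs})/(B + 1),
bounded away from zero so downstream FDR machinery is well defined. A
degenerate null (zero residual variance) yields all-zero null scores, so
any positive observed score gets the minimum attainable p-value.

### Null parameter estimation — why pooled

At 14 points the AR(1) parameters cannot be usefully estimated per series:
estimated from the raw values, the oscillation itself inflates the fitted
autocorrelation and variance, making the test severely conservative
(measured type-I ≈ 1–2% at nominal 5%) and nearly powerless for strong
cyclers; estimated from the harmonic residuals, the projection removes
low-frequency noise power and whitens the residuals, making the test wildly
anticonservative (type-I ≈ 30%); even a per-series projection-debiased fit
stays anticonservative (≈ 18%) purely from parameter noise. The default is
therefore a cohort-pooled, projection-debiased moment estimator
(`fit_ar1_pooled`): residual lag-1 and variance moments are summed across
all series, and φ solves the equation matching the *expected* residual
moment ratio under the harmonic projection (computed from tr(P·C(φ)·P)
traces, P the residual-maker of the design, C the AR(1) correlation
Toeplitz matrix) to the pooled observed ratio; the innovation variance is
scaled by the matching trace. This assumes a common noise process across
the cohort (true of the generator; an approximation for real data, applied
separately per level). Measured operating characteristics under the
generator's conditions (φ = 0.3, σ = 0.25): type-I error 4–5%, power ≈ 95%
over half-amplitudes 0.25–2.5, realized FDR ≈ 0.03–0.07 at q ≤ 0.05. The
per-series raw-values fit (`fit_ar1`) remains available
(`null_params="per-series"`) as a deliberately stringent variant, and is
what a lone `CosinorResults.test_cycling()` call uses, there being no
cohort to pool.

### Multiple testing

π₀ is estimated from π̂₀(λ) = #{p > λ}/(m(1−λ)) on λ = 0, 0.05, …, 0.90,
smoothed by a cubic polynomial evaluated at the largest λ and clamped to
(0, 1]; q-values are the step-up π̂₀·m·p/rank with the robust small-m
modifier dividing by 1 − (1−p)^m, clamped to [0, 1] and monotone in p. The
polynomial-smoothing reconstruction follows the classic q-value program's
option of that name; the method tag is recorded in every output. π₀
estimation is unreliable below a few hundred tests or when nearly all
series genuinely cycle — in small demonstration cohorts the estimate can
collapse to its 1/m floor, and the q cutoff (default 0.05, always reported)
should be read accordingly. The cycling-proportion correction
(r + Sp − 1)/(Se + Sp − 1) uses sensitivity/specificity measured by pushing
simulated cyclers (amplitudes from the significant fits) and pure-noise
series through the full test (`operating_characteristics`).

## Protein rollup

Processing order is fixed and audited: orient → CV filter → log2 → median
normalize → IIR → estimate → timecourse build → timepoint outliers. Every
run reports the counting identity peaks_in = retained + cv_filtered +
iir_flagged + rejected.

- **Orientation.** The ¹⁵N-labelled culture is a constant internal
  standard, so sample abundance is proportional to the light:heavy ratio;
  heavy:light inputs are inverted. Nonpositive ratios are rejected and
  counted.
- **CV filter.** One global threshold: the linearly interpolated 80th
  percentile of the pooled CV distribution; peaks strictly above are
  dropped. The realized threshold is logged (≈ 38–40% CV under generator
  defaults).
- **Median normalization.** Per-timepoint medians of retained log2 ratios
  are subtracted, absorbing deviations of the isotope mixing ratio from
  1:1. Offsets are returned for audit; recovery of injected biases is
  accurate to < 0.02 log2 at 10⁴ peaks per timepoint. Note the estimator is
  the median over *peaks*, so proteins with more peaks weigh more, and a
  cohort-wide shared oscillation would be partially absorbed — with many
  proteins at spread phases the effect is negligible.
- **IIR peak outliers.** For protein × timepoint groups of ≥ 4 retained
  peaks, score(x_i) = mean_{j≠i}|x_i − x_j| divided by the grand mean of
  all pairwise distances; values above 1.81 are flagged. The score is this
  package's concrete reconstruction of an under-specified published method,
  chosen to be scale- and shift-invariant so the cutoff reads as "1.81×
  more inconsistent than the group average". Zero-dispersion groups are
  guarded (no flags). Measured under generator defaults (group sizes
  1+Poisson(7), 5% injected peaks displaced by 5 median sigmas,
  heteroscedastic per-peak sigmas): sensitivity ≈ 0.69, false flags ≈ 3%.
  Sensitivity is limited by groups of 4–6 peaks, where the outlier's own
  displacement inflates the denominator, and by noisy-but-retained peaks
  for which a 5×-median-sigma displacement is only ~3 of their own sigmas.
- **Ratio estimate.** Lognormal fit on the natural log of the linear
  ratios; the point estimate is the lognormal mean exp(μ̂+σ̂²/2), reported
  in log2. σ̂ uses the N−1 denominator so that the Gurland–Tripathi factor
  c_N = √((N−1)/2)·Γ((N−1)/2)/Γ(N/2) makes c_N·σ̂ exactly unbiased for σ
  (the strict MLE's N denominator would defeat the correction). s is the
  fitted lognormal's linear-scale sd √(exp(σ̂²)−1)·exp(μ̂+σ̂²/2); the 95% CI
  is point ± 1.96·c_N·s/√N on the linear ratio scale, then log2-transformed
  (asymmetric in log2; a lower bound at or below zero becomes −inf).
  Measured coverage of this z-based interval at N = 8 is ≈ 0.91, not 0.95:
  c_N removes the bias of s but not its sampling variability, which only a
  t-quantile would absorb (≈ 0.92 coverage in the normal limit, less with
  lognormal skew). `use_t=True` switches to the t-quantile for users who
  want nominal coverage; the default keeps the z form. N = 1 groups carry
  the single ratio with an undefined-wide CI and a flag.
- **Timecourse construction.** A protein enters the output if ≥ 8
  timepoints hold ≥ k peaks, with k lowered 4→3→2→1; the per-protein k is
  recorded. Proteins failing at k = 1 are counted detected-but-unresolvable.
- **Timepoint outliers.** d_i = |y_i − y_{i−1}| + |y_i − y_{i+1}|
  (endpoints: twice their single neighbor distance); points with
  d_i > 4.15 × mean(d) are flagged and masked from fitting. The rule is
  model-free. Constant series (mean d = 0) are never flagged. Under
  generator defaults (+3-log2 spikes at a 1.1% rate on series carrying
  sinusoidal signal, AR(1) noise and rollup noise) measured sensitivity is
  ≈ 0.4–0.5 with ≈ 0 false flags: the factor 4.15 is aggressive when the
  series' own dynamics contribute nearest-neighbor distance, and a spike of
  +3 (d ≈ 6) falls under the threshold whenever mean(d) exceeds ≈ 1.45. The
  factor is kept configurable (`nn_factor`).

## Transcript quantification

Normalized abundance = (sum of per-base depth over the gene body on the
gene's strand)/gene length/total aligned bases; the opposite strand gives
the antisense abundance. No deconvolution of opposite-strand overlaps is
attempted (none exist in the generator's gene layout). "Antisense detected"
means any nonzero antisense coverage in the gene body (configurable minimum
threshold), and the antisense:sense ratio is averaged over genes with
antisense detected and sense > 0 — averaging over all genes would conflate
prevalence with abundance. Per-timepoint fractions are summarized as
mean ± sd across timepoints. For rhythm detection, sense abundances are
log2-transformed with a pseudo-floor for zeros (default: half the smallest
nonzero abundance, logged in the output).

## Paired comparison

The protein–transcript lag is ((φ_protein − φ_mRNA + 2) mod 24) − 2, a
bijection onto (−2, 22]: offsets within ±2 h (the sampling resolution)
count as in phase, and all larger offsets are positive — the protein
maximum is read as following the transcript peak, possibly of the previous
cycle. Phase classes partition every paired gene: in_phase (|lag| ≤ 2),
lagged_2_8 (2 < lag ≤ 8), antiphase (11 ≤ lag ≤ 13), other (the unnamed
8–11 and 13–22 gaps). Amplitude comparison reports both conventions in
use — the ratio of half-amplitudes in log2 units (H_m/H_p) and the ratio of
fold changes 2^(2(H_m−H_p)) — because they answer different questions and
differ numerically; damping means H_m/H_p > 1. "Transcriptional control" is
the conjunction of in-phase timing and fold-change ratios within 2× either
way. Peak-window summaries (defaults: morning 02:00–05:00, evening
16:00–20:00, inclusive) report per-window n and median lag. Only genes
cycling significantly at both levels with defined phases are paired; with
damped protein amplitudes a large fraction of true cyclers is expected to
drop out at the protein level, and paired-cohort medians are conditioned
on that selection (e.g. the paired median amplitude ratio sits below the
generating median).

## Synthetic generator

Per gene: mRNA log2 series = baseline + H·cos(2π(t−φ)/24) + AR(1) noise;
protein series use phase φ + lag and half-amplitude H/ratio with the
damping ratio ≥ 1. Defaults encode the experiment the pipeline targets:
14-point 2-h grid; 87% cyclers (the observed transcript cycling
proportion); phases uniform; mRNA half-amplitudes uniform on [0.25, 2.5]
log2; damping ratio lognormal with median 4.9 (the observed median
amplitude ratio in log2 units); lags normal(5, 3) h wrapped into (−2, 22];
AR(1) noise φ = 0.3, innovation sd 0.25 log2; peaks per protein×timepoint
1+Poisson(7) (a mix of data-rich and data-poor proteins that exercises the
threshold-lowering rule); per-peak scatter lognormal around a median sigma
of 0.35 log2 with lognormal spread 0.5, the reported CV computed exactly
from each peak's sigma (so CV filtering removes genuinely noisy peaks);
mixing biases N(0, 0.05) log2 per timepoint; 5% outlier peaks displaced
±5 median sigmas; 1.1% spiked timepoints (+3 log2); antisense assigned to
73% of genes with gene-level sense fractions lognormal around mean 0.354;
Poisson per-base coverage at mean sense depth 25. The peaks-per-timepoint
and peak-sigma values are calibration choices (the underlying distributions
are not published), fixed once; the realized 80th-percentile CV threshold
they produce (≈ 38–40%) lands close to the printed 41%.

Reproducibility: every stream derives from (master seed, gene index, stage
code), so identical configs are bit-identical and adding genes never
perturbs existing series. One caveat: the exact cycler count round(n·f) is
assigned to the leading gene indices, so changing n relabels which genes
cycle; the underlying per-gene parameter draws are unaffected.

What the generator does **not** emulate: read-level or spectrum-level
noise, peptide-to-protein inference ambiguity, heteroscedastic noise across
genes (the AR(1) process is homoscedastic — precisely the assumption the
pooled null estimator exploits), antisense presence varying across
timepoints within a gene, overlapping gene models, and non-sinusoidal
waveforms. Passing tests therefore demonstrate correctness of the
machinery under these idealized conditions, not robustness to every
property of real data.

## Numerical choices and degenerate inputs

Percentiles are linearly interpolated between order statistics. Harmonic
fits use a cached pseudoinverse per time grid. Fits require ≥ 4 points
spanning ≥ half a period; rhythm detection requires ≥ 8. AR(1) φ estimates
are clamped to ±0.99 with a warning. p-values are add-one; q-values
clamped to [0, 1]; π̂₀ clamped to (0, 1] with a 1/m floor. Constant series:
flat fit, undefined phase, degenerate null, no outlier flags. Empty inputs
raise immediately with the offending field or file named; malformed GFF3 or
bedGraph lines raise parse errors with line numbers, never silent coercion.
Table floats are written at 6 significant digits, which is what makes
byte-identical reruns possible.

## Problem sizes

The test suite and the acceptance script run cohorts of 400–1200 genes with
1000-simulation nulls (roughly 10⁶–10⁷ simulated series per full run),
chosen as the smallest sizes at which the binomial error of the measured
rates is well inside the tolerances being checked; all complete in minutes
on one CPU.

## Known limitations

- The pooled AR(1) null assumes homoscedastic noise within a level; cohorts
  with strongly gene-dependent noise would need the stringent per-series
  variant or an intermediate shrinkage estimator (not implemented).
- The z-based 95% CI undercovers at small N (≈ 0.91 at N = 8); see above.
- The IIR rule at cutoff 1.81 has limited sensitivity in groups of 4–6
  peaks, and the 4.15× timepoint rule has limited sensitivity on series
  with substantial intrinsic dynamics; both cutoffs are faithful to the
  published workflow and configurable.
- π₀/q-value calibration needs cohorts of hundreds of tests.
- Antisense positional analysis within gene bodies is exported as raw
  per-gene coverage only; no positional statistic is claimed.
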