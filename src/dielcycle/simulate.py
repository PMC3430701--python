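"""Ground-truthed synthetic data generator.

Emulates a synchronized light/dark experiment sampled every 2 h over 26 h:
sinusoidal 24-h log2-abundance signals with gene-specific phase and amplitude,
protein oscillations damped and lagged relative to the transcript, AR(1)
observation noise, lognormal peptide-peak scatter with heteroscedastic
reported CVs, per-timepoint isotope mixing biases, injected outlier peaks and
timepoints, and strand-specific Poisson read coverage with antisense
transcription for a configurable fraction of genes.

Reproducibility contract: per-gene generator streams are derived from
``(master seed, gene index, stage code)`` so identical configs give
bit-identical outputs and adding genes never perturbs existing series.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig, sample_dist
from .timecourse import Timecourse
from .transcripts import GeneModel, StrandCoverage

PERIOD_H = 24.0

# stage codes for per-gene substreams
_TRUTH, _MRNA, _PROTEIN, _PEAKS, _COVERAGE = 0, 1, 2, 3, 4


def _gene_rng(seed: int, gene_index: int, stage: int, extra: int | None = None):
    keys = [seed, gene_index, stage]
    if extra is not None:
        keys.append(extra)
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass
class DielTruth:
    """Generating parameters for one gene (the ground truth for recovery tests)."""

    gene_id: str
    mrna_phase: float        # hours in [0, 24)
    mrna_halfamp: float      # log2 units
    protein_halfamp: float   # log2 units
    lag: float               # hours; protein phase = (mrna_phase + lag) mod 24
    mrna_baseline: float
    protein_baseline: float
    is_cycler: bool

    @property
    def protein_phase(self) -> float:
        return (self.mrna_phase + self.lag) % PERIOD_H


def generate_diel_truth(config: SimConfig) -> list:
    """Draw per-gene phases, amplitudes, lags and baselines.

    Exactly ``round(n_genes * fraction_cyclers)`` genes are cyclers (the
    leading indices; gene parameters are iid so the labelling is
    exchangeable).  Non-cyclers have both half-amplitudes equal to zero.
    """
    config.validate()
    n = config.n_genes
    n_cyclers = int(round(n * config.fraction_cyclers))
    width = max(4, len(str(n)))
    truth = []
    for i in range(n):
        rng = _gene_rng(config.seed, i, _TRUTH)
        phase = float(sample_dist(config.phase_dist, 1, rng, "phase_dist")[0]) % PERIOD_H
        halfamp = abs(float(sample_dist(config.halfamp_dist, 1, rng, "halfamp_dist")[0]))
        ratio = float(sample_dist(config.amp_ratio_dist, 1, rng, "amp_ratio_dist")[0])
        if config.damping:
            ratio = max(ratio, 1.0)
        elif ratio <= 0:
            ratio = 1.0
        lag = float(sample_dist(config.lag_dist, 1, rng, "lag_dist")[0])
        lag = ((lag + 2.0) % PERIOD_H) - 2.0    # canonical (-2, 22] window
        mrna_base = float(sample_dist(config.baseline_dist, 1, rng, "baseline_dist")[0])
        protein_base = float(sample_dist(config.baseline_dist, 1, rng, "baseline_dist")[0])
        is_cycler = i < n_cyclers
        truth.append(DielTruth(
            gene_id=f"gene_{i:0{width}d}",
            mrna_phase=phase,
            mrna_halfamp=halfamp if is_cycler else 0.0,
            protein_halfamp=(halfamp / ratio) if is_cycler else 0.0,
            lag=lag,
            mrna_baseline=mrna_base,
            protein_baseline=protein_base,
            is_cycler=is_cycler,
        ))
    return truth


def ar1_noise(rng: np.random.Generator, n: int, phi: float, innovation_sd: float,
              size: int | None = None) -> np.ndarray:
    """Stationary AR(1) noise: e_t = phi*e_{t-1} + N(0, innovation_sd^2).

    The first point is drawn from the stationary distribution
    N(0, innovation_sd^2/(1-phi^2)), avoiding burn-in artifacts on short
    series.  With ``size`` given, returns shape (size, n).
    """
    shape = (n,) if size is None else (size, n)
    if innovation_sd == 0:
        return np.zeros(shape)
    e = np.empty(shape)
    stat_sd = innovation_sd / np.sqrt(1.0 - phi * phi)
    e[..., 0] = rng.normal(0.0, stat_sd, None if size is None else size)
    for t in range(1, n):
        e[..., t] = phi * e[..., t - 1] + rng.normal(
            0.0, innovation_sd, None if size is None else size)
    return e


def _cosine(times, baseline, halfamp, phase):
    return baseline + halfamp * np.cos(2 * np.pi * (np.asarray(times) - phase) / PERIOD_H)


def simulate_timecourses(truth, config: SimConfig):
    """Simulate (mRNA, protein) log2 timecourses for every gene.

    value(t) = baseline + H*cos(2*pi*(t - phase)/24) + AR(1) noise.
    """
    config.validate()
    times = np.asarray(config.times, dtype=float)
    n = len(times)
    mrna, protein = [], []
    for i, g in enumerate(truth):
        for level, store, stage, phase, amp, base in (
                ("mRNA", mrna, _MRNA, g.mrna_phase, g.mrna_halfamp, g.mrna_baseline),
                ("protein", protein, _PROTEIN, g.protein_phase, g.protein_halfamp,
                 g.protein_baseline)):
            rng = _gene_rng(config.seed, i, stage)
            noise = ar1_noise(rng, n, config.ar1_phi, config.innovation_sd)
            store.append(Timecourse(id=g.gene_id, level=level, times=times,
                                    values=_cosine(times, base, amp, phase) + noise))
    return mrna, protein


def mixing_biases(config: SimConfig) -> np.ndarray:
    """Per-timepoint log2 mixing-ratio offsets b_t (deviation from 1:1 mixing)."""
    if config.mixing_bias is not None:
        return np.asarray(config.mixing_bias, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000_019]))
    return rng.normal(0.0, config.mixing_bias_sd, len(config.times))


def simulate_peak_table(protein_timecourses, config: SimConfig):
    """Generate the peptide peak-ratio table around the protein timecourses.

    Returns ``(peaks, truth)`` DataFrames.  ``peaks`` has one row per
    quantified peakgroup pair (peak_id, protein_id, timepoint_index, time_h,
    ratio, cv) with the ratio in the configured orientation.  ``truth``
    records the per-peak generating values and injected-outlier flags plus
    per-timepoint spike flags.
    """
    config.validate()
    biases = mixing_biases(config)
    sigma_spread = float(config.cv_model.get("sigma_spread", 0.0))
    ln2 = np.log(2.0)
    rows, truth_rows = [], []
    for i, tc in enumerate(protein_timecourses):
        rng = _gene_rng(config.seed, i, _PEAKS)
        counts = sample_dist(config.peaks_per_timepoint_dist, len(tc.times), rng,
                             "peaks_per_timepoint_dist").astype(int)
        spikes = rng.random(len(tc.times)) < config.outlier_timepoint_rate
        for j, (t, v) in enumerate(zip(tc.times, tc.values)):
            true_log2 = v + (config.outlier_timepoint_shift if spikes[j] else 0.0)
            for k in range(counts[j]):
                if sigma_spread > 0:
                    sig = config.peak_sigma * rng.lognormal(0.0, sigma_spread)
                else:
                    sig = config.peak_sigma
                is_out = rng.random() < config.outlier_peak_rate
                disp = 0.0
                if is_out:
                    disp = config.outlier_peak_scale * config.peak_sigma * rng.choice((-1.0, 1.0))
                log2_ratio = true_log2 + biases[j] + rng.normal(0.0, sig) + disp
                cv = float(np.sqrt(np.expm1((sig * ln2) ** 2)))
                ratio = 2.0 ** log2_ratio
                if config.peak_orientation == "heavy_over_light":
                    ratio = 1.0 / ratio
                peak_id = f"{tc.id}_t{j:02d}_p{k:03d}"
                rows.append((peak_id, tc.id, j, t, ratio, cv))
                truth_rows.append((peak_id, tc.id, j, true_log2, biases[j], sig,
                                   bool(is_out), disp, bool(spikes[j])))
    peaks = pd.DataFrame(rows, columns=[
        "peak_id", "protein_id", "timepoint_index", "time_h", "ratio", "cv"])
    truth = pd.DataFrame(truth_rows, columns=[
        "peak_id", "protein_id", "timepoint_index", "true_log2", "mixing_bias",
        "peak_sigma", "is_outlier_peak", "displacement", "is_outlier_timepoint"])
    return peaks, truth


def make_gene_models(config: SimConfig) -> list:
    """Lay the genes out on one chromosome, alternating strands, with gaps."""
    genes = []
    pos = config.gene_gap
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        start, end = pos, pos + config.gene_length
        genes.append(GeneModel(gene_id=f"gene_{i:0{width}d}", start=start, end=end,
                               strand="+" if i % 2 == 0 else "-"))
        pos = end + config.gene_gap
    return genes


def genome_length(config: SimConfig) -> int:
    return config.n_genes * (config.gene_length + config.gene_gap) + config.gene_gap


def antisense_assignment(config: SimConfig):
    """Which genes carry antisense transcription, and at what sense fraction.

    The per-gene antisense:sense ratio is lognormal with mean
    ``antisense_ratio_mean``; assignment and ratio are fixed per gene across
    timepoints (antisense presence is a gene property in this generator).
    """
    has_as = np.zeros(config.n_genes, dtype=bool)
    ratios = np.zeros(config.n_genes)
    sdlog = config.antisense_ratio_sdlog
    meanlog = np.log(config.antisense_ratio_mean) - 0.5 * sdlog ** 2 \
        if config.antisense_ratio_mean > 0 else -np.inf
    for i in range(config.n_genes):
        rng = _gene_rng(config.seed, i, _COVERAGE)
        has_as[i] = rng.random() < config.antisense_detect_prob
        if has_as[i] and np.isfinite(meanlog):
            ratios[i] = rng.lognormal(meanlog, sdlog)
    return has_as, ratios


def simulate_coverage(mrna_timecourses, gene_models, config: SimConfig):
    """Yield per-timepoint strand-specific coverage (lazy, one timepoint at a time).

    Per-base sense depth is Poisson with mean proportional to the linear mRNA
    abundance 2**log2_value, scaled so the mean per-base sense depth across
    genes equals ``depth``.  Antisense depth is generated on the opposite
    strand for the assigned genes at their gene-specific sense fraction.
    """
    config.validate()
    glen = genome_length(config)
    for g in gene_models:
        if g.start < 0 or g.end > glen:
            raise ValueError(f"gene {g.gene_id} outside chromosome bounds [0, {glen})")
    has_as, as_ratios = antisense_assignment(config)
    values = np.array([tc.values for tc in mrna_timecourses])  # (n_genes, n_times)
    linear = 2.0 ** values
    scale = config.depth / linear.mean(axis=0)                 # per-timepoint scaling
    n_times = len(config.times)
    for j in range(n_times):
        plus = np.zeros(glen)
        minus = np.zeros(glen)
        for i, g in enumerate(gene_models):
            rng = _gene_rng(config.seed, i, _COVERAGE, extra=j + 1)
            lam = linear[i, j] * scale[j]
            sense = rng.poisson(lam, g.length)
            anti = rng.poisson(lam * as_ratios[i], g.length) if has_as[i] else None
            if g.strand == "+":
                plus[g.start:g.end] += sense
                if anti is not None:
                    minus[g.start:g.end] += anti
            else:
                minus[g.start:g.end] += sense
                if anti is not None:
                    plus[g.start:g.end] += anti
        total = float(plus.sum() + minus.sum())
        yield StrandCoverage(timepoint_index=j, plus=plus, minus=minus,
                             total_aligned_bp=total)


def truth_to_frame(truth) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": g.gene_id,
        "mrna_phase": g.mrna_phase,
        "mrna_halfamp": g.mrna_halfamp,
        "protein_halfamp": g.protein_halfamp,
        "lag": g.lag,
        "protein_phase": g.protein_phase,
        "mrna_baseline": g.mrna_baseline,
        "protein_baseline": g.protein_baseline,
        "is_cycler": g.is_cycler,
    } for g in truth])
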