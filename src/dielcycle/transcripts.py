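"""Gene-level quantification of strand-specific coverage.

Normalized abundance of a gene at one timepoint is the per-base coverage
summed over the gene body on the gene's strand, divided by gene length, and
divided by the total number of aligned bases at that timepoint — a
depth-normalized mean coverage, dimensionless and comparable across samples.
The same quantity computed on the opposite strand is the antisense abundance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timecourse import Timecourse


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 0-based half-open coordinates on one strand."""

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StrandCoverage:
    """Per-base depth arrays for both strands at one timepoint."""

    timepoint_index: int
    plus: np.ndarray
    minus: np.ndarray
    total_aligned_bp: float

    def __post_init__(self):
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        if len(self.plus) != len(self.minus):
            raise ValueError("strand coverage arrays differ in length")
        if np.any(self.plus < 0) or np.any(self.minus < 0):
            raise ValueError("coverage depths must be >= 0")
        if self.total_aligned_bp <= 0:
            raise ValueError("total_aligned_bp must be > 0")


def summarize_gene_coverage(coverage: StrandCoverage, genes) -> pd.DataFrame:
    """Sense/antisense normalized abundance per gene for one timepoint.

    sense = sum(depth over gene on gene strand) / length / total_aligned_bp;
    antisense is the same sum on the opposite strand.
    """
    glen = len(coverage.plus)
    rows = []
    for g in genes:
        if g.start < 0 or g.end > glen:
            raise ValueError(
                f"gene {g.gene_id} interval [{g.start}, {g.end}) outside chromosome "
                f"bounds [0, {glen})")
        same = coverage.plus if g.strand == "+" else coverage.minus
        opp = coverage.minus if g.strand == "+" else coverage.plus
        sense = same[g.start:g.end].sum() / g.length / coverage.total_aligned_bp
        anti = opp[g.start:g.end].sum() / g.length / coverage.total_aligned_bp
        frac = anti / sense if sense > 0 else np.nan
        rows.append((g.gene_id, coverage.timepoint_index, sense, anti, frac))
    return pd.DataFrame(rows, columns=[
        "gene_id", "timepoint_index", "sense", "antisense", "antisense_fraction"])


def quantify_timepoints(coverages, genes) -> pd.DataFrame:
    """Concatenate :func:`summarize_gene_coverage` over an iterable of timepoints."""
    return pd.concat([summarize_gene_coverage(c, genes) for c in coverages],
                     ignore_index=True)


def antisense_stats(abundances: pd.DataFrame, detect_threshold: float = 0.0) -> tuple:
    """Antisense prevalence and relative abundance.

    Per timepoint: the fraction of genes with antisense abundance above
    ``detect_threshold`` (default: any nonzero coverage), and the mean
    antisense:sense percentage over genes where antisense was detected and
    sense > 0.  The across-timepoint summary reports mean +/- sd of both.

    Returns ``(per_timepoint DataFrame, summary dict)``.
    """
    if abundances.empty:
        raise ValueError("no abundances supplied")
    rows = []
    for tp, sub in abundances.groupby("timepoint_index", sort=True):
        detected = sub["antisense"] > detect_threshold
        frac = float(detected.mean())
        expressed = detected & (sub["sense"] > 0)
        if expressed.any():
            ratio = float((sub.loc[expressed, "antisense"]
                           / sub.loc[expressed, "sense"]).mean())
        else:
            ratio = 0.0
        rows.append((tp, frac, ratio))
    per_tp = pd.DataFrame(rows, columns=["timepoint_index", "detect_fraction",
                                         "mean_antisense_sense_ratio"])
    summary = {
        "detect_fraction_mean": float(per_tp["detect_fraction"].mean()),
        "detect_fraction_sd": float(per_tp["detect_fraction"].std(ddof=1))
        if len(per_tp) > 1 else 0.0,
        "antisense_sense_ratio_mean": float(per_tp["mean_antisense_sense_ratio"].mean()),
        "antisense_sense_ratio_sd": float(per_tp["mean_antisense_sense_ratio"].std(ddof=1))
        if len(per_tp) > 1 else 0.0,
        "n_timepoints": int(len(per_tp)),
    }
    return per_tp, summary


def gene_positional_coverage(coverage: StrandCoverage, gene: GeneModel) -> pd.DataFrame:
    """Per-base sense/antisense depth along one gene body (5'->3' on the
    gene's strand), for positional inspection of antisense coverage."""
    if gene.start < 0 or gene.end > len(coverage.plus):
        raise ValueError(f"gene {gene.gene_id} outside chromosome bounds")
    same = coverage.plus if gene.strand == "+" else coverage.minus
    opp = coverage.minus if gene.strand == "+" else coverage.plus
    sense = same[gene.start:gene.end]
    anti = opp[gene.start:gene.end]
    if gene.strand == "-":
        sense, anti = sense[::-1], anti[::-1]
    return pd.DataFrame({"position": np.arange(gene.length),
                         "sense": sense, "antisense": anti})


def to_log2_timecourses(abundances: pd.DataFrame, times, floor: float | None = None):
    """Convert sense abundances into log2 timecourses for rhythm detection.

    Zero abundances are replaced by ``floor`` before the log; the default
    floor is half the smallest nonzero sense abundance in the table.
    """
    times = np.asarray(times, dtype=float)
    sense = abundances.pivot(index="gene_id", columns="timepoint_index", values="sense")
    sense = sense.sort_index(axis=1)
    if sense.shape[1] != len(times):
        raise ValueError(f"{sense.shape[1]} timepoints in table but {len(times)} times given")
    if floor is None:
        nonzero = sense.values[sense.values > 0]
        floor = float(nonzero.min()) / 2.0 if len(nonzero) else 1.0
    vals = np.log2(np.maximum(sense.values, floor))
    return [Timecourse(id=gid, level="mRNA", times=times, values=vals[i])
            for i, gid in enumerate(sense.index)]
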