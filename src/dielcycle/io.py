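"""File formats: TSV tables with unit headers, GFF3 gene models, bedGraph
coverage.

Every table written by the package starts with ``#``-prefixed header lines
naming the units of its columns and the hash of the producing configuration;
readers skip those lines.  GFF3 is 1-based closed on disk and converted to
0-based half-open internally; bedGraph intervals are half-open as the format
specifies.  Malformed lines raise :class:`ParseError` naming the line number
— never silent coercion.
"""
from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .timecourse import frame_to_timecourses, timecourses_to_frame
from .transcripts import GeneModel, StrandCoverage


class ParseError(ValueError):
    pass


_FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path, units: str = "", config_hash: str = "") -> None:
    with open(path, "w") as fh:
        if units:
            fh.write(f"# units: {units}\n")
        if config_hash:
            fh.write(f"# config: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FORMAT,
                  lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_timecourses(tcs, path, config_hash: str = "") -> None:
    write_table(timecourses_to_frame(tcs), path,
                units="time_h: hours; log2_abundance: log2 units",
                config_hash=config_hash)


def read_timecourses(path):
    df = read_table(path)
    required = {"id", "level", "time_h", "log2_abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return frame_to_timecourses(df)


def write_peaks(peaks: pd.DataFrame, path, config_hash: str = "") -> None:
    write_table(peaks, path, units="time_h: hours; ratio: linear; cv: proportion",
                config_hash=config_hash)


def read_peaks(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"peak_id", "protein_id", "timepoint_index", "time_h", "ratio", "cv"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(genes, path, source: str = "dielcycle") -> None:
    """Internal 0-based half-open -> GFF3 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                "chr1", source, "gene", str(g.start + 1), str(g.end), ".",
                g.strand, ".", f"ID={g.gene_id}"]) + "\n")


def read_gff3(path, feature_types=("gene",)) -> list:
    """Parse gene features; GFF3 1-based closed -> 0-based half-open."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, "
                                 f"got {len(parts)}")
            _, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in feature_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates")
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"{path}:{lineno}: invalid coordinates {start}..{end}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: feature without ID attribute")
            genes.append(GeneModel(gene_id=gene_id, start=start_i - 1, end=end_i,
                                   strand=strand))
    return genes


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(depths: np.ndarray, path, chrom: str = "chr1") -> None:
    """Run-length encode a per-base depth array (half-open intervals)."""
    depths = np.asarray(depths)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{os.path.basename(path)}"\n')
        if len(depths) == 0:
            return
        boundaries = np.flatnonzero(np.diff(depths)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(depths)]])
        for s, e in zip(starts, ends):
            v = depths[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{_FLOAT_FORMAT % v}\n")


def read_bedgraph(path, length: int) -> np.ndarray:
    """Expand a bedGraph file into a per-base depth array of ``length``."""
    depths = np.zeros(length)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            _, start, end, value = parts
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric fields")
            if v < 0:
                raise ParseError(f"{path}:{lineno}: negative depth {v}")
            if s < 0 or e > length or s >= e:
                raise ParseError(f"{path}:{lineno}: interval [{s}, {e}) outside [0, {length})")
            depths[s:e] = v
    return depths


def coverage_filename(timepoint_index: int, strand: str) -> str:
    return f"cov_t{timepoint_index}_{'plus' if strand == '+' else 'minus'}.bedgraph"


def write_coverage_dir(coverages, out_dir) -> pd.DataFrame:
    """Write one bedGraph per strand per timepoint plus the totals table.

    Consumes an iterable of :class:`StrandCoverage` lazily; returns the
    totals DataFrame (timepoint_index, total_aligned_bp).
    """
    os.makedirs(out_dir, exist_ok=True)
    totals = []
    for cov in coverages:
        write_bedgraph(cov.plus, os.path.join(out_dir, coverage_filename(cov.timepoint_index, "+")))
        write_bedgraph(cov.minus, os.path.join(out_dir, coverage_filename(cov.timepoint_index, "-")))
        totals.append((cov.timepoint_index, cov.total_aligned_bp))
    df = pd.DataFrame(totals, columns=["timepoint_index", "total_aligned_bp"])
    write_table(df, os.path.join(out_dir, "totals.tsv"), units="total_aligned_bp: bp")
    return df


def read_coverage_dir(cov_dir, totals_path, length: int):
    """Yield StrandCoverage per timepoint from a coverage directory."""
    totals = read_table(totals_path)
    for _, row in totals.sort_values("timepoint_index").iterrows():
        tp = int(row["timepoint_index"])
        plus = read_bedgraph(os.path.join(cov_dir, coverage_filename(tp, "+")), length)
        minus = read_bedgraph(os.path.join(cov_dir, coverage_filename(tp, "-")), length)
        yield StrandCoverage(timepoint_index=tp, plus=plus, minus=minus,
                             total_aligned_bp=float(row["total_aligned_bp"]))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
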