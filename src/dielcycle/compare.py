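"""Paired mRNA-protein comparison: lags, amplitude ratios, phase classes.

The protein-transcript lag is wrapped into (-2, 22]: offsets within +/-2 h
count as in phase (matching the 2-h sampling resolution), while every larger
offset is taken as positive — the protein maximum is read as following the
transcript peak of the previous diel cycle.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

PERIOD_H = 24.0

PHASE_CLASSES = ("in_phase", "lagged_2_8", "antiphase", "other")


def compute_lag(phase_mrna: float, phase_protein: float) -> float:
    """Protein-transcript lag, hours in (-2, 22].

    lag = ((phase_protein - phase_mrna + 2) mod 24) - 2.  NaN phases (flat
    fits) yield NaN.
    """
    if np.isnan(phase_mrna) or np.isnan(phase_protein):
        return float("nan")
    return float(((phase_protein - phase_mrna + 2.0) % PERIOD_H) - 2.0)


def amplitude_ratio(halfamp_mrna: float, halfamp_protein: float) -> tuple:
    """Transcript:protein amplitude comparison, both ways the field states it.

    Returns ``(amp_ratio_log, amp_ratio_fold)`` where amp_ratio_log is the
    ratio of half-amplitudes in log2 units (H_m / H_p) and amp_ratio_fold is
    the ratio of peak-to-trough fold changes, 2**(2*(H_m - H_p)).  A zero
    protein amplitude gives an infinite log ratio (undamped flag upstream).
    """
    fold = float(2.0 ** (2.0 * (halfamp_mrna - halfamp_protein)))
    if halfamp_protein == 0:
        return float("inf"), fold
    return float(halfamp_mrna / halfamp_protein), fold


def classify_phase_relationship(lag: float, in_phase_window: float = 2.0,
                                lag_band=(2.0, 8.0), antiphase_band=(11.0, 13.0)) -> str:
    """Partition the lag into the named phase-relationship classes.

    |lag| <= 2 h -> in_phase; 2 < lag <= 8 -> lagged_2_8; 11 <= lag <= 13 ->
    antiphase; anything else (including the unnamed 8-11 h and 13-22 h gaps)
    -> other.
    """
    if np.isnan(lag):
        raise ValueError("lag undefined")
    if abs(lag) <= in_phase_window:
        return "in_phase"
    if lag_band[0] < lag <= lag_band[1]:
        return "lagged_2_8"
    if antiphase_band[0] <= lag <= antiphase_band[1]:
        return "antiphase"
    return "other"


def classify_transcriptional_control(lag: float, amp_ratio_fold: float,
                                     in_phase_window: float = 2.0,
                                     control_fold: float = 2.0) -> bool:
    """Direct transcriptional control: in phase and amplitudes within
    ``control_fold`` of each other (fold ratio between 1/2 and 2 by default)."""
    if np.isnan(lag) or not np.isfinite(amp_ratio_fold):
        return False
    ratio = max(amp_ratio_fold, 1.0 / amp_ratio_fold) if amp_ratio_fold > 0 else np.inf
    return bool(abs(lag) <= in_phase_window and ratio <= control_fold)


def pair_cycling(mrna: pd.DataFrame, protein: pd.DataFrame,
                 require_significant: bool = True,
                 in_phase_window: float = 2.0, lag_band=(2.0, 8.0),
                 antiphase_band=(11.0, 13.0), control_fold: float = 2.0) -> pd.DataFrame:
    """Join per-gene cycling results from both levels and derive the paired stats.

    Only genes cycling significantly at both levels with defined phases enter
    (the paired cohort); set ``require_significant=False`` to pair every gene
    with finite fits on both levels.
    """
    cols = ["id", "halfamp", "fold_change", "phase_h", "q", "significant"]
    m = mrna[cols].rename(columns={c: f"mrna_{c}" for c in cols if c != "id"})
    p = protein[cols].rename(columns={c: f"protein_{c}" for c in cols if c != "id"})
    df = m.merge(p, on="id", how="inner")
    if require_significant:
        df = df[df["mrna_significant"].fillna(False)
                & df["protein_significant"].fillna(False)]
    df = df[np.isfinite(df["mrna_phase_h"]) & np.isfinite(df["protein_phase_h"])].copy()
    if df.empty:
        for c in ("lag", "amp_ratio_log", "amp_ratio_fold"):
            df[c] = []
        df["phase_class"] = []
        df["damped"] = []
        df["transcriptional_control"] = []
        return df.rename(columns={"id": "gene_id"})
    df["lag"] = [compute_lag(a, b) for a, b in
                 zip(df["mrna_phase_h"], df["protein_phase_h"])]
    ratios = [amplitude_ratio(a, b) for a, b in
              zip(df["mrna_halfamp"], df["protein_halfamp"])]
    df["amp_ratio_log"] = [r[0] for r in ratios]
    df["amp_ratio_fold"] = [r[1] for r in ratios]
    df["damped"] = df["amp_ratio_log"] > 1.0
    df["phase_class"] = [classify_phase_relationship(l, in_phase_window, lag_band,
                                                     antiphase_band)
                         for l in df["lag"]]
    df["transcriptional_control"] = [
        classify_transcriptional_control(l, f, in_phase_window, control_fold)
        for l, f in zip(df["lag"], df["amp_ratio_fold"])]
    return df.rename(columns={"id": "gene_id"})


def lag_by_peak_window(paired: pd.DataFrame,
                       windows={"morning": (2.0, 5.0), "evening": (16.0, 20.0)}) -> dict:
    """Median protein-transcript lag for genes whose transcript peaks inside
    each clock-time window (bounds inclusive; phases taken mod 24)."""
    out = {}
    clock = paired["mrna_phase_h"] % PERIOD_H
    for name, (lo, hi) in windows.items():
        inside = (clock >= lo) & (clock <= hi)
        lags = paired.loc[inside, "lag"]
        out[name] = {"n": int(inside.sum()),
                     "median_lag_h": float(lags.median()) if inside.any() else None,
                     "window_h": [lo, hi]}
    return out


def summarize_cohort(paired: pd.DataFrame) -> dict:
    """Headline summary of a paired cohort (counts per class, damping, medians)."""
    if paired.empty:
        raise ValueError("empty paired cohort")
    n = len(paired)
    counts = {c: int((paired["phase_class"] == c).sum()) for c in PHASE_CLASSES}
    finite_log = paired["amp_ratio_log"][np.isfinite(paired["amp_ratio_log"])]
    return {
        "n_paired": n,
        "phase_class_counts": counts,
        "damped_count": int(paired["damped"].sum()),
        "damped_fraction": float(paired["damped"].mean()),
        "median_amp_ratio_log": float(finite_log.median()) if len(finite_log) else None,
        "median_amp_ratio_fold": float(paired["amp_ratio_fold"].median()),
        "median_lag_h": float(paired["lag"].median()),
        "transcriptional_control_count": int(paired["transcriptional_control"].sum()),
        "peak_windows": lag_by_peak_window(paired),
    }
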