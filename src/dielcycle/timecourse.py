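"""Shared per-gene timecourse container used by the mRNA and protein stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Timecourse:
    """A log2-abundance series on the sampling grid.

    Attributes
    ----------
    id : series identifier (gene or protein id)
    level : one of ``mRNA``, ``protein``, ``other``
    times : hours since experiment start, strictly increasing
    values : log2 abundance (or log2 sample:standard ratio)
    mask : per-point retained flag; masked-out points are excluded from fits
    errors : optional per-point uncertainty (half CI width, log2 units)
    """

    id: str
    level: str
    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray = None
    errors: np.ndarray = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.times), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.times) != len(self.values) or len(self.mask) != len(self.times):
            raise ValueError(f"timecourse {self.id}: times/values/mask length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"timecourse {self.id}: times must be strictly increasing")

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def retained(self) -> tuple:
        return self.times[self.mask], self.values[self.mask]


def timecourses_to_frame(tcs) -> pd.DataFrame:
    """Long-format table: id, level, time_h, log2_abundance, retained."""
    rows = []
    for tc in tcs:
        for t, v, m in zip(tc.times, tc.values, tc.mask):
            rows.append((tc.id, tc.level, t, v, bool(m)))
    return pd.DataFrame(rows, columns=["id", "level", "time_h", "log2_abundance", "retained"])


def frame_to_timecourses(df: pd.DataFrame) -> list:
    out = []
    for (gid, level), sub in df.groupby(["id", "level"], sort=True):
        sub = sub.sort_values("time_h")
        retained = sub["retained"].to_numpy() if "retained" in sub else None
        out.append(Timecourse(id=gid, level=level,
                              times=sub["time_h"].to_numpy(),
                              values=sub["log2_abundance"].to_numpy(),
                              mask=retained))
    return out
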