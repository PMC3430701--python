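"""Configuration objects for simulation and pipeline runs.

All randomness in the package flows from a single master seed held in the
configuration; per-gene / per-series generator streams are derived from it so
that enlarging a cohort never perturbs the series already generated.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration value or distribution name is invalid."""


#: Distribution vocabulary for SimConfig fields.  Each spec is a mapping with a
#: ``name`` key plus the parameters of that family.
_DIST_NAMES = {
    "point": ("value",),
    "uniform": ("low", "high"),
    "normal": ("mean", "sd"),
    "lognormal": ("meanlog", "sdlog"),
    "shifted_poisson": ("mean", "min"),
}


def sample_dist(spec: Mapping[str, Any], size: int, rng: np.random.Generator,
                fieldname: str = "distribution") -> np.ndarray:
    """Draw ``size`` samples from a named distribution spec.

    Raises :class:`ConfigError` naming the offending config field when the
    distribution name is unknown or its parameters are missing.
    """
    try:
        name = spec["name"]
    except (TypeError, KeyError):
        raise ConfigError(f"{fieldname}: distribution spec must be a mapping with a 'name' key")
    if name not in _DIST_NAMES:
        raise ConfigError(
            f"{fieldname}: unknown distribution {name!r}; expected one of {sorted(_DIST_NAMES)}")
    missing = [p for p in _DIST_NAMES[name] if p not in spec and not (name == "shifted_poisson" and p == "min")]
    if missing:
        raise ConfigError(f"{fieldname}: distribution {name!r} missing parameters {missing}")
    if name == "point":
        return np.full(size, float(spec["value"]))
    if name == "uniform":
        return rng.uniform(float(spec["low"]), float(spec["high"]), size)
    if name == "normal":
        return rng.normal(float(spec["mean"]), float(spec["sd"]), size)
    if name == "lognormal":
        return rng.lognormal(float(spec["meanlog"]), float(spec["sdlog"]), size)
    if name == "shifted_poisson":
        lo = int(spec.get("min", 1))
        mean = float(spec["mean"])
        if mean < lo:
            raise ConfigError(f"{fieldname}: shifted_poisson mean {mean} below minimum {lo}")
        return lo + rng.poisson(mean - lo, size)
    raise AssertionError("unreachable")


def _default_times() -> tuple:
    # 14 samples every 2 h over a 26-h span; t=0 at local midnight.
    return tuple(float(t) for t in range(0, 27, 2))


@dataclass
class SimConfig:
    """Parameters of the synthetic diel-expression generator.

    Defaults emulate a synchronized 24-h light/dark experiment: 14 timepoints
    on a 2-h grid over 26 h, a high fraction of cycling transcripts with
    damped protein oscillations lagging the mRNA, AR(1) observation noise,
    lognormal peptide-peak scatter with heteroscedastic reported CVs, small
    per-timepoint isotope mixing biases, a low rate of injected outliers, and
    strand-specific coverage with abundant antisense transcription.
    """

    n_genes: int = 300
    times: Sequence[float] = field(default_factory=_default_times)
    ar1_phi: float = 0.3
    innovation_sd: float = 0.25          # log2 units
    fraction_cyclers: float = 0.87
    phase_dist: Mapping[str, Any] = field(
        default_factory=lambda: {"name": "uniform", "low": 0.0, "high": 24.0})
    halfamp_dist: Mapping[str, Any] = field(
        default_factory=lambda: {"name": "uniform", "low": 0.25, "high": 2.5})
    # transcript:protein half-amplitude ratio (>=1 damps the protein)
    amp_ratio_dist: Mapping[str, Any] = field(
        default_factory=lambda: {"name": "lognormal", "meanlog": 1.589, "sdlog": 0.5})
    lag_dist: Mapping[str, Any] = field(
        default_factory=lambda: {"name": "normal", "mean": 5.0, "sd": 3.0})
    baseline_dist: Mapping[str, Any] = field(
        default_factory=lambda: {"name": "normal", "mean": 0.0, "sd": 0.5})
    damping: bool = True

    # peptide peak layer
    peaks_per_timepoint_dist: Mapping[str, Any] = field(
        default_factory=lambda: {"name": "shifted_poisson", "mean": 8.0, "min": 1})
    peak_sigma: float = 0.35             # log2 units, median per-peak scatter
    cv_model: Mapping[str, Any] = field(
        default_factory=lambda: {"sigma_spread": 0.5})
    mixing_bias: Sequence[float] | None = None   # explicit per-timepoint log2 offsets
    mixing_bias_sd: float = 0.05         # drawn offsets when mixing_bias is None
    outlier_peak_rate: float = 0.05
    outlier_peak_scale: float = 5.0      # displacement in units of peak_sigma
    outlier_timepoint_rate: float = 0.011
    outlier_timepoint_shift: float = 3.0  # log2 units
    peak_orientation: str = "heavy_over_light"

    # coverage layer
    antisense_detect_prob: float = 0.73
    antisense_ratio_mean: float = 0.354
    antisense_ratio_sdlog: float = 0.3
    depth: float = 25.0                  # mean per-base sense coverage
    gene_length: int = 900
    gene_gap: int = 100

    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_genes <= 0:
            raise ConfigError("n_genes: must be > 0")
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
            raise ConfigError("times: must be a strictly increasing sequence")
        if not (-1.0 < self.ar1_phi < 1.0):
            raise ConfigError("ar1_phi: must satisfy |phi| < 1")
        for name in ("fraction_cyclers", "outlier_peak_rate", "outlier_timepoint_rate",
                     "antisense_detect_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}: must lie in [0, 1]")
        for name in ("innovation_sd", "peak_sigma", "depth", "antisense_ratio_mean"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.peak_orientation not in ("heavy_over_light", "light_over_heavy"):
            raise ConfigError("peak_orientation: expected heavy_over_light or light_over_heavy")
        if self.mixing_bias is not None and len(self.mixing_bias) != len(times):
            raise ConfigError("mixing_bias: length must match times")
        # surface bad distribution names early
        probe = np.random.default_rng(0)
        for name in ("phase_dist", "halfamp_dist", "amp_ratio_dist", "lag_dist",
                     "baseline_dist", "peaks_per_timepoint_dist"):
            sample_dist(getattr(self, name), 1, probe, fieldname=name)
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["times"] = [float(t) for t in self.times]
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown SimConfig fields: {sorted(bad)}")
        return cls(**d).validate()


@dataclass
class RunConfig:
    """Stage parameters of the full analysis chain.

    Defaults follow the study protocol: 80th-percentile CV filter, IIR peak
    outlier cutoff 1.81, 4.15x nearest-neighbor timepoint rule, >=4 peaks at
    >=8 timepoints for timecourse construction, 1000 AR(1) null simulations
    per series, and the +/-2 h / 2-8 h / 11-13 h phase-relationship bands.
    """

    cv_percentile: float = 80.0
    iir_cutoff: float = 1.81
    nn_factor: float = 4.15
    min_peaks: int = 4
    min_timepoints: int = 8
    n_sims: int = 1000
    q_cutoff: float = 0.05
    in_phase_window: float = 2.0
    lag_band: tuple = (2.0, 8.0)
    antiphase_band: tuple = (11.0, 13.0)
    control_fold: float = 2.0
    log_floor: float | None = None       # pseudo-floor for log2 of zero coverage
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> "RunConfig":
        if not (0.0 < self.cv_percentile <= 100.0):
            raise ConfigError("cv_percentile: must lie in (0, 100]")
        if self.iir_cutoff <= 0 or self.nn_factor <= 0:
            raise ConfigError("iir_cutoff and nn_factor must be > 0")
        if self.min_peaks < 1 or self.min_timepoints < 3:
            raise ConfigError("min_peaks >= 1 and min_timepoints >= 3 required")
        if self.n_sims < 100:
            raise ConfigError("n_sims: must be >= 100")
        if not (0.0 < self.q_cutoff <= 1.0):
            raise ConfigError("q_cutoff: must lie in (0, 1]")
        if self.control_fold < 1.0:
            raise ConfigError("control_fold: must be >= 1")
        self.sim.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["lag_band"] = list(self.lag_band)
        d["antiphase_band"] = list(self.antiphase_band)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], Mapping):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "lag_band" in d:
            d["lag_band"] = tuple(d["lag_band"])
        if "antiphase_band" in d:
            d["antiphase_band"] = tuple(d["antiphase_band"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown RunConfig fields: {sorted(bad)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]
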