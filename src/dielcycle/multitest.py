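"""Multiple-testing control: pi0 estimation, q-values, and the
sensitivity/specificity correction of the cycling proportion.

The q-value machinery follows the classic approach: pi0 is estimated from
the flat right tail of the p-value distribution via pi0_hat(lambda) =
#{p > lambda} / (m * (1 - lambda)) on a lambda grid, smoothed by a cubic
polynomial evaluated at the largest lambda ("polynomial" method); q-values
are the step-up pi0*m*p/rank, optionally with the robust small-m modifier
dividing by 1 - (1-p)^m, and are monotone nondecreasing in p.
"""
from __future__ import annotations

import numpy as np


def estimate_pi0(pvals: np.ndarray, lambda_grid=None, method: str = "polynomial") -> dict:
    """Estimate the proportion of true nulls.

    Returns a dict with pi0 (clamped to (0, 1]), the grid, the raw
    pi0_hat(lambda) sequence and the method tag.
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.9001, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    m = len(p)
    raw = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if method == "polynomial":
        coeffs = np.polyfit(lam, raw, deg=3)
        pi0 = float(np.polyval(coeffs, lam.max()))
    elif method == "fixed":
        pi0 = 1.0
    elif method == "last":
        pi0 = float(raw[-1])
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    pi0 = float(min(max(pi0, 1.0 / m), 1.0))
    return {"pi0": pi0, "lambda_grid": lam, "pi0_raw": raw, "method": method}


def qvalues_from_pvalues(pvals, pi0: float = 1.0, robust: bool = True) -> np.ndarray:
    """Step-up q-values at a given pi0.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j, with the robust modifier
    dividing by (1 - (1 - p_(j))^m); clamped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q = pi0 * m * ps / ranks
    if robust:
        with np.errstate(divide="ignore"):
            denom = -np.expm1(m * np.log1p(-ps))   # 1 - (1-p)^m, stable for small p
        denom = np.where(denom <= 0, np.finfo(float).tiny, denom)
        q = q / denom
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def estimate_qvalues(pvals, lambda_grid=None, pi0_method: str = "polynomial",
                     robust: bool = True, q_cutoff: float = 0.05):
    """Full q-value computation.

    Returns ``(qvals, summary)`` where summary carries the pi0 estimate, the
    grid, the method tag, the cutoff and the significant count at it.
    """
    p = np.asarray(pvals, dtype=float)
    info = estimate_pi0(p, lambda_grid=lambda_grid, method=pi0_method)
    q = qvalues_from_pvalues(p, pi0=info["pi0"], robust=robust)
    summary = {
        "pi0": info["pi0"],
        "pi0_method": info["method"],
        "lambda_grid": [float(x) for x in info["lambda_grid"]],
        "robust": robust,
        "q_cutoff": q_cutoff,
        "n_tests": int(len(p)),
        "n_significant": int((q <= q_cutoff).sum()),
    }
    return q, summary


def estimate_cycling_proportion(n_significant: int, n_total: int,
                                sensitivity: float, specificity: float) -> dict:
    """Correct the observed cycling rate for imperfect test operating
    characteristics.

    With observed positive rate r, sensitivity Se and specificity Sp, the
    corrected cycling proportion is (r + Sp - 1) / (Se + Sp - 1), clamped to
    [0, 1] (the standard misclassification correction).  Requires
    Se + Sp > 1 (an informative test).
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if sensitivity + specificity <= 1.0:
        raise ValueError("sensitivity + specificity must exceed 1 (non-informative test)")
    observed = n_significant / n_total
    corrected = (observed + specificity - 1.0) / (sensitivity + specificity - 1.0)
    corrected = float(np.clip(corrected, 0.0, 1.0))
    return {
        "observed_rate": float(observed),
        "corrected_proportion": corrected,
        "corrected_count": int(round(corrected * n_total)),
        "sensitivity": float(sensitivity),
        "specificity": float(specificity),
    }


def operating_characteristics(halfamps, phis, innovation_sds, times,
                              p_threshold: float, n_sims: int = 1000,
                              seed: int = 0) -> dict:
    """Sensitivity and specificity of the AR(1)-null cycling test.

    For each supplied parameter triple, one synthetic cycler (random phase,
    given half-amplitude, AR(1) noise) and one pure-noise series are pushed
    through the full test (per-series null of ``n_sims`` simulations); the
    fraction of cyclers with p <= p_threshold is the sensitivity and the
    fraction of noise series with p > p_threshold the specificity.
    """
    from .cosinor import Cosinor24, PERIOD_H
    from .simulate import ar1_noise
    halfamps = np.asarray(halfamps, dtype=float)
    phis = np.asarray(phis, dtype=float)
    sds = np.asarray(innovation_sds, dtype=float)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77_003]))
    hits = 0
    false_alarms = 0
    n = len(halfamps)
    for i in range(n):
        phase = rng.uniform(0, PERIOD_H)
        signal = halfamps[i] * np.cos(2 * np.pi * (times - phase) / PERIOD_H)
        for is_cycler, series in ((True, signal + ar1_noise(rng, len(times), phis[i], sds[i])),
                                  (False, ar1_noise(rng, len(times), phis[i], sds[i]))):
            res = Cosinor24(times, series).fit()
            test = res.test_cycling(n_sims=n_sims, rng=rng)
            if test.p_value <= p_threshold:
                if is_cycler:
                    hits += 1
                else:
                    false_alarms += 1
    return {"sensitivity": hits / n, "specificity": 1.0 - false_alarms / n, "n": n}
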