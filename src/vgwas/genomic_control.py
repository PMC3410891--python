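"""Genomic control for 1-df chi-square genome scans.

Population structure inflates association test scores genome-wide.  Genomic
control (GC) estimates a single inflation factor lambda from the bulk of the
observed chi-square scores — most markers are assumed null — and divides the
scores by it before computing p-values.

Two estimators are provided:

* ``lambda_regression`` — regress the sorted observed scores on the
  corresponding null chi-square(1) quantiles through the origin and take
  the slope.  Expected to be conservative relative to (or similar to) the
  median ratio because the regression weights the informative upper tail.
* ``lambda_median`` — ratio of the observed median score to the
  chi-square(1) median (~0.4549), the classic Devlin–Roeder estimator.

Correction divides scores by ``max(lambda, 1)`` by default so that an
apparently deflated genome (lambda < 1) is never amplified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class GCResult:
    lambda_hat: float
    method: str  # "regression" or "median"
    n_scores: int
    clamped: bool = False  # lambda was floored at 1 when correcting

    def __post_init__(self):
        if not self.lambda_hat > 0:
            raise ValueError(f"lambda_hat must be positive, got {self.lambda_hat}")


def null_chi2_quantiles(n: int) -> np.ndarray:
    """Expected order statistics of n null scores: chi-square(1) quantiles at
    plotting positions (i - 0.5)/n, ascending."""
    if n < 2:
        raise ValueError(f"need at least 2 scores, got {n}")
    probs = (np.arange(1, n + 1) - 0.5) / n
    return stats.chi2.ppf(probs, df=1)


def _validate_scores(chi2_obs) -> np.ndarray:
    obs = np.asarray(chi2_obs, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need a 1-d vector of at least 2 scores")
    if np.any(obs < 0) or np.any(~np.isfinite(obs)):
        raise ValueError("chi-square scores must be finite and non-negative")
    return obs


def lambda_regression(chi2_obs) -> GCResult:
    """Zero-intercept regression of sorted observed scores on null quantiles.

    lambda = sum(x_i y_i) / sum(x_i^2) with x the null chi-square(1)
    quantiles and y the ascending observed scores; exactly scale-equivariant.
    """
    obs = _validate_scores(chi2_obs)
    x = null_chi2_quantiles(obs.size)
    y = np.sort(obs)
    lam = float(np.dot(x, y) / np.dot(x, x))
    return GCResult(lambda_hat=lam, method="regression", n_scores=obs.size)


def lambda_median(chi2_obs) -> GCResult:
    """Median-ratio inflation estimate: median(observed) / median(chi2_1)."""
    obs = _validate_scores(chi2_obs)
    lam = float(np.median(obs) / CHI2_1_MEDIAN)
    return GCResult(lambda_hat=lam, method="median", n_scores=obs.size)


def estimate_lambda(chi2_obs, method: str = "regression") -> GCResult:
    if method == "regression":
        return lambda_regression(chi2_obs)
    if method == "median":
        return lambda_median(chi2_obs)
    raise ValueError(f"unknown GC method: {method!r}")


def gc_correct(chi2_obs, gc: GCResult, clamp: bool = True) -> np.ndarray:
    """GC-corrected p-values: upper-tail chi-square(1) of score / lambda_eff.

    With ``clamp`` (default) lambda_eff = max(lambda_hat, 1), so correction
    never makes p-values smaller than nominal.
    """
    obs = np.asarray(chi2_obs, dtype=float)
    lam_eff = max(gc.lambda_hat, 1.0) if clamp else gc.lambda_hat
    return stats.chi2.sf(obs / lam_eff, df=1)


def corrected_scores(chi2_obs, gc: GCResult, clamp: bool = True) -> np.ndarray:
    obs = np.asarray(chi2_obs, dtype=float)
    lam_eff = max(gc.lambda_hat, 1.0) if clamp else gc.lambda_hat
    return obs / lam_eff
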