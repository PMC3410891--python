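"""Per-marker association tests for inbred biallelic data.

Two complementary tests are run per marker:

* **Brown–Forsythe** (Levene's test with median centering) detects a
  difference in phenotypic *variance* between the two homozygous genotype
  classes.  With phenotype ``y_ij`` (individual i, genotype j) and group
  medians ``m_j``, the absolute deviations ``z_ij = |y_ij - m_j|`` are
  subjected to a one-way ANOVA:

      F = [ sum_j n_j (zbar_j - zbar)^2 / (K-1) ]
          / [ sum_ij (z_ij - zbar_j)^2 / (N-K) ]

  F follows an F(K-1, N-K) distribution under the null; for the sample
  sizes of a genome scan, (K-1)·F is well approximated by a chi-square with
  K-1 degrees of freedom, which is the score genomic control operates on.

* **Wilcoxon rank-sum** (Mann–Whitney) detects a difference in *location*
  and serves as the mean-effect scan that the variance scan is contrasted
  against.  The normal approximation with tie correction and continuity
  correction is the default; exact enumeration is available for small N.

Both results carry a 1-df chi-square score (``(K-1)·F`` and ``Z²``) so that
genome-wide inflation can be estimated and corrected on a common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GenotypeGroups

#: Smallest representable positive double, used for degenerate
#: zero-within-variance markers (infinite F).
TINY_P = float(np.nextafter(0.0, 1.0))


class MarkerSkipped(ValueError):
    """Marker does not satisfy a test's preconditions (monomorphic or
    undersized group); scan code converts this into a reason code."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class BFResult:
    """Brown–Forsythe test outcome at one marker."""

    F: float
    df1: int
    df2: int
    p_F: float
    chi2: float
    p_chi2: float
    z_bar_by_group: tuple  # mean |median deviation| per genotype (low, high)
    degenerate: bool = False


@dataclass(frozen=True)
class WilcoxonResult:
    """Wilcoxon rank-sum / Mann–Whitney test outcome at one marker."""

    rank_sum: float  # sum of ranks of the low-coded (call 0) group
    U: float  # Mann–Whitney statistic of the low-coded group
    Z: float  # normal deviate (tie-corrected, continuity-corrected)
    p: float  # two-sided
    chi2: float  # Z^2, the 1-df GC score
    exact: bool = False


def _check_two_groups(groups: GenotypeGroups, min_group_size: int):
    if groups.K < 2:
        raise MarkerSkipped(
            "monomorphic", f"need two genotype classes, got K={groups.K}"
        )
    if min(groups.n_low, groups.n_high) < min_group_size:
        raise MarkerSkipped(
            "low_count",
            f"smallest genotype class has {min(groups.n_low, groups.n_high)} "
            f"observations (< {min_group_size})",
        )


def abs_median_deviation(y: np.ndarray, groups: GenotypeGroups) -> np.ndarray:
    """Absolute deviations from each genotype's median.

    ``z_ij = |y_ij - median_j|``; the median of an even-sized group is the
    midpoint of its two central order statistics.  Positions with a MISSING
    call get NaN.
    """
    y = np.asarray(y, dtype=float)
    z = np.full_like(y, np.nan)
    for mask in groups.masks():
        if mask.any():
            z[mask] = np.abs(y[mask] - np.median(y[mask]))
    return z


def brown_forsythe(
    y: np.ndarray, groups: GenotypeGroups, min_group_size: int = 2
) -> BFResult:
    """Brown–Forsythe variance-heterogeneity test at one marker.

    Parameters
    ----------
    y : array
        Phenotype values, aligned with ``groups.group_index``.
    groups : GenotypeGroups
        Two-class genotype grouping (K must be 2).
    min_group_size : int
        Smallest admissible genotype class; a single-observation class
        contributes no within-group dispersion information.

    Raises
    ------
    MarkerSkipped
        When the marker is monomorphic or a class is undersized.
    """
    _check_two_groups(groups, max(min_group_size, 1))
    low_mask, high_mask = groups.masks()
    y = np.asarray(y, dtype=float)
    K, N = 2, groups.N
    if N < K + 1:
        raise MarkerSkipped("low_count", f"need N >= {K + 1}, got {N}")

    z_groups = [np.abs(y[m] - np.median(y[m])) for m in (low_mask, high_mask)]
    n = np.array([len(z) for z in z_groups], dtype=float)
    zbar_j = np.array([z.mean() for z in z_groups])
    zbar = float(np.concatenate(z_groups).mean())
    ss_between = float(np.sum(n * (zbar_j - zbar) ** 2))
    ss_within = float(sum(((z - zb) ** 2).sum() for z, zb in zip(z_groups, zbar_j)))
    df1, df2 = K - 1, N - K

    if ss_within == 0.0:
        if ss_between == 0.0:
            return BFResult(0.0, df1, df2, 1.0, 0.0, 1.0, tuple(zbar_j), False)
        return BFResult(
            math.inf, df1, df2, TINY_P, math.inf, TINY_P, tuple(zbar_j), True
        )

    F = (ss_between / df1) / (ss_within / df2)
    chi2 = df1 * F
    p_F = float(stats.f.sf(F, df1, df2))
    p_chi2 = float(stats.chi2.sf(chi2, df1))
    return BFResult(
        F=float(F),
        df1=df1,
        df2=df2,
        p_F=max(p_F, TINY_P),
        chi2=float(chi2),
        p_chi2=max(p_chi2, TINY_P),
        z_bar_by_group=tuple(zbar_j),
    )


def wilcoxon_rank_sum(
    y: np.ndarray,
    groups: GenotypeGroups,
    min_group_size: int = 2,
    exact: bool = False,
    continuity: bool = True,
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test at one marker.

    The default is the normal approximation with average ranks for ties,
    a tie-corrected variance and a 0.5 continuity correction.  With
    ``exact=True`` (permitted for N <= 20, no ties required by scipy's
    enumeration) the exact two-sided p-value is reported instead; the
    chi-square score is always the squared normal deviate so that genomic
    control sees a consistent scale.
    """
    _check_two_groups(groups, max(min_group_size, 1))
    low_mask, high_mask = groups.masks()
    y = np.asarray(y, dtype=float)
    x1, x2 = y[low_mask], y[high_mask]
    n1, n2 = len(x1), len(x2)
    N = n1 + n2

    ranks = stats.rankdata(np.concatenate([x1, x2]))
    rank_sum = float(ranks[:n1].sum())
    U = rank_sum - n1 * (n1 + 1) / 2.0

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x1, x2]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:  # all observations tied
        Z = 0.0
    else:
        diff = U - mu
        if continuity and diff != 0:
            diff -= 0.5 * np.sign(diff)
        Z = float(diff / math.sqrt(var))
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(Z))))

    used_exact = False
    if exact:
        if N > 20:
            raise ValueError(f"exact enumeration limited to N <= 20, got N={N}")
        p = float(
            stats.mannwhitneyu(x1, x2, alternative="two-sided", method="exact").pvalue
        )
        used_exact = True

    return WilcoxonResult(
        rank_sum=rank_sum,
        U=float(U),
        Z=Z,
        p=max(p, TINY_P),
        chi2=Z * Z,
        exact=used_exact,
    )
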