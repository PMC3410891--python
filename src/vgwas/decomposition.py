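"""Single-locus decomposition of phenotypic variance for inbred populations.

In a population of fully homozygous lines a biallelic locus has two
genotype classes.  Let ``p`` be the frequency of the low-variance allele
(LAF) and ``q = 1 - p`` that of the high-variance allele (HAF); each
genotype class has its own phenotype mean and standard deviation, with
``d_mu = mean_high - mean_low`` and ``d_sigma = sd_high - sd_low >= 0`` by
the labeling convention.  The phenotypic variance then splits into three
parts::

    sigma2_P = sigma2_m + sigma2_d + sigma2_eps

    sigma2_m   = p * q * d_mu^2          variance from the mean shift
                                         (the additive variance: no
                                         dominance in inbreds)
    sigma2_d   = p * q * d_sigma^2       variance from the heterogeneity of
                                         the per-genotype SD (its variance
                                         across the population)
    sigma2_eps = (p*sd_low + q*sd_high)^2  residual: the squared mean
                                           per-genotype SD

so that ``sigma2_P`` equals the equivalent mixture form
``p*q*d_mu^2 + p*sd_low^2 + q*sd_high^2`` exactly.  The proportions
``h2_m = sigma2_m / sigma2_P`` and ``h2_d = sigma2_d / sigma2_P`` are the
fractions of phenotypic variance attributable to the mean-controlling and
variance-controlling effect of the locus.  Both are maximized, at fixed
per-genotype moments, when the low-variance allele frequency equals
``sd_high / (sd_high + sd_low)`` — which is why the strongest
variance-controlling loci tend to have a LAF above one half.

Estimation is plug-in: population moments are replaced by sample means,
sample SDs (n-1 denominator) and sample genotype frequencies, with no
small-sample bias correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeGroups


@dataclass(frozen=True)
class GroupMoments:
    n: int
    mean: float
    sd: float
    median: float


@dataclass(frozen=True)
class LocusMoments:
    """Per-genotype sample moments with low/high-variance labeling.

    ``low``/``high`` refer to the genotype with the smaller/larger sample
    SD; on an exact tie the allele_a homozygote (call 0) is labeled low.
    ``p_low`` is the sample frequency of the low-variance genotype, which
    in inbreds equals the low-variance allele frequency (LAF).
    """

    low: GroupMoments
    high: GroupMoments
    p_low: float
    swapped: bool  # True when the call-2 genotype is the low-variance one


@dataclass(frozen=True)
class VarDecomp:
    """Results of the single-locus variance dissection.

    All fields follow the labeling convention d_sigma >= 0.  ``h2_m`` is the
    fraction of phenotypic variance from the mean shift (the locus's
    additive variance fraction), ``h2_d`` the fraction from variance
    heterogeneity.
    """

    p_low: float
    q_high: float
    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    d_mu: float
    d_sigma: float
    s2_m: float
    s2_d: float
    s2_eps: float
    s2_P: float
    h2_m: float
    h2_d: float

    def summary(self) -> str:
        lines = [
            "Single-locus variance decomposition",
            "-" * 41,
            f"LAF (low-variance allele freq)  {self.p_low:10.4f}",
            f"HAF                             {self.q_high:10.4f}",
            f"mean  low / high     {self.mean_low:10.4f} {self.mean_high:10.4f}",
            f"sd    low / high     {self.sd_low:10.4f} {self.sd_high:10.4f}",
            f"d_mu                            {self.d_mu:10.4f}",
            f"d_sigma                         {self.d_sigma:10.4f}",
            f"s2_m   (mean shift)             {self.s2_m:10.5f}",
            f"s2_d   (variance heterogeneity) {self.s2_d:10.5f}",
            f"s2_eps (residual)               {self.s2_eps:10.5f}",
            f"s2_P   (total)                  {self.s2_P:10.5f}",
            f"h2_m                            {self.h2_m:10.4f}",
            f"h2_d                            {self.h2_d:10.4f}",
        ]
        return "\n".join(lines)


def genotype_moments(y: np.ndarray, groups: GenotypeGroups) -> LocusMoments:
    """Per-genotype sample moments, labeled low/high by sample SD."""
    if groups.K != 2:
        raise ValueError(f"need two genotype classes, got K={groups.K}")
    if min(groups.n_low, groups.n_high) < 2:
        raise ValueError("each genotype class needs >= 2 observations for a sample SD")
    y = np.asarray(y, dtype=float)
    mom = []
    for mask in groups.masks():
        v = y[mask]
        mom.append(
            GroupMoments(
                n=int(v.size),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)),
                median=float(np.median(v)),
            )
        )
    a, b = mom  # a: call-0 (allele_a homozygote), b: call-2
    swapped = b.sd < a.sd  # ties keep allele_a as the low-variance class
    low, high = (b, a) if swapped else (a, b)
    return LocusMoments(
        low=low, high=high, p_low=low.n / (low.n + high.n), swapped=swapped
    )


def decompose(
    p_low: float,
    mean_low: float,
    mean_high: float,
    sd_low: float,
    sd_high: float,
) -> VarDecomp:
    """Closed-form variance dissection from per-genotype moments.

    Inputs may arrive with the labels reversed (sd_low > sd_high); they are
    canonicalized by swapping the two genotypes and replacing p with 1-p, so
    the result is invariant to a label exchange.
    """
    if not 0.0 < p_low < 1.0:
        raise ValueError(f"p_low must lie in (0, 1), got {p_low}")
    if sd_low < 0 or sd_high < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_low > sd_high:
        p_low, mean_low, mean_high, sd_low, sd_high = (
            1.0 - p_low,
            mean_high,
            mean_low,
            sd_high,
            sd_low,
        )
    p, q = p_low, 1.0 - p_low
    d_mu = mean_high - mean_low
    d_sigma = sd_high - sd_low
    s2_m = p * q * d_mu**2
    s2_d = p * q * d_sigma**2
    s2_eps = (p * sd_low + q * sd_high) ** 2
    s2_P = s2_m + s2_d + s2_eps
    if s2_P == 0.0:
        h2_m = h2_d = 0.0
    else:
        h2_m = s2_m / s2_P
        h2_d = s2_d / s2_P
    return VarDecomp(
        p_low=p,
        q_high=q,
        mean_low=mean_low,
        mean_high=mean_high,
        sd_low=sd_low,
        sd_high=sd_high,
        d_mu=d_mu,
        d_sigma=d_sigma,
        s2_m=s2_m,
        s2_d=s2_d,
        s2_eps=s2_eps,
        s2_P=s2_P,
        h2_m=h2_m,
        h2_d=h2_d,
    )


def decompose_locus(y: np.ndarray, groups: GenotypeGroups) -> VarDecomp:
    """Plug-in decomposition from raw phenotypes at one marker."""
    m = genotype_moments(y, groups)
    return decompose(m.p_low, m.low.mean, m.high.mean, m.low.sd, m.high.sd)


def optimal_laf(sd_high: float, sd_low: float) -> float:
    """Low-variance allele frequency maximizing h2_m and h2_d.

    At fixed per-genotype moments both variance fractions peak at
    ``sd_high / (sd_high + sd_low)``; with no heterogeneity (equal SDs) the
    maximum is at 0.5.  The location does not depend on d_mu.
    """
    if sd_high < 0 or sd_low < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_high + sd_low == 0:
        raise ValueError("at least one SD must be positive")
    return sd_high / (sd_high + sd_low)


def h2_curves(
    mean_low: float,
    mean_high: float,
    sd_low: float,
    sd_high: float,
    grid: np.ndarray,
) -> pd.DataFrame:
    """h2_m and h2_d as functions of the LAF, for fixed genotype moments.

    Returns a DataFrame with columns ``laf``, ``h2_m``, ``h2_d`` — the data
    behind the LAF-sweep partitioning curves.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("grid frequencies must lie strictly inside (0, 1)")
    rows = [
        decompose(p, mean_low, mean_high, sd_low, sd_high) for p in grid
    ]
    return pd.DataFrame(
        {
            "laf": grid,
            "h2_m": [r.h2_m for r in rows],
            "h2_d": [r.h2_d for r in rows],
        }
    )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = sd / mean (mean must be nonzero)."""
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return sd / mean


def median_deviation_correlation(
    traits: pd.DataFrame, mode: str = "signed", min_pairs: int = 3
) -> pd.DataFrame:
    """Spearman correlation matrix of per-trait deviations from the median.

    Each trait column is centered on its own median ("signed" mode) or
    replaced by the absolute deviation ("absolute" mode); rank correlations
    are then computed on pairwise complete cases.  Cells with fewer than
    ``min_pairs`` complete pairs are NaN.  Used to ask whether accessions
    that deviate most on one trait also deviate most on another — the
    signature of variance heterogeneity propagating through a pathway.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    dev = traits - traits.median(axis=0, skipna=True)
    if mode == "absolute":
        dev = dev.abs()
    return dev.corr(method="spearman", min_periods=min_pairs)
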