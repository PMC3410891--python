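"""Synthetic inbred genotype/phenotype data and power / error studies.

The generator emulates an inbred-line association panel: ~200 fully
homozygous accessions typed at independent biallelic markers, with one
designated causal marker whose genotype sets both the phenotype mean and
the phenotype standard deviation (the "standard deviation model"):

    y_i = mu_g(i) + delta_s(i) + sigma_g(i) * eps_i,   eps ~ N(0, 1)

where g(i) is the line's genotype at the causal marker (low-variance
homozygote with probability ``laf``) and s(i) its subpopulation.  With
``n_subpops > 1``, marker allele frequencies differentiate across
subpopulations via Balding–Nichols beta draws with parameter ``fst``, and
subpopulations receive additive phenotype mean offsets of scale
``subpop_shift`` — the classic recipe for structure-induced test-score
inflation.  A heavy-tailed noise option (unit-variance Student t) is
available to probe the Brown–Forsythe test's robustness to non-normality.

The study drivers estimate empirical rejection rates of the
Brown–Forsythe test over a parameter grid (false-positive rate on null
cells, power on variance-heterogeneous cells) and the behaviour of the
genomic-control inflation factor on structured null genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix, PhenotypeTable
from .genomic_control import estimate_lambda, corrected_scores


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults reproduce the panel the method targets: 200 inbred lines,
    intermediate allele frequency, and a null causal marker (equal means
    and SDs) — effect sizes are set per study.
    """

    n_lines: int = 200
    n_markers: int = 1000
    laf: float = 0.5  # frequency of the low-variance allele (call 0)
    mean_low: float = 0.0
    mean_high: float = 0.0
    sd_low: float = 1.0
    sd_high: float = 1.0
    n_subpops: int = 1
    fst: float = 0.0
    subpop_shift: float = 0.0
    seed: int = 0
    noise: str = "normal"  # or "t" (unit-variance Student t, df=3)
    t_df: int = 3

    def __post_init__(self):
        if not 0.0 < self.laf < 1.0:
            raise ValueError(f"laf must lie in (0, 1), got {self.laf}")
        if self.sd_low < 0 or self.sd_high < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.noise not in ("normal", "t"):
            raise ValueError(f"noise must be 'normal' or 't', got {self.noise!r}")
        if self.noise == "t" and self.t_df <= 2:
            raise ValueError("t noise needs df > 2 for a finite variance")


def _noise(rng: np.random.Generator, size, cfg: SimConfig) -> np.ndarray:
    if cfg.noise == "normal":
        return rng.standard_normal(size)
    scale = math.sqrt(cfg.t_df / (cfg.t_df - 2))
    return rng.standard_t(cfg.t_df, size) / scale


def _balding_nichols(rng, p_anc: float, fst: float, n_subpops: int) -> np.ndarray:
    """Subpopulation allele frequencies around an ancestral frequency."""
    if fst == 0.0:
        return np.full(n_subpops, p_anc)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return np.clip(rng.beta(a, b, size=n_subpops), 1e-6, 1 - 1e-6)


def simulate_dataset(cfg: SimConfig):
    """Simulate one dataset; returns (GenotypeMatrix, PhenotypeTable, truth).

    Marker 0 is the causal marker; all other markers are null given the
    subpopulation structure.  Calls count copies of allele "B", so call 0
    is the allele-A homozygote = the low-variance genotype.  The truth
    record carries the causal marker id and the generating parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_lines, cfg.n_markers
    subpop = np.repeat(np.arange(cfg.n_subpops), math.ceil(n / cfg.n_subpops))[:n]

    calls = np.empty((m, n), dtype=np.int8)
    for j in range(m):
        p_anc = cfg.laf if j == 0 else rng.uniform(0.05, 0.95)
        p_sub = _balding_nichols(rng, p_anc, cfg.fst, cfg.n_subpops)
        low = rng.random(n) < p_sub[subpop]
        calls[j] = np.where(low, 0, 2).astype(np.int8)

    causal = calls[0]
    mu = np.where(causal == 0, cfg.mean_low, cfg.mean_high)
    sigma = np.where(causal == 0, cfg.sd_low, cfg.sd_high)
    shifts = cfg.subpop_shift * (np.arange(cfg.n_subpops) - (cfg.n_subpops - 1) / 2)
    y = mu + shifts[subpop] + sigma * _noise(rng, n, cfg)

    acc = np.array([f"line{i + 1:04d}" for i in range(n)], dtype=object)
    marker_ids = np.array(
        ["causal"] + [f"null{j:05d}" for j in range(1, m)], dtype=object
    )
    G = GenotypeMatrix(
        marker_ids=marker_ids,
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1) * 1000,
        allele_a=np.array(["A"] * m, dtype=object),
        allele_b=np.array(["B"] * m, dtype=object),
        calls=calls,
        accession_ids=acc,
    )
    P = PhenotypeTable(pd.DataFrame({"trait": y}, index=pd.Index(acc, name="accession_id")))
    truth = {
        "causal_marker": "causal",
        "subpop": subpop.tolist(),
        **asdict(cfg),
    }
    return G, P, truth


# ---------------------------------------------------------------------------
# fast Brown-Forsythe helpers for Monte-Carlo studies


def _bf_chi2_batch(y_low: np.ndarray, y_high: np.ndarray) -> np.ndarray:
    """(K-1)*F of the Brown-Forsythe test, rows = replicates.

    ``y_low``/``y_high`` are (reps, n_low) and (reps, n_high) phenotype
    blocks; group assignment within a replicate is exchangeable, so fixing
    the block layout is distributionally equivalent to random assignment.
    """
    z1 = np.abs(y_low - np.median(y_low, axis=1, keepdims=True))
    z2 = np.abs(y_high - np.median(y_high, axis=1, keepdims=True))
    n1, n2 = z1.shape[1], z2.shape[1]
    N = n1 + n2
    zb1 = z1.mean(axis=1)
    zb2 = z2.mean(axis=1)
    zbar = (n1 * zb1 + n2 * zb2) / N
    ss_between = n1 * (zb1 - zbar) ** 2 + n2 * (zb2 - zbar) ** 2
    ss_within = ((z1 - zb1[:, None]) ** 2).sum(axis=1) + (
        (z2 - zb2[:, None]) ** 2
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_between / (ss_within / (N - 2))
    F = np.where(ss_within == 0, np.where(ss_between == 0, 0.0, np.inf), F)
    return F  # df1 = 1, so chi2 == F


def bf_rejection_rate(
    n: int,
    laf: float,
    alpha: float,
    n_reps: int,
    rng: np.random.Generator,
    mean_low: float = 0.0,
    mean_high: float = 0.0,
    sd_low: float = 1.0,
    sd_high: float = 1.0,
    min_group_size: int = 2,
    noise: str = "normal",
    t_df: int = 3,
) -> float:
    """Empirical Brown-Forsythe rejection rate at level ``alpha``.

    Group sizes are drawn binomially from ``laf`` and conditioned on both
    genotype classes having at least ``min_group_size`` members (markers
    failing that are filtered before testing in a real scan).  Replicates
    are batched by group size so the test vectorizes.
    """
    n_low = rng.binomial(n, laf, size=n_reps)
    bad = (n_low < min_group_size) | (n - n_low < min_group_size)
    while bad.any():
        n_low[bad] = rng.binomial(n, laf, size=int(bad.sum()))
        bad = (n_low < min_group_size) | (n - n_low < min_group_size)

    cfg = SimConfig(sd_low=sd_low, sd_high=sd_high, noise=noise, t_df=t_df)
    crit = stats.chi2.isf(alpha, df=1)
    rejected = 0
    for k in np.unique(n_low):
        reps = int(np.sum(n_low == k))
        y_low = mean_low + sd_low * _noise(rng, (reps, int(k)), cfg)
        y_high = mean_high + sd_high * _noise(rng, (reps, int(n - k)), cfg)
        chi2 = _bf_chi2_batch(y_low, y_high)
        rejected += int(np.sum(chi2 > crit))
    return rejected / n_reps


def _study_row(n, laf, sd_ratio, d_mu, alpha, rate, n_reps) -> dict:
    return {
        "n": n,
        "laf": laf,
        "sd_ratio": sd_ratio,
        "d_mu": d_mu,
        "alpha": alpha,
        "rejection_rate": rate,
        "mc_se": math.sqrt(rate * (1 - rate) / n_reps),
        "n_reps": n_reps,
    }


def fpr_study(
    ns=(100, 200, 500),
    lafs=(0.1, 0.3, 0.5),
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int = 0,
    noise: str = "normal",
) -> pd.DataFrame:
    """False-positive rate of the variance test on fully null cells."""
    rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        for laf in lafs:
            rate = bf_rejection_rate(n, laf, alpha, n_reps, rng, noise=noise)
            rows.append(_study_row(n, laf, 1.0, 0.0, alpha, rate, n_reps))
    return pd.DataFrame(rows)


def power_study(
    ns=(100, 200, 500),
    lafs=(0.3, 0.5, 0.7),
    sd_ratios=(1.0, 1.5, 2.0, 3.0),
    d_mu: float = 0.0,
    alpha: float = 0.05,
    n_reps: int = 2_000,
    seed: int = 0,
    noise: str = "normal",
) -> pd.DataFrame:
    """Power of the variance test across sample size, LAF and SD ratio.

    The low-variance genotype has SD 1 and the high-variance genotype SD
    equal to ``sd_ratio``; ``d_mu`` adds a mean shift on top.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        for laf in lafs:
            for r in sd_ratios:
                rate = bf_rejection_rate(
                    n,
                    laf,
                    alpha,
                    n_reps,
                    rng,
                    mean_high=d_mu,
                    sd_low=1.0,
                    sd_high=r,
                    noise=noise,
                )
                rows.append(_study_row(n, laf, r, d_mu, alpha, rate, n_reps))
    return pd.DataFrame(rows)


def gc_structure_study(
    cfg: SimConfig,
    n_reps: int = 100,
    gc_method: str = "regression",
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Inflation of the variance scan on structured null genomes.

    Each replicate simulates a genome under ``cfg`` (all markers null with
    respect to genotype effects; subpopulation shifts only), computes the
    Brown-Forsythe chi-square score at every polymorphic marker, estimates
    lambda, divides the scores by it (no clamping — the point is to see the
    corrected scores recalibrate) and re-estimates lambda on the corrected
    scores.  Returns one row per replicate: lambda_pre, lambda_post,
    n_markers_used.
    """
    rows = []
    for rep in range(n_reps):
        rep_cfg = SimConfig(**{**asdict(cfg), "seed": cfg.seed + rep})
        G, P, _ = simulate_dataset(rep_cfg)
        y = P.frame["trait"].to_numpy(float)
        scores = []
        for j in range(G.n_markers):
            calls = G.calls[j]
            low = calls == 0
            n1 = int(low.sum())
            if n1 < min_group_size or (calls.size - n1) < min_group_size:
                continue
            chi2 = _bf_chi2_batch(y[low][None, :], y[~low][None, :])[0]
            if np.isfinite(chi2):
                scores.append(float(chi2))
        scores = np.asarray(scores)
        gc_pre = estimate_lambda(scores, gc_method)
        adj = corrected_scores(scores, gc_pre, clamp=False)
        gc_post = estimate_lambda(adj, gc_method)
        rows.append(
            {
                "rep": rep,
                "lambda_pre": gc_pre.lambda_hat,
                "lambda_post": gc_post.lambda_hat,
                "n_markers_used": scores.size,
            }
        )
    return pd.DataFrame(rows)
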