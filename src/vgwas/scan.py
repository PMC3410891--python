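"""Genome scan model: per-trait variance-heterogeneity and mean GWAS.

``VarianceScan`` is built from a genotype matrix, a phenotype table and a
trait name; ``fit()`` runs the full per-trait pipeline and returns a
``ScanResults``:

1. complete-case alignment of accessions;
2. MAF filter (markers with minor allele frequency below ``maf_min`` are
   excluded, with a reason code) and group-size filter;
3. Brown–Forsythe (variance) and Wilcoxon (mean) tests per surviving
   marker;
4. genomic-control lambda estimated per test family over the surviving
   markers; corrected p-values;
5. a Bonferroni significance threshold (alpha over the number of markers
   actually tested, by default);
6. the single-locus variance decomposition at every tested marker;
7. a triage flag when the Brown–Forsythe inflation factor exceeds
   ``lambda_max`` — such traits are reported but regarded as too confounded
   by population structure for a primary report.

No adjustment is made across traits; each trait is scanned independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import assoc
from .assoc import MarkerSkipped
from .data import (
    DataError,
    GenotypeMatrix,
    PhenotypeTable,
    align_complete_cases,
    groups_from_calls,
    maf as _maf,
)
from .decomposition import decompose_locus
from .genomic_control import estimate_lambda, gc_correct

REASON_TESTED = "tested"
REASON_MONOMORPHIC = "monomorphic"
REASON_LOW_MAF = "low_maf"
REASON_LOW_COUNT = "low_count"


@dataclass
class ScanConfig:
    """Tuning knobs of a per-trait scan.

    maf_min
        Minimum minor-allele frequency; markers below it are not tested
        (default 0.10).
    alpha
        Genome-wide significance level before Bonferroni division
        (default 0.05).
    gc_method
        "regression" (zero-intercept fit of sorted scores on null
        quantiles) or "median" (median ratio).
    gc_clamp
        Floor lambda at 1 when correcting, so deflation is never amplified.
    lambda_max
        Triage threshold: a Brown–Forsythe lambda strictly above this flags
        the trait as structure-confounded (default 1.5).
    min_group_size
        Smallest genotype class admissible for testing (default 2).
    bonferroni_m
        Optional fixed Bonferroni denominator; default None divides alpha
        by the number of markers tested for this trait.
    """

    maf_min: float = 0.10
    alpha: float = 0.05
    gc_method: str = "regression"
    gc_clamp: bool = True
    lambda_max: float = 1.5
    min_group_size: int = 2
    bonferroni_m: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError(f"maf_min must lie in [0, 0.5), got {self.maf_min}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.gc_method not in ("regression", "median"):
            raise ValueError(f"unknown gc_method: {self.gc_method!r}")


def bonferroni_threshold(m_tests: int, alpha: float) -> float:
    """Per-marker p-value threshold alpha / m_tests."""
    if m_tests < 1:
        raise ValueError(f"need at least one test, got m_tests={m_tests}")
    return alpha / m_tests


SCAN_COLUMNS = [
    "marker_id",
    "chrom",
    "pos",
    "maf",
    "N",
    "n_low",
    "n_high",
    "reason_code",
    "bf_F",
    "bf_chi2",
    "bf_p",
    "bf_p_gc",
    "wx_Z",
    "wx_p",
    "wx_p_gc",
    "laf",
    "d_mu",
    "d_sigma",
    "h2_m",
    "h2_d",
]


class VarianceScan:
    """Per-trait genome scan for mean- and variance-controlling loci."""

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotypes: PhenotypeTable,
        trait: str,
        config: ScanConfig | None = None,
    ):
        self.genotypes = genotypes
        self.phenotypes = phenotypes
        self.trait = trait
        self.config = config or ScanConfig()
        phenotypes.trait(trait)  # fail fast on an unknown trait

    def fit(self) -> "ScanResults":
        cfg = self.config
        G = self.genotypes
        accessions = align_complete_cases(G, self.phenotypes, self.trait)
        cols = G.accession_indexer(accessions)
        y_all = self.phenotypes.trait(self.trait).loc[accessions].to_numpy(float)

        records = []
        for i in range(G.n_markers):
            calls = G.calls[i, cols]
            groups = groups_from_calls(calls)
            rec = {
                "marker_id": G.marker_ids[i],
                "chrom": G.chrom[i],
                "pos": int(G.pos[i]),
                "N": groups.N,
                "n_low": groups.n_low,
                "n_high": groups.n_high,
            }
            if groups.N == 0 or groups.K < 2:
                rec["maf"] = 0.0 if groups.N else math.nan
                rec["reason_code"] = REASON_MONOMORPHIC
                records.append(rec)
                continue
            f = _maf(groups)
            rec["maf"] = f
            if f < cfg.maf_min:
                rec["reason_code"] = REASON_LOW_MAF
                records.append(rec)
                continue
            mask = groups.group_index != -1
            y, g = y_all[mask], groups_from_calls(calls[mask])
            try:
                bf = assoc.brown_forsythe(y, g, cfg.min_group_size)
                wx = assoc.wilcoxon_rank_sum(y, g, cfg.min_group_size)
            except MarkerSkipped as exc:
                rec["reason_code"] = exc.reason
                records.append(rec)
                continue
            rec["reason_code"] = REASON_TESTED
            rec["bf_F"] = bf.F
            rec["bf_chi2"] = bf.chi2
            rec["bf_p"] = bf.p_chi2  # chi-square approximation, as used by GC
            rec["wx_Z"] = wx.Z
            rec["wx_chi2"] = wx.chi2
            rec["wx_p"] = wx.p
            dec = decompose_locus(y, g)
            rec["laf"] = dec.p_low
            rec["d_mu"] = dec.d_mu
            rec["d_sigma"] = dec.d_sigma
            rec["h2_m"] = dec.h2_m
            rec["h2_d"] = dec.h2_d
            records.append(rec)

        table = pd.DataFrame.from_records(records)
        tested = table["reason_code"] == REASON_TESTED
        n_tested = int(tested.sum())
        if n_tested == 0:
            counts = table["reason_code"].value_counts().to_dict()
            raise DataError(
                f"no marker passed the filters for trait {self.trait!r}; "
                f"reason counts: {counts}"
            )

        # Degenerate (infinite) scores would dominate the regression; they are
        # corrected but excluded from lambda estimation.
        bf_scores = table.loc[tested, "bf_chi2"].to_numpy(float)
        wx_scores = table.loc[tested, "wx_chi2"].to_numpy(float)
        finite_bf = bf_scores[np.isfinite(bf_scores)]
        gc_bf = estimate_lambda(finite_bf, cfg.gc_method)
        gc_wx = estimate_lambda(wx_scores, cfg.gc_method)
        table.loc[tested, "bf_p_gc"] = gc_correct(bf_scores, gc_bf, cfg.gc_clamp)
        table.loc[tested, "wx_p_gc"] = gc_correct(wx_scores, gc_wx, cfg.gc_clamp)

        m = cfg.bonferroni_m if cfg.bonferroni_m is not None else n_tested
        threshold = bonferroni_threshold(m, cfg.alpha)
        table = table.drop(columns=["wx_chi2"]).reindex(columns=SCAN_COLUMNS)
        return ScanResults(
            model=self,
            table=table,
            lambda_bf=gc_bf.lambda_hat,
            lambda_wx=gc_wx.lambda_hat,
            bonferroni=threshold,
            n_tested=n_tested,
            inflated=gc_bf.lambda_hat > cfg.lambda_max,
        )


@dataclass
class ScanResults:
    """Fitted per-trait scan: the joined marker table plus trait-level
    inflation factors, threshold and triage flag."""

    model: VarianceScan
    table: pd.DataFrame
    lambda_bf: float
    lambda_wx: float
    bonferroni: float
    n_tested: int
    inflated: bool

    @property
    def trait(self) -> str:
        return self.model.trait

    @property
    def config(self) -> ScanConfig:
        return self.model.config

    def significant(self, which: str = "bf") -> pd.DataFrame:
        """Markers whose GC-corrected p-value beats the Bonferroni threshold."""
        col = {"bf": "bf_p_gc", "wx": "wx_p_gc"}[which]
        t = self.table
        return t[(t["reason_code"] == REASON_TESTED) & (t[col] < self.bonferroni)]

    def summary(self) -> str:
        t = self.table
        counts = t["reason_code"].value_counts().to_dict()
        lines = [
            f"vGWAS scan results: trait {self.trait!r}",
            "=" * 46,
            f"markers total            {len(t):>8d}",
            f"markers tested           {self.n_tested:>8d}",
            f"filtered (low MAF)       {counts.get(REASON_LOW_MAF, 0):>8d}",
            f"filtered (monomorphic)   {counts.get(REASON_MONOMORPHIC, 0):>8d}",
            f"filtered (low count)     {counts.get(REASON_LOW_COUNT, 0):>8d}",
            f"lambda (Brown-Forsythe)  {self.lambda_bf:>8.3f}",
            f"lambda (Wilcoxon)        {self.lambda_wx:>8.3f}",
            f"Bonferroni threshold     {self.bonferroni:>12.3e}",
            f"significant vGWAS (BF)   {len(self.significant('bf')):>8d}",
            f"significant GWAS (WX)    {len(self.significant('wx')):>8d}",
            f"inflation triage (>{self.config.lambda_max})   "
            f"{'FLAGGED' if self.inflated else 'ok':>8s}",
        ]
        return "\n".join(lines)

    # -- exports ------------------------------------------------------------

    def manhattan_frame(self, which: str = "bf") -> pd.DataFrame:
        """Per-tested-marker chrom, pos and -log10 p (nominal and GC)."""
        p, pgc = {"bf": ("bf_p", "bf_p_gc"), "wx": ("wx_p", "wx_p_gc")}[which]
        t = self.table[self.table["reason_code"] == REASON_TESTED]
        return pd.DataFrame(
            {
                "chrom": t["chrom"].to_numpy(),
                "pos": t["pos"].to_numpy(),
                "neglog10_p": -np.log10(t[p].to_numpy(float)),
                "neglog10_p_gc": -np.log10(t[pgc].to_numpy(float)),
            }
        )

    def qq_frame(self, which: str = "bf") -> pd.DataFrame:
        """Expected vs observed -log10 p, ascending in the expected column."""
        col = {"bf": "bf_p_gc", "wx": "wx_p_gc"}[which]
        t = self.table[self.table["reason_code"] == REASON_TESTED]
        obs = np.sort(t[col].to_numpy(float))
        n = obs.size
        expected = (np.arange(1, n + 1) - 0.5) / n
        return pd.DataFrame(
            {
                "expected_neglog10_p": -np.log10(expected[::-1]),
                "observed_neglog10_p": -np.log10(obs[::-1]),
            }
        )

    def summary_dict(self) -> dict:
        t = self.table
        return {
            "trait": self.trait,
            "config": asdict(self.config),
            "n_markers": int(len(t)),
            "n_tested": self.n_tested,
            "reason_counts": {
                k: int(v) for k, v in t["reason_code"].value_counts().items()
            },
            "lambda_bf": self.lambda_bf,
            "lambda_wx": self.lambda_wx,
            "bonferroni_threshold": self.bonferroni,
            "n_significant_bf": int(len(self.significant("bf"))),
            "n_significant_wx": int(len(self.significant("wx"))),
            "inflated": bool(self.inflated),
        }

    def to_files(self, prefix: str) -> list:
        """Write PREFIX.scan.tsv, PREFIX.summary.json, PREFIX.qq.tsv and
        PREFIX.manhattan.tsv; returns the paths written."""
        import json

        paths = []
        p = f"{prefix}.scan.tsv"
        self.table.to_csv(p, sep="\t", index=False, na_rep="NA")
        paths.append(p)
        p = f"{prefix}.summary.json"
        with open(p, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)
            fh.write("\n")
        paths.append(p)
        for which in ("bf", "wx"):
            p = f"{prefix}.qq.{which}.tsv"
            self.qq_frame(which).to_csv(p, sep="\t", index=False)
            paths.append(p)
            p = f"{prefix}.manhattan.{which}.tsv"
            self.manhattan_frame(which).to_csv(p, sep="\t", index=False)
            paths.append(p)
        return paths

    def plot_manhattan(self, which: str = "bf", ax=None):
        """Manhattan plot of GC-corrected p-values (requires matplotlib)."""
        import matplotlib.pyplot as plt

        frame = self.manhattan_frame(which)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset, ticks = 0, {}
        for chrom, sub in frame.groupby("chrom", sort=True):
            x = sub["pos"].to_numpy() + offset
            ax.scatter(x, sub["neglog10_p_gc"], s=4)
            ticks[chrom] = x.mean()
            offset = x.max()
        ax.axhline(-math.log10(self.bonferroni), ls="--", c="red", lw=0.8)
        ax.set_xticks(list(ticks.values()), list(ticks.keys()))
        ax.set_ylabel(r"$-\log_{10} p$ (GC)")
        ax.set_xlabel("chromosome")
        return ax


def run_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    config: ScanConfig | None = None,
) -> ScanResults:
    """Convenience wrapper: build a VarianceScan and fit it."""
    return VarianceScan(genotypes, phenotypes, trait, config).fit()


@dataclass(frozen=True)
class ScanOverlap:
    n: int
    n_sig_gwas: int
    n_sig_vgwas: int
    n_sig_both: int
    ratio_vgwas_to_gwas: float
    joint_per_mille: float


def compare_scans(p_gwas, p_vgwas, threshold: float) -> ScanOverlap:
    """Overlap of significant markers between a mean and a variance scan.

    ``joint_per_mille`` is the number of markers significant in both scans
    per 1000 markers significant in either.
    """
    p_gwas = np.asarray(p_gwas, dtype=float)
    p_vgwas = np.asarray(p_vgwas, dtype=float)
    if p_gwas.shape != p_vgwas.shape:
        raise ValueError("p-value vectors must have equal length")
    sig_g = p_gwas < threshold
    sig_v = p_vgwas < threshold
    both = int(np.sum(sig_g & sig_v))
    either = int(np.sum(sig_g | sig_v))
    n_g, n_v = int(sig_g.sum()), int(sig_v.sum())
    return ScanOverlap(
        n=p_gwas.size,
        n_sig_gwas=n_g,
        n_sig_vgwas=n_v,
        n_sig_both=both,
        ratio_vgwas_to_gwas=(n_v / n_g) if n_g else math.inf if n_v else math.nan,
        joint_per_mille=(1000.0 * both / either) if either else 0.0,
    )
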