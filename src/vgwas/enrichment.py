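"""Candidate-gene enrichment by merged rank-order lists.

A scan that identifies true signals should place a-priori candidate genes
unusually high in its marker ranking.  Each SNP is ranked by ascending
GC-corrected p-value; a gene's rank is the best SNP rank within a window
around the gene, and the GWAS and vGWAS rank lists are merged by taking the
element-wise best (minimum) rank.  An improvement of candidate-gene ranks
when the variance scan is merged in indicates that the variance scan
contributes real, complementary signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import REASON_TESTED


def rank_pvalues(p: np.ndarray) -> np.ndarray:
    """Rank 1..m by ascending p; tied values share the floored average of
    their tied positions (deterministic)."""
    p = np.asarray(p, dtype=float)
    return np.floor(stats.rankdata(p, method="average")).astype(int)


def gene_best_ranks(
    scan_table: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 20_000,
    p_column: str = "bf_p_gc",
) -> pd.Series:
    """Best SNP rank per gene, NaN when no SNP falls in the gene window.

    ``genes`` is BED-like (chrom, start 0-based half-open, end, gene_id);
    a SNP at 1-based position x is assigned to the gene when
    start - window < x <= end + window.
    """
    t = scan_table[scan_table["reason_code"] == REASON_TESTED]
    if t.empty:
        raise ValueError("scan table has no tested markers")
    ranks = rank_pvalues(t[p_column].to_numpy(float))
    chroms = t["chrom"].to_numpy()
    pos = t["pos"].to_numpy(int)

    out = {}
    for row in genes.itertuples(index=False):
        on_chrom = chroms == row.chrom
        # BED start is 0-based half-open: bases start+1 .. end in 1-based.
        hit = on_chrom & (pos > row.start - window) & (pos <= row.end + window)
        out[row.gene_id] = int(ranks[hit].min()) if hit.any() else np.nan
    return pd.Series(out, name="best_rank")


@dataclass(frozen=True)
class EnrichmentSummary:
    n_genes: int  # genes with a rank in both scans
    n_improved: int  # combined rank strictly better than GWAS-only
    fraction_improved: float
    mean_rank_change: float  # mean of (gwas - combined) over genes with both


def merge_and_score(
    gwas_ranks: pd.Series, vgwas_ranks: pd.Series
) -> tuple[pd.DataFrame, EnrichmentSummary]:
    """Merge per-gene best ranks; combined rank is the element-wise minimum.

    A gene "improved" when the combined rank is strictly smaller than its
    GWAS-only rank, i.e. the variance scan ranked it better.  Summary
    statistics cover genes with a rank in both scans.
    """
    table = pd.DataFrame(
        {"best_rank_gwas": gwas_ranks, "best_rank_vgwas": vgwas_ranks}
    )
    table["best_rank_combined"] = table[["best_rank_gwas", "best_rank_vgwas"]].min(
        axis=1, skipna=True
    )
    table["improved"] = (
        table["best_rank_combined"] < table["best_rank_gwas"]
    ) & table["best_rank_vgwas"].notna()

    both = table.dropna(subset=["best_rank_gwas", "best_rank_vgwas"])
    n = len(both)
    n_improved = int(both["improved"].sum())
    change = (both["best_rank_gwas"] - both["best_rank_combined"]).mean()
    summary = EnrichmentSummary(
        n_genes=n,
        n_improved=n_improved,
        fraction_improved=(n_improved / n) if n else 0.0,
        mean_rank_change=float(change) if n else 0.0,
    )
    return table, summary
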