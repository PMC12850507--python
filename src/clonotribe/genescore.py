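"""Gene-level target scoring, rank-sum differential expression, and the
threshold-defined down-regulated network.

The per-gene HyperTRIBE score is the sum of differential editing
frequencies over the gene's retained edit sites (a gene edited at two
nucleotides in 50% and 70% of reads scores 1.2). Differential expression
between perturbed and control cell groups uses a two-sided Wilcoxon
rank-sum test on normalized expression, gated on the percent of
expressing cells, with BH adjustment over tested genes. The network is
the intersection of bound (score >= 0.2) and significantly down-regulated
(relative expression <= 0.95, adjusted P < 0.05) genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from clonotribe.editing import bh_adjust
from clonotribe.filtering import annotate_sites

PSEUDOCOUNT = 1e-9


def map_sites_to_genes(retained_sites: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign each retained site to every overlapping gene on its strand.

    Intergenic or strand-mismatched sites are dropped with a warning; a
    site inside two overlapping genes contributes to both.
    """
    return annotate_sites(retained_sites, annotation)


def hypertribe_scores(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-gene score: sum of diff_freq over assigned retained sites.

    Genes without retained sites are absent (score 0 by convention).
    """
    if assignments.empty:
        return pd.DataFrame(columns=["gene_id", "n_sites", "score"])
    grouped = assignments.groupby("gene_id", sort=True)["diff_freq"]
    out = pd.DataFrame({"n_sites": grouped.size(), "score": grouped.sum()}).reset_index()
    return out


def _normalize(matrix: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Counts-per-10k normalization (cells x genes)."""
    totals = matrix.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts cannot be normalized")
    return matrix.div(totals, axis=0) * target_sum


def rank_sum_de(
    matrix: pd.DataFrame,
    labels: pd.Series,
    perturbed: str,
    control: str,
    min_pct: float = 0.10,
    min_abs_change: float = 0.05,
    normalize: bool = True,
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum differential expression.

    Parameters
    ----------
    matrix
        Cells x genes expression counts (raw counts if ``normalize``).
    labels
        Per-cell group labels containing the two requested groups.
    perturbed, control
        Group labels; relative expression is perturbed over control.
    min_pct
        Genes expressed (count > 0) in at least this fraction of cells in
        one of the two groups are tested; others are skipped.
    min_abs_change
        Genes with ``|rel_expr - 1| < min_abs_change`` are reported but
        flagged non-significant.

    Returns a table with rel_expr, pct per group, the raw and BH-adjusted
    rank-sum p-value over tested genes, and a ``significant`` flag
    combining the adjusted-p and effect-size gates.
    """
    for g, name in ((perturbed, "perturbed"), (control, "control")):
        if (labels == g).sum() < 3:
            raise ValueError(f"{name} group '{g}' needs >= 3 cells")
    a = matrix.loc[labels[labels == perturbed].index]
    b = matrix.loc[labels[labels == control].index]
    norm_a = _normalize(a) if normalize else a
    norm_b = _normalize(b) if normalize else b

    pct_a = (a > 0).mean(axis=0)
    pct_b = (b > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)

    mean_a = norm_a.mean(axis=0)
    mean_b = norm_b.mean(axis=0)
    rel = (mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT)

    pvals = pd.Series(np.nan, index=matrix.columns)
    genes = matrix.columns[tested]
    small = len(a) + len(b) <= 20
    for gene in genes:
        xa = norm_a[gene].to_numpy()
        xb = norm_b[gene].to_numpy()
        has_ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
        method = "exact" if small and not has_ties else "asymptotic"
        pvals[gene] = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method).pvalue

    out = pd.DataFrame(
        {
            "gene_id": matrix.columns,
            "rel_expr": rel.to_numpy(),
            "pct_perturbed": pct_a.to_numpy(),
            "pct_control": pct_b.to_numpy(),
            "tested": tested.to_numpy(),
            "p_value": pvals.to_numpy(),
        }
    )
    out["adj_p"] = np.nan
    if tested.any():
        out.loc[out["tested"], "adj_p"] = bh_adjust(out.loc[out["tested"], "p_value"].to_numpy())
    out["significant"] = (
        out["tested"]
        & (out["adj_p"] < 0.05)
        & ((out["rel_expr"] - 1.0).abs() >= min_abs_change)
    )
    return out


def define_network(
    scores: pd.DataFrame,
    de: pd.DataFrame,
    min_score: float = 0.2,
    max_rel: float = 0.95,
    max_adj_p: float = 0.05,
) -> pd.DataFrame:
    """Intersect bound and down-regulated genes.

    Included iff score >= min_score (inclusive) AND rel_expr <= max_rel
    (inclusive) AND adj_p < max_adj_p (strict).
    """
    merged = scores.merge(de, on="gene_id", how="inner")
    keep = (
        (merged["score"] >= min_score)
        & (merged["rel_expr"] <= max_rel)
        & (merged["adj_p"] < max_adj_p)
    )
    cols = ["gene_id", "n_sites", "score", "rel_expr", "adj_p"]
    return merged.loc[keep, cols].reset_index(drop=True)
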