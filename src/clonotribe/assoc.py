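"""Allele-specific read skew and fixed-effect meta-analysis.

``allelic_skew`` quantifies departure from the 50:50 read balance
expected at a heterozygous site (e.g. reference vs alternate alleles in
ChIP or ATAC reads), reporting allele fractions, their fold ratio, and an
exact two-sided binomial test against 0.5. ``ivw_meta`` pools per-study
log-odds-ratio estimates with inverse-variance weights (fixed effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SkewResult:
    ref_label: str
    alt_label: str
    ref_fraction: float
    alt_fraction: float
    fold: float | None  # rounded for reporting
    fold_raw: float | None
    p_value: float
    extreme: bool  # alt fraction 0: fold undefined


def allelic_skew(
    ref_label: str,
    alt_label: str,
    ref_reads: int,
    alt_reads: int,
    fold_decimals: int = 1,
) -> SkewResult:
    """Skew of read fractions at a heterozygous site.

    Fractions sum to 1; the fold is ref fraction over alt fraction,
    rounded to ``fold_decimals`` for reporting (raw ratio carried
    alongside). With zero alternate reads the fold is undefined: the
    result is flagged ``extreme`` with fraction 1.0 instead of a number.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total < 1:
        raise ValueError("total reads must be >= 1")
    ref_frac = ref_reads / total
    alt_frac = alt_reads / total
    p = stats.binomtest(ref_reads, total, 0.5, alternative="two-sided").pvalue
    if alt_reads == 0:
        return SkewResult(ref_label, alt_label, 1.0, 0.0, None, None, p, extreme=True)
    raw = ref_frac / alt_frac
    return SkewResult(
        ref_label,
        alt_label,
        ref_frac,
        alt_frac,
        round(raw, fold_decimals),
        raw,
        p,
        extreme=False,
    )


@dataclass
class MetaResult:
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_studies: int


def ivw_meta(betas, ses, ci_multiplier: float = 1.96) -> MetaResult:
    """Inverse-variance-weighted fixed-effect meta-analysis.

    Weights are 1/se^2; the pooled effect is the weighted mean with
    standard error (sum of weights)^(-1/2). The odds ratio and its 95%
    CI are the exponentiated pooled log-odds-ratio.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("at least one study is required")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return MetaResult(
        beta=beta,
        se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - ci_multiplier * se)),
        ci_high=float(np.exp(beta + ci_multiplier * se)),
        n_studies=int(betas.size),
    )
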