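"""Candidate edit-site discovery and filtering.

Reproduces the pre-statistics filtering of an ADAR-fusion editing screen:
per-sample discovery thresholds (coverage and minor-allele frequency),
dbSNP-style blacklist exclusion, the >=2-treatment-sample rule, the
strand/mismatch-type rule (A>G forward or T>C reverse, so that A or T is
the major allele in controls), and assembly of a per-site count matrix
across all samples with k=0 where controls are unedited.

Site tables are long DataFrames with columns
``chrom, pos (1-based), strand, ref, alt, sample, group, k, n``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from clonotribe.simulate import CONTROL, TREATMENT

logger = logging.getLogger(__name__)

SITE_KEY = ["chrom", "pos", "strand", "ref", "alt"]


def per_sample_site_discovery(
    counts: pd.DataFrame,
    min_coverage: int = 10,
    min_maf: float = 0.01,
) -> pd.DataFrame:
    """Flag, per (site, sample) row, whether the mismatch is discovered.

    A site is discovered in a sample iff coverage >= ``min_coverage`` and
    k/n >= ``min_maf``. Rows with n = 0 are silently undiscovered.
    Returns a copy of ``counts`` with a boolean ``discovered`` column.
    """
    if (counts["k"] < 0).any() or (counts["n"] < 0).any():
        raise ValueError("counts must be non-negative")
    out = counts.copy()
    n = out["n"].to_numpy()
    k = out["k"].to_numpy(dtype=float)
    maf = np.divide(k, n, out=np.zeros_like(k), where=n > 0)
    out["discovered"] = (n >= min_coverage) & (maf >= min_maf)
    return out


def filter_known_variants(sites: pd.DataFrame, snp_blacklist: pd.DataFrame) -> pd.DataFrame:
    """Remove rows whose (chrom, pos, alt) key appears in the blacklist."""
    if snp_blacklist.empty:
        return sites.copy()
    bad = set(zip(snp_blacklist["chrom"], snp_blacklist["pos"], snp_blacklist["alt"]))
    keep = [
        (c, p, a) not in bad
        for c, p, a in zip(sites["chrom"], sites["pos"], sites["alt"])
    ]
    return sites.loc[keep].reset_index(drop=True)


def _strand_rule(ref: str, alt: str, strand: str) -> bool:
    return (ref == "A" and alt == "G" and strand == "+") or (ref == "T" and alt == "C" and strand == "-")


def select_candidates(
    counts: pd.DataFrame,
    min_treatment_samples: int = 2,
    min_coverage: int = 10,
    min_maf: float = 0.01,
) -> pd.DataFrame:
    """Apply the candidacy rules and return the retained site keys.

    A site is a candidate iff

    1. it passes per-sample discovery in at least ``min_treatment_samples``
       treatment samples (discovery thresholds are applied to treatment
       samples only; control frequencies may legitimately sit below the
       MAF gate),
    2. the mismatch is A>G on the forward strand or T>C on the reverse
       strand, and
    3. the reference allele is the majority allele in pooled control
       reads (sum k / sum n < 0.5); zero pooled control coverage fails
       this check, since the majority condition is unverifiable.
    """
    disc = per_sample_site_discovery(counts, min_coverage=min_coverage, min_maf=min_maf)
    trt = disc[disc["group"] == TREATMENT]
    n_disc = trt.groupby(SITE_KEY, sort=False)["discovered"].sum()
    ctl = disc[disc["group"] == CONTROL]
    pooled = ctl.groupby(SITE_KEY, sort=False)[["k", "n"]].sum()

    keys = []
    for key, count in n_disc.items():
        if count < min_treatment_samples:
            continue
        chrom, pos, strand, ref, alt = key
        if not _strand_rule(ref, alt, strand):
            continue
        if key not in pooled.index:
            continue
        k_sum, n_sum = pooled.loc[key, "k"], pooled.loc[key, "n"]
        if n_sum == 0 or k_sum / n_sum >= 0.5:
            continue
        keys.append(key)
    return pd.DataFrame(keys, columns=SITE_KEY)


def annotate_sites(sites: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign sites to overlapping genes on the matching strand.

    Sites falling in no annotated gene (or on the wrong strand) are
    dropped with a logged warning. A site inside two overlapping genes is
    assigned to both (one output row each).
    """
    rows = []
    dropped = 0
    for site in sites.itertuples():
        hit = annotation[
            (annotation["chrom"] == site.chrom)
            & (annotation["gene_start"] < site.pos)
            & (site.pos <= annotation["gene_end"])
            & (annotation["strand"] == site.strand)
        ]
        if hit.empty:
            dropped += 1
            continue
        for gene in hit.itertuples():
            row = site._asdict()
            row.pop("Index", None)
            row["gene_id"] = gene.gene_id
            rows.append(row)
    if dropped:
        logger.warning("%d site(s) outside annotated genes were dropped", dropped)
    if not rows:
        return pd.DataFrame(columns=list(sites.columns) + ["gene_id"])
    return pd.DataFrame(rows)


def assemble_count_matrix(candidates: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Extract the full per-sample count rows for every candidate site.

    Every candidate gets one row per sample; k = 0 where the sample shows
    no mismatch (unedited controls), n = that sample's coverage. Rows with
    n = 0 are flagged ``usable = False`` and excluded from model fitting
    downstream. Candidates with zero coverage in all samples of either
    group are dropped with a logged warning.
    """
    if candidates.empty:
        raise ValueError("candidate set is empty")
    merged = candidates.merge(counts, on=SITE_KEY, how="left", validate="one_to_many")
    if merged[["sample", "k", "n"]].isna().any().any():
        raise ValueError("candidate site missing from the count table")
    merged["usable"] = merged["n"] > 0
    ok_groups = (
        merged[merged["usable"]]
        .groupby(SITE_KEY, sort=False)["group"]
        .nunique()
    )
    full = ok_groups[ok_groups == 2].index
    n_dropped = merged.groupby(SITE_KEY, sort=False).ngroups - len(full)
    if n_dropped:
        logger.warning("%d candidate site(s) with no usable coverage in one group were dropped", n_dropped)
    key_index = pd.MultiIndex.from_frame(merged[SITE_KEY])
    return merged[key_index.isin(full)].reset_index(drop=True)
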