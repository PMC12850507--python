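"""3'UTR motif-window construction and k-mer enrichment.

Sequence windows extend +/-100 bp around each retained 3'UTR edit site,
clipped to the containing UTR; overlapping windows are merged. Background
segments of 201 bp are sampled uniformly from 3'UTRs that do not overlap
the target pool. Windows are strand-oriented (reverse-complemented for
minus-strand genes) and reported as RNA (T -> U). Enrichment of each
observed k-mer (k in {6, 7, 8}; all overlapping occurrences counted) is a
one-sided binomial test of the target occurrence count against the
background per-position rate, with a pseudocount of 1 on background
counts and BH adjustment across k-mers of the same length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from clonotribe.editing import bh_adjust

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_CODE = {c: i for i, c in enumerate("ACGU")}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _to_rna(seq: str, strand: str) -> str:
    if strand == "-":
        seq = reverse_complement(seq)
    return seq.replace("T", "U")


@dataclass
class WindowSet:
    """Merged genomic intervals with their strand-oriented RNA sequences."""

    intervals: pd.DataFrame  # chrom, start, end (0-based half-open), strand
    sequences: list[str] = field(default_factory=list)
    role: str = "target"


def _merge_intervals(intervals: list[tuple[str, int, int, str]]) -> list[tuple[str, int, int, str]]:
    merged: list[tuple[str, int, int, str]] = []
    for chrom, start, end, strand in sorted(intervals):
        if merged and merged[-1][0] == chrom and merged[-1][3] == strand and start <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], end), strand))
        else:
            merged.append((chrom, start, end, strand))
    return merged


def build_windows(
    sites: pd.DataFrame,
    annotation: pd.DataFrame,
    genome: dict[str, str],
    flank: int = 100,
) -> WindowSet:
    """Build merged target windows around 3'UTR edit sites.

    Each site contributes the interval [pos - flank, pos + flank] clipped
    to its containing UTR (an interior site yields a 201-bp window);
    overlapping intervals are merged. Sites outside every annotated UTR
    are skipped with a warning.
    """
    raw: list[tuple[str, int, int, str]] = []
    skipped = 0
    for site in sites.itertuples():
        p0 = site.pos - 1  # 1-based -> 0-based
        utr = annotation[
            (annotation["chrom"] == site.chrom)
            & (annotation["strand"] == site.strand)
            & (annotation["utr_start"] <= p0)
            & (p0 < annotation["utr_end"])
        ]
        if utr.empty:
            skipped += 1
            continue
        u = utr.iloc[0]
        start = max(p0 - flank, int(u["utr_start"]))
        end = min(p0 + flank + 1, int(u["utr_end"]))
        raw.append((site.chrom, start, end, site.strand))
    if skipped:
        logger.warning("%d site(s) outside annotated 3'UTRs were skipped", skipped)
    merged = _merge_intervals(raw)
    intervals = pd.DataFrame(merged, columns=["chrom", "start", "end", "strand"])
    seqs = [_to_rna(genome[c][s:e], st) for c, s, e, st in merged]
    return WindowSet(intervals=intervals, sequences=seqs, role="target")


def sample_background(
    annotation: pd.DataFrame,
    genome: dict[str, str],
    targets: WindowSet,
    n_segments: int,
    seed: int,
    segment_len: int = 201,
) -> WindowSet:
    """Sample fixed-length background segments from non-target 3'UTR space.

    Draws are uniform over feasible UTR start positions (UTRs shorter
    than ``segment_len`` are never sampled) and rejected if they overlap
    any target interval. Raises after ``10 * n_segments`` rejections,
    naming the deficit.
    """
    rng = np.random.default_rng(seed)
    utrs = annotation[annotation["utr_end"] - annotation["utr_start"] >= segment_len]
    if utrs.empty:
        raise ValueError(f"no 3'UTR of length >= {segment_len} to sample from")
    weights = (utrs["utr_end"] - utrs["utr_start"] - segment_len + 1).to_numpy(dtype=float)
    weights /= weights.sum()
    tgt = targets.intervals

    chosen: list[tuple[str, int, int, str]] = []
    rejections = 0
    while len(chosen) < n_segments:
        if rejections > 10 * n_segments:
            raise ValueError(
                f"could not place {n_segments} background segments "
                f"({len(chosen)} placed, {rejections} rejections); "
                "not enough non-target 3'UTR space"
            )
        u = utrs.iloc[int(rng.choice(len(utrs), p=weights))]
        start = int(rng.integers(u["utr_start"], u["utr_end"] - segment_len + 1))
        end = start + segment_len
        overlap = (
            (tgt["chrom"] == u["chrom"]) & (tgt["start"] < end) & (start < tgt["end"])
        ).any()
        if overlap:
            rejections += 1
            continue
        chosen.append((u["chrom"], start, end, u["strand"]))
    intervals = pd.DataFrame(chosen, columns=["chrom", "start", "end", "strand"])
    seqs = [_to_rna(genome[c][s:e], st) for c, s, e, st in chosen]
    return WindowSet(intervals=intervals, sequences=seqs, role="background")


def _kmer_counts(sequences: list[str], k: int) -> tuple[np.ndarray, int]:
    """Occurrence counts of every k-mer over ACGU, plus total positions."""
    counts = np.zeros(4**k, dtype=np.int64)
    positions = 0
    powers = 4 ** np.arange(k - 1, -1, -1)
    for seq in sequences:
        if len(seq) < k:
            continue
        arr = np.array([_RNA_CODE[c] for c in seq], dtype=np.int64)
        codes = np.lib.stride_tricks.sliding_window_view(arr, k) @ powers
        counts += np.bincount(codes, minlength=4**k)
        positions += len(seq) - k + 1
    return counts, positions


def _decode(code: int, k: int) -> str:
    letters = "ACGU"
    out = []
    for _ in range(k):
        out.append(letters[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_enrichment(targets: WindowSet, background: WindowSet, k: int) -> pd.DataFrame:
    """Binomial k-mer enrichment of target windows over background.

    For each k-mer observed in the target set, a one-sided conditional
    binomial (rate-ratio) test is applied: under the null of equal
    per-position occurrence rates, the target count among the pooled
    total of ``tc + bc`` occurrences is Binomial with success probability
    ``t_pos / (t_pos + b_pos)``. Conditioning on the pooled total
    accounts for the sampling noise of the background rate, so k-mers
    absent from the background still get a finite, calibrated p-value.
    The reported enrichment ratio uses a pseudocount of 1 on background
    counts to stay finite.
    """
    if not targets.sequences or not background.sequences:
        raise ValueError("both window sets must be non-empty")
    t_counts, t_pos = _kmer_counts(targets.sequences, k)
    b_counts, b_pos = _kmer_counts(background.sequences, k)
    null_frac = t_pos / (t_pos + b_pos)
    observed = np.nonzero(t_counts)[0]
    rows = []
    for code in observed:
        tc = int(t_counts[code])
        bc = int(b_counts[code])
        p = stats.binomtest(tc, tc + bc, null_frac, alternative="greater").pvalue
        rows.append(
            {
                "kmer": _decode(int(code), k),
                "target_count": tc,
                "background_count": bc,
                "enrichment": (tc / t_pos) / ((bc + 1) / b_pos),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "kmer"], ignore_index=True)
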