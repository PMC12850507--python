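"""Seeded synthetic-data generators with ground-truth tables.

Every downstream stage of the pipeline is exercised on data produced here:
an ADAR-fusion editing experiment (three treatment and three control
samples, overdispersed site coverage, strand-annotated A>G / T>C
mismatches, dbSNP-like contaminants) and a serial-sample clonal
hematopoiesis cohort (two blood draws, genotype-dependent clone growth,
binomial sequencing noise on VAFs).

All generators are deterministic given their ``seed``: the same config run
twice yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUCLEOTIDES = np.array(list("ACGT"))

TREATMENT = "treatment"
CONTROL = "control"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class EditSimConfig:
    """Parameters of the synthetic ADAR-fusion editing experiment.

    Parameters
    ----------
    seed
        Seed for all random draws.
    n_treatment, n_control
        Number of ADAR-fusion and empty-vector samples (3 + 3 mirrors the
        experimental design the pipeline is built for).
    n_sites
        Total number of emitted mismatch sites.
    frac_true_edits
        Fraction of sites that are genuinely edited in the treatment group.
    coverage_mean, coverage_dispersion
        Mean and dispersion of the negative-binomial per-site, per-sample
        coverage distribution (variance = m + m^2/dispersion), truncated
        below at 1 read.
    edit_freq_range
        Range of true editing frequencies for genuinely edited sites.
    control_noise_freq
        Background mismatch rate at unedited sites (sequencing error plus
        trace editing), applied to both groups at non-edited sites and to
        the control group at edited sites.
    frac_snp_contaminants
        Fraction of sites simulating germline SNPs: high, group-independent
        alt fraction (~0.5 het or ~1.0 hom), flagged in the truth table.
    frac_wrong_strand
        Fraction of sites carrying treatment-level editing signal but with
        a mismatch type that violates the A>G-forward / T>C-reverse rule,
        exercising the strand filter.
    """

    seed: int
    n_sites: int = 200
    n_treatment: int = 3
    n_control: int = 3
    frac_true_edits: float = 0.3
    coverage_mean: float = 200.0
    coverage_dispersion: float = 2.0
    edit_freq_range: tuple[float, float] = (0.1, 0.7)
    control_noise_freq: float = 0.005
    frac_snp_contaminants: float = 0.05
    frac_wrong_strand: float = 0.05

    def __post_init__(self) -> None:
        for name in ("frac_true_edits", "control_noise_freq", "frac_snp_contaminants", "frac_wrong_strand"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.edit_freq_range[0] <= self.edit_freq_range[1] <= 1.0):
            raise ValueError(f"edit_freq_range must be an ordered pair in [0, 1], got {self.edit_freq_range}")
        if self.coverage_mean < 10:
            raise ValueError("coverage_mean must be >= 10")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")
        if self.frac_true_edits + self.frac_snp_contaminants + self.frac_wrong_strand > 1.0:
            raise ValueError("site-class fractions sum to more than 1")


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic serial-sample CHIP cohort.

    Each person carries one CHIP mutation measured at two blood draws.
    The latent annualized clonal growth rate is

        r = mean_growth_noncarrier + genotype_effect * dosage + N(0, residual_sd)

    and the latent second-draw VAF is ``VAF1 * (1 + r)**dt`` clipped to
    (0, 1). Observed VAFs at both draws are binomial resamples at the
    drawn sequencing depths, so the calling thresholds downstream act on
    realistic read counts.
    """

    seed: int
    n_people: int = 3000
    carrier_freq: float = 0.065  # heterozygote frequency of the protective allele
    baseline_vaf_dist: tuple[float, float] = (1.2, 4.0)  # Beta shape params, scaled to [0.02, 0.40]
    mean_growth_noncarrier: float = 0.005  # per year
    genotype_effect: float = -0.004  # per year per protective allele
    residual_sd: float = 0.10  # per year
    dt_range: tuple[float, float] = (0.7, 13.0)  # years between draws
    depth_mean: float = 1725.0  # reads, error-corrected
    driver_genes: dict[str, float] = field(
        default_factory=lambda: {
            "DNMT3A": 0.45,
            "TET2": 0.25,
            "ASXL1": 0.10,
            "JAK2": 0.05,
            "TP53": 0.05,
            "SF3B1": 0.10,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise ValueError("carrier_freq must be in [0, 1]")
        if self.dt_range[0] <= 0 or self.dt_range[1] < self.dt_range[0]:
            raise ValueError("dt_range must be positive and ordered")
        if self.depth_mean < 100:
            raise ValueError("depth_mean must allow the 100x calling threshold")
        if self.n_people < 1:
            raise ValueError("n_people must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


# ---------------------------------------------------------------------------
# annotation / genome
# ---------------------------------------------------------------------------


def generate_annotation(
    seed: int,
    n_genes: int = 20,
    utr_len_range: tuple[int, int] = (240, 1200),
    body_len_range: tuple[int, int] = (300, 900),
    gap_range: tuple[int, int] = (200, 600),
    chrom: str = "chr1",
    planted_motifs: list[tuple[int, int, str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate non-overlapping gene models on one chromosome.

    Each gene has a body and a single 3'UTR at its 3' end (rightmost
    interval on '+' genes, leftmost on '-' genes). Coordinates are 0-based
    half-open, matching the BED emission. The chromosome sequence is
    uniform random over ACGT; ``planted_motifs`` is a list of
    ``(gene_index, offset_within_utr, motif)`` triples written into the
    sequence (on the genomic forward strand).

    Returns
    -------
    annotation : DataFrame
        Columns gene_id, chrom, strand, gene_start, gene_end, utr_start,
        utr_end.
    genome : dict
        Chromosome name -> sequence string.
    """
    if utr_len_range[0] <= 0 or utr_len_range[1] < utr_len_range[0]:
        raise ValueError("utr_len_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    rows = []
    cursor = int(rng.integers(gap_range[0], gap_range[1] + 1))
    for i in range(n_genes):
        utr_len = int(rng.integers(utr_len_range[0], utr_len_range[1] + 1))
        body_len = int(rng.integers(body_len_range[0], body_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        end = start + body_len + utr_len
        if strand == "+":
            utr_start, utr_end = end - utr_len, end
        else:
            utr_start, utr_end = start, start + utr_len
        rows.append(
            {
                "gene_id": f"G{i:04d}",
                "chrom": chrom,
                "strand": strand,
                "gene_start": start,
                "gene_end": end,
                "utr_start": utr_start,
                "utr_end": utr_end,
            }
        )
        cursor = end + int(rng.integers(gap_range[0], gap_range[1] + 1))
    annotation = pd.DataFrame(rows)
    seq = rng.choice(NUCLEOTIDES, size=cursor + gap_range[1]).astype(object)
    if planted_motifs:
        for gene_idx, offset, motif in planted_motifs:
            utr_start = int(annotation.loc[gene_idx, "utr_start"])
            pos = utr_start + offset
            seq[pos : pos + len(motif)] = list(motif)
    genome = {chrom: "".join(seq)}
    return annotation, genome


# ---------------------------------------------------------------------------
# editing dataset
# ---------------------------------------------------------------------------


def _truncated_nb(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial draws truncated below at 1 (zeros resampled)."""
    p = dispersion / (dispersion + mean)
    out = rng.negative_binomial(dispersion, p, size=size)
    while np.any(out == 0):
        zero = out == 0
        out[zero] = rng.negative_binomial(dispersion, p, size=int(zero.sum()))
    return out


def _eligible_positions(annotation: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """All 3'UTR positions whose reference base fits the editing chemistry.

    A>G on forward-strand genes, T>C on reverse-strand genes (deamination
    always acts on the adenosine of the transcript).
    """
    frames = []
    for row in annotation.itertuples():
        seq = genome[row.chrom]
        base = "A" if row.strand == "+" else "T"
        offsets = np.array([p for p in range(row.utr_start, row.utr_end) if seq[p] == base], dtype=int)
        if offsets.size:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": row.chrom,
                        "pos0": offsets,
                        "strand": row.strand,
                        "gene_id": row.gene_id,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos0", "strand", "gene_id"])
    return pd.concat(frames, ignore_index=True)


def generate_editing_dataset(
    config: EditSimConfig,
    annotation: pd.DataFrame,
    genome: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-site, per-sample allele counts plus a truth table.

    Sites fall into four classes: true edits (treatment frequency drawn
    from ``edit_freq_range``, control at the background rate), background
    noise sites (background rate in both groups), SNP contaminants (high
    group-independent alt fraction, flagged), and wrong-strand signal
    sites (treatment-level editing on a mismatch type the strand rule
    must reject).

    Returns
    -------
    counts : DataFrame
        Long table: chrom, pos (1-based), strand, ref, alt, sample,
        group, k, n.
    truth : DataFrame
        One row per site: coordinates, gene_id, is_true_edit, is_snp,
        is_wrong_strand, true_freq_treatment, true_freq_control.
    """
    if annotation.empty:
        raise ValueError("annotation must be non-empty")
    rng = np.random.default_rng(config.seed)

    n_true = round(config.frac_true_edits * config.n_sites)
    n_snp = round(config.frac_snp_contaminants * config.n_sites)
    n_wrong = round(config.frac_wrong_strand * config.n_sites)
    n_noise = config.n_sites - n_true - n_snp - n_wrong
    if n_noise < 0:
        raise ValueError("site-class fractions exceed n_sites")

    eligible = _eligible_positions(annotation, genome)
    if len(eligible) < n_true + n_noise + n_snp:
        raise ValueError(
            f"requested {n_true + n_noise + n_snp} A/T 3'UTR sites but only "
            f"{len(eligible)} eligible positions exist"
        )
    picks = eligible.iloc[rng.choice(len(eligible), size=n_true + n_noise + n_snp, replace=False)].reset_index(
        drop=True
    )

    sites = []
    lo, hi = config.edit_freq_range
    for i, row in enumerate(picks.itertuples()):
        is_true = i < n_true
        is_snp = i >= n_true + n_noise
        ref = "A" if row.strand == "+" else "T"
        alt = "G" if row.strand == "+" else "C"
        if is_snp:
            af = 0.5 if rng.random() < 0.5 else 1.0
            f_trt = f_ctl = af
        elif is_true:
            f_trt = float(rng.uniform(lo, hi))
            f_ctl = config.control_noise_freq
        else:
            f_trt = f_ctl = config.control_noise_freq
        sites.append(
            {
                "chrom": row.chrom,
                "pos": int(row.pos0) + 1,
                "strand": row.strand,
                "ref": ref,
                "alt": alt,
                "gene_id": row.gene_id,
                "is_true_edit": is_true,
                "is_snp": is_snp,
                "is_wrong_strand": False,
                "true_freq_treatment": f_trt,
                "true_freq_control": f_ctl,
            }
        )

    # wrong-strand sites: treatment-level signal on the wrong mismatch type
    used = set(zip(picks["chrom"], picks["pos0"]))
    wrong_pool = []
    for row in annotation.itertuples():
        seq = genome[row.chrom]
        base = "T" if row.strand == "+" else "A"  # opposite of the eligible base
        for p in range(row.utr_start, row.utr_end):
            if seq[p] == base and (row.chrom, p) not in used:
                wrong_pool.append((row.chrom, p, row.strand, row.gene_id))
    if n_wrong > len(wrong_pool):
        raise ValueError("not enough positions for wrong-strand sites")
    if n_wrong:
        for j in rng.choice(len(wrong_pool), size=n_wrong, replace=False):
            chrom, p, strand, gene_id = wrong_pool[j]
            ref = "T" if strand == "+" else "A"
            alt = "C" if strand == "+" else "G"
            sites.append(
                {
                    "chrom": chrom,
                    "pos": p + 1,
                    "strand": strand,
                    "ref": ref,
                    "alt": alt,
                    "gene_id": gene_id,
                    "is_true_edit": False,
                    "is_snp": False,
                    "is_wrong_strand": True,
                    "true_freq_treatment": float(rng.uniform(lo, hi)) if hi > 0 else 0.0,
                    "true_freq_control": config.control_noise_freq,
                }
            )

    truth = pd.DataFrame(sites).sort_values(["chrom", "pos"]).reset_index(drop=True)

    samples = [(f"ADAR-{i + 1}", TREATMENT) for i in range(config.n_treatment)] + [
        (f"EV-{i + 1}", CONTROL) for i in range(config.n_control)
    ]
    n_total = len(truth) * len(samples)
    cov = _truncated_nb(rng, config.coverage_mean, config.coverage_dispersion, n_total)
    freq_trt = np.repeat(truth["true_freq_treatment"].to_numpy(), len(samples))
    freq_ctl = np.repeat(truth["true_freq_control"].to_numpy(), len(samples))
    group = np.tile([g for _, g in samples], len(truth))
    freqs = np.where(group == TREATMENT, freq_trt, freq_ctl)
    k = rng.binomial(cov, freqs)

    counts = pd.DataFrame(
        {
            "chrom": np.repeat(truth["chrom"].to_numpy(), len(samples)),
            "pos": np.repeat(truth["pos"].to_numpy(), len(samples)),
            "strand": np.repeat(truth["strand"].to_numpy(), len(samples)),
            "ref": np.repeat(truth["ref"].to_numpy(), len(samples)),
            "alt": np.repeat(truth["alt"].to_numpy(), len(samples)),
            "sample": np.tile([s for s, _ in samples], len(truth)),
            "group": group,
            "k": k,
            "n": cov,
        }
    )
    return counts, truth


def snp_blacklist_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Blacklist table (chrom, pos, alt) for the simulated SNP contaminants."""
    snp = truth.loc[truth["is_snp"], ["chrom", "pos", "alt"]]
    return snp.reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-draw CHIP cohort with genotype-dependent growth.

    Age and sex are drawn independently of genotype (a known-null
    confounding structure, so covariate-recovery tests have a clean
    target). Depths are Poisson around ``depth_mean``; alt-read counts
    and VAFs are binomial resamples of the latent clone size.

    Returns (cohort, truth): the cohort table carries observed
    measurements only, the truth table the latent growth rate and
    genotype per person.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_people

    # dosage of the protective allele; hets at carrier_freq, rare homozygotes
    hom_freq = (config.carrier_freq / 2.0) ** 2
    u = rng.random(n)
    dosage = np.where(u < hom_freq, 2, np.where(u < hom_freq + config.carrier_freq, 1, 0))

    age = np.clip(rng.normal(65.0, 8.0, n), 35.0, 95.0)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    genes = list(config.driver_genes)
    weights = np.array([config.driver_genes[g] for g in genes], dtype=float)
    weights = weights / weights.sum()
    gene = rng.choice(genes, size=n, p=weights)

    a, b = config.baseline_vaf_dist
    vaf1_true = 0.02 + 0.38 * rng.beta(a, b, n)
    dt = rng.uniform(config.dt_range[0], config.dt_range[1], n)
    r_true = (
        config.mean_growth_noncarrier
        + config.genotype_effect * dosage
        + (rng.normal(0.0, config.residual_sd, n) if config.residual_sd > 0 else 0.0)
    )
    vaf2_true = np.clip(vaf1_true * (1.0 + r_true) ** dt, 1e-6, 0.999)

    depth1 = np.maximum(rng.poisson(config.depth_mean, n), 1)
    depth2 = np.maximum(rng.poisson(config.depth_mean, n), 1)
    if np.any(depth1 < 0) or np.any(depth2 < 0):
        raise ValueError("negative sequencing depth")
    alt1 = rng.binomial(depth1, vaf1_true)
    alt2 = rng.binomial(depth2, vaf2_true)

    cohort = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "genotype": dosage,
            "gene": gene,
            "vaf1": alt1 / depth1,
            "depth1": depth1,
            "alt1": alt1,
            "vaf2": alt2 / depth2,
            "depth2": depth2,
            "alt2": alt2,
            "dt_years": dt,
        }
    )
    truth = pd.DataFrame(
        {
            "id": cohort["id"],
            "genotype": dosage,
            "true_r": r_true,
            "true_vaf1": vaf1_true,
            "true_vaf2": vaf2_true,
        }
    )
    return cohort, truth


def generate_expression(
    seed: int,
    gene_ids: list[str],
    target_genes: set[str],
    n_cells_per_group: int = 100,
    effect: float = 0.8,
    mean_range: tuple[float, float] = (20.0, 100.0),
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a two-group expression matrix with planted down-regulation.

    Per-gene baseline means are uniform over ``mean_range``; counts are
    Poisson. Genes in ``target_genes`` have their mean multiplied by
    ``effect`` in the perturbed group (0.8 = 20% down-regulation).
    Returns a cells x genes count matrix and per-cell labels
    ('perturbed' / 'control').
    """
    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    base = rng.uniform(mean_range[0], mean_range[1], n_genes)
    is_target = np.array([g in target_genes for g in gene_ids])
    mean_pert = np.where(is_target, base * effect, base)
    pert = rng.poisson(np.tile(mean_pert, (n_cells_per_group, 1)))
    ctrl = rng.poisson(np.tile(base, (n_cells_per_group, 1)))
    cells = [f"pert-{i}" for i in range(n_cells_per_group)] + [f"ctrl-{i}" for i in range(n_cells_per_group)]
    matrix = pd.DataFrame(np.vstack([pert, ctrl]), index=cells, columns=gene_ids)
    labels = pd.Series(
        ["perturbed"] * n_cells_per_group + ["control"] * n_cells_per_group,
        index=cells,
        name="group",
    )
    return matrix, labels


def simulate_transience_labels(
    cohort: pd.DataFrame,
    log_or: float,
    seed: int,
    base_rate: float = 0.22,
) -> pd.Series:
    """Draw binary transience outcomes from a logistic model with a known
    genotype log-odds-ratio; used for parameter-recovery checks of the
    transience regression."""
    rng = np.random.default_rng(seed)
    eta = np.log(base_rate / (1 - base_rate)) + log_or * cohort["genotype"].to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(rng.random(len(cohort)) < p, index=cohort.index, name="transient").astype(int)


def simulate_null_site(
    rng: np.random.Generator,
    freq: float = 0.01,
    coverage_mean: float = 200.0,
    coverage_dispersion: float = 1.0,
    n_treatment: int = 3,
    n_control: int = 3,
) -> pd.DataFrame:
    """One site with identical true frequency in both groups and
    overdispersed coverage; the null instrument for type-I calibration."""
    m = n_treatment + n_control
    n = _truncated_nb(rng, coverage_mean, coverage_dispersion, m)
    k = rng.binomial(n, freq)
    group = np.array([TREATMENT] * n_treatment + [CONTROL] * n_control)
    return pd.DataFrame({"group": group, "k": k, "n": n})
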