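"""Pipeline configuration and the end-to-end synthetic run.

``PipelineConfig`` collects every stage threshold (defaulting to the
analysis' canonical values) plus simulation parameters and the mandatory
seed; ``run_full_pipeline`` executes the stages in dependency order on
synthetic data, writes each artifact as TSV/BED/FASTA/JSON next to the
resolved config, and returns a manifest with per-artifact row counts and
the truth-table recall of the edit-site caller.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from clonotribe import clonal, editing, filtering, genescore, io, motifs, simulate


@dataclass
class PipelineConfig:
    """All stage thresholds and simulation parameters of one run."""

    seed: int
    outdir: str = "clonotribe-run"
    # discovery / candidacy
    min_coverage: int = 10
    min_maf: float = 0.01
    min_treatment_samples: int = 2
    # retention criteria
    min_diff: float = 0.1
    max_control_freq: float = 0.02
    max_fdr: float = 0.05
    # network thresholds
    min_score: float = 0.2
    max_rel: float = 0.95
    max_adj_p: float = 0.05
    min_pct: float = 0.10
    min_abs_change: float = 0.05
    # CHIP calling
    min_depth: int = 100
    min_alt_reads: int = 3
    min_vaf: float = 0.02
    # motif windows
    flank: int = 100
    background_len: int = 201
    n_background: int = 200
    kmer_lengths: tuple[int, ...] = (6, 7, 8)
    # simulation sizes
    n_genes: int = 40
    n_sites: int = 200
    frac_true_edits: float = 0.3
    coverage_mean: float = 200.0
    coverage_dispersion: float = 2.0
    edit_freq_range: tuple[float, float] = (0.2, 0.7)
    n_people: int = 2000
    n_cells_per_group: int = 100

    _RANGES = {
        "min_maf": (0.0, 1.0),
        "min_diff": (0.0, 1.0),
        "max_control_freq": (0.0, 1.0),
        "max_fdr": (0.0, 1.0),
        "min_score": (0.0, None),
        "max_rel": (0.0, None),
        "max_adj_p": (0.0, 1.0),
        "min_pct": (0.0, 1.0),
        "min_abs_change": (0.0, 1.0),
        "min_vaf": (0.0, 1.0),
        "frac_true_edits": (0.0, 1.0),
    }

    def validate(self) -> None:
        """Raise ValueError naming the first out-of-range field."""
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ValueError(f"config field '{name}' out of range: {v}")
        for name in ("min_coverage", "min_treatment_samples", "min_depth", "min_alt_reads",
                     "flank", "background_len", "n_genes", "n_sites", "n_people"):
            if getattr(self, name) < 1:
                raise ValueError(f"config field '{name}' must be >= 1")
        if self.seed is None:
            raise ValueError("config field 'seed' is mandatory")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["edit_freq_range"] = list(self.edit_freq_range)
        data["kmer_lengths"] = list(self.kmer_lengths)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "edit_freq_range" in data:
            data["edit_freq_range"] = tuple(data["edit_freq_range"])
        if "kmer_lengths" in data:
            data["kmer_lengths"] = tuple(data["kmer_lengths"])
        return cls(**data)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> filter -> model -> score -> network, plus the
    motif and cohort branches, writing all artifacts under ``outdir``.

    Returns the output manifest (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    manifest: dict = {"artifacts": {}, "metrics": {}}

    def emit(name: str, df, path: Path, comments: list[str] | None = None) -> None:
        io.write_tsv(df, path, comments=comments)
        manifest["artifacts"][name] = {"path": str(path), "rows": int(len(df))}

    # --- simulate -----------------------------------------------------
    annotation, genome = simulate.generate_annotation(config.seed, n_genes=config.n_genes)
    edit_cfg = simulate.EditSimConfig(
        seed=config.seed + 1,
        n_sites=config.n_sites,
        frac_true_edits=config.frac_true_edits,
        coverage_mean=config.coverage_mean,
        coverage_dispersion=config.coverage_dispersion,
        edit_freq_range=config.edit_freq_range,
    )
    counts, truth = simulate.generate_editing_dataset(edit_cfg, annotation, genome)
    blacklist = simulate.snp_blacklist_from_truth(truth)
    io.write_bed(annotation, out / "utr.bed", feature="utr")
    io.write_fasta(genome, out / "genome.fa")
    emit("site_counts", counts, out / "site_counts.tsv", [f"seed={config.seed}"])
    emit("truth_sites", truth, out / "truth_sites.tsv")
    emit("snp_blacklist", blacklist, out / "snp_blacklist.tsv")

    # --- filter -------------------------------------------------------
    candidates = filtering.select_candidates(
        counts,
        min_treatment_samples=config.min_treatment_samples,
        min_coverage=config.min_coverage,
        min_maf=config.min_maf,
    )
    candidates = filtering.filter_known_variants(candidates, blacklist)
    count_matrix = filtering.assemble_count_matrix(candidates, counts)
    emit("candidates", candidates, out / "candidates.tsv")

    # --- model --------------------------------------------------------
    results = editing.test_sites(count_matrix)
    retained = editing.call_edit_sites(
        results,
        min_diff=config.min_diff,
        max_control_freq=config.max_control_freq,
        max_fdr=config.max_fdr,
    )
    emit("site_tests", results, out / "site_tests.tsv")
    emit("retained_sites", retained, out / "retained_sites.tsv")

    true_keys = set(map(tuple, truth.loc[truth["is_true_edit"], ["chrom", "pos"]].to_numpy()))
    ret_keys = set(map(tuple, retained[["chrom", "pos"]].to_numpy())) if len(retained) else set()
    recall = len(true_keys & ret_keys) / len(true_keys) if true_keys else float("nan")
    false_retained = len(ret_keys - true_keys)
    manifest["metrics"]["edit_site_recall"] = recall
    manifest["metrics"]["edit_site_fdr"] = false_retained / len(ret_keys) if ret_keys else 0.0

    # --- score + network ---------------------------------------------
    assignments = genescore.map_sites_to_genes(retained, annotation)
    scores = genescore.hypertribe_scores(assignments)
    emit("gene_scores", scores, out / "gene_scores.tsv")

    target_genes = set(truth.loc[truth["is_true_edit"], "gene_id"])
    matrix, labels = simulate.generate_expression(
        config.seed + 2,
        gene_ids=list(annotation["gene_id"]),
        target_genes=target_genes,
        n_cells_per_group=config.n_cells_per_group,
    )
    io.write_expression_mtx(matrix, out / "expression.mtx")
    io.write_tsv(labels.rename("group").rename_axis("cell").reset_index(), out / "cell_labels.tsv")
    de = genescore.rank_sum_de(
        matrix,
        labels,
        perturbed="perturbed",
        control="control",
        min_pct=config.min_pct,
        min_abs_change=config.min_abs_change,
    )
    network = genescore.define_network(
        scores,
        de,
        min_score=config.min_score,
        max_rel=config.max_rel,
        max_adj_p=config.max_adj_p,
    )
    emit("de_results", de, out / "de_results.tsv")
    emit("network", network, out / "network.tsv")

    # --- motif --------------------------------------------------------
    if len(retained):
        windows = motifs.build_windows(retained, annotation, genome, flank=config.flank)
        background = motifs.sample_background(
            annotation,
            genome,
            windows,
            n_segments=config.n_background,
            seed=config.seed + 3,
            segment_len=config.background_len,
        )
        io.write_fasta(
            {f"target_{i}": s for i, s in enumerate(windows.sequences)}, out / "target_windows.fa"
        )
        io.write_fasta(
            {f"background_{i}": s for i, s in enumerate(background.sequences)}, out / "background_windows.fa"
        )
        for k in config.kmer_lengths:
            enr = motifs.kmer_enrichment(windows, background, k)
            emit(f"motif_k{k}", enr, out / f"motif_k{k}.tsv")

    # --- cohort -------------------------------------------------------
    cohort_cfg = simulate.CohortSimConfig(seed=config.seed + 4, n_people=config.n_people)
    cohort, cohort_truth = simulate.generate_cohort(cohort_cfg)
    classified = clonal.classify_trajectories(
        cohort,
        min_depth=config.min_depth,
        min_alt_reads=config.min_alt_reads,
        min_vaf=config.min_vaf,
    )
    emit("cohort", cohort, out / "cohort.tsv")
    emit("cohort_truth", cohort_truth, out / "cohort_truth.tsv")
    emit("cohort_classified", classified, out / "cohort_classified.tsv")

    persistent = classified[classified["class"] == clonal.PERSISTENT]
    baseline = classified[classified["class"].isin([clonal.PERSISTENT, clonal.TRANSIENT])]
    growth_table = clonal.fit_growth_model(persistent)
    transience_table = clonal.fit_transience_model(baseline)
    emit("growth_model", growth_table, out / "growth_model.tsv")
    emit("transience_model", transience_table, out / "transience_model.tsv")
    manifest["metrics"]["n_persistent"] = int((classified["class"] == clonal.PERSISTENT).sum())
    manifest["metrics"]["n_transient"] = int((classified["class"] == clonal.TRANSIENT).sum())
    manifest["metrics"]["genotype_growth_coef"] = float(clonal.genotype_effect(growth_table)["coef"])
    manifest["metrics"]["genotype_transience_or"] = float(clonal.genotype_effect(transience_table)["or"])

    io.write_manifest(manifest, out / "manifest.json")
    return manifest
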