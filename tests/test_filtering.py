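"""Discovery thresholds, blacklist semantics and candidacy rules."""

import numpy as np
import pandas as pd
import pytest

from clonotribe import filtering, simulate
from conftest import make_counts


@pytest.mark.parametrize(
    "k,n,expected",
    [
        (5, 9, False),  # below the coverage gate
        (1, 10, True),  # maf 0.1 at minimum coverage
        (5, 1000, False),  # maf 0.005 below the 0.01 gate
        (0, 500, False),
        (10, 1000, True),  # maf exactly 0.01 (inclusive)
        (0, 0, False),  # zero coverage: silently undiscovered
    ],
)
def test_per_sample_discovery_thresholds(k, n, expected):
    counts = make_counts([("chr1", 100, "+", "A", "G", "s1", "treatment", k, n)])
    out = filtering.per_sample_site_discovery(counts)
    assert out["discovered"].iloc[0] == expected


def test_discovery_rejects_negative_counts():
    counts = make_counts([("chr1", 100, "+", "A", "G", "s1", "treatment", -1, 10)])
    with pytest.raises(ValueError):
        filtering.per_sample_site_discovery(counts)


class TestBlacklist:
    def test_empty_blacklist_is_identity(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "alt": ["G"]})
        out = filtering.filter_known_variants(sites, pd.DataFrame(columns=["chrom", "pos", "alt"]))
        pd.testing.assert_frame_equal(out, sites)

    def test_exact_key_match_removed_other_alt_retained(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [100, 100], "alt": ["G", "A"]}
        )
        blacklist = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "alt": ["G"]})
        out = filtering.filter_known_variants(sites, blacklist)
        assert out["alt"].tolist() == ["A"]

    def test_mismatched_alt_not_removed(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "alt": ["G"]})
        blacklist = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "alt": ["T"]})
        out = filtering.filter_known_variants(sites, blacklist)
        assert len(out) == 1


def _six_sample_site(pos, ref, alt, strand, trt_k, ctl_k, n=200):
    rows = []
    for i, k in enumerate(trt_k):
        rows.append(("chr1", pos, strand, ref, alt, f"ADAR-{i+1}", "treatment", k, n))
    for i, k in enumerate(ctl_k):
        rows.append(("chr1", pos, strand, ref, alt, f"EV-{i+1}", "control", k, n))
    return rows


class TestCandidateSelection:
    def test_single_treatment_sample_not_enough(self):
        counts = make_counts(_six_sample_site(10, "A", "G", "+", (50, 1, 0), (0, 0, 0)))
        assert len(filtering.select_candidates(counts)) == 0

    def test_two_treatment_samples_with_minor_control_kept(self):
        counts = make_counts(_six_sample_site(10, "A", "G", "+", (50, 40, 0), (2, 2, 2)))
        assert len(filtering.select_candidates(counts)) == 1

    def test_wrong_mismatch_type_dropped(self):
        counts = make_counts(_six_sample_site(10, "C", "T", "+", (50, 40, 45), (0, 0, 0)))
        assert len(filtering.select_candidates(counts)) == 0

    def test_t_to_c_on_reverse_strand_kept(self):
        counts = make_counts(_six_sample_site(10, "T", "C", "-", (50, 40, 45), (0, 0, 0)))
        assert len(filtering.select_candidates(counts)) == 1

    def test_control_majority_alt_fails(self):
        # alt is the control major allele (e.g. a homozygous SNP)
        counts = make_counts(_six_sample_site(10, "A", "G", "+", (190, 185, 180), (150, 160, 170)))
        assert len(filtering.select_candidates(counts)) == 0

    def test_zero_pooled_control_coverage_fails(self):
        rows = _six_sample_site(10, "A", "G", "+", (50, 40, 45), (0, 0, 0))
        rows = [r if r[6] == "treatment" else r[:8] + (0,) for r in rows]
        counts = make_counts(rows)
        assert len(filtering.select_candidates(counts)) == 0


class TestAssembleMatrix:
    def test_unedited_control_row_has_zero_k_full_coverage(self):
        counts = make_counts(_six_sample_site(10, "A", "G", "+", (50, 40, 45), (0, 0, 0)))
        candidates = filtering.select_candidates(counts)
        matrix = filtering.assemble_count_matrix(candidates, counts)
        ev = matrix[matrix["sample"] == "EV-1"]
        assert ev["k"].iloc[0] == 0 and ev["n"].iloc[0] == 200

    def test_shape_is_candidates_times_samples(self):
        rows = []
        for pos in range(10, 110, 10):
            rows += _six_sample_site(pos, "A", "G", "+", (50, 40, 45), (1, 0, 2))
        counts = make_counts(rows)
        candidates = filtering.select_candidates(counts)
        assert len(candidates) == 10
        matrix = filtering.assemble_count_matrix(candidates, counts)
        assert len(matrix) == 60

    def test_missing_coverage_flagged_not_fitted(self):
        rows = _six_sample_site(10, "A", "G", "+", (50, 40, 45), (1, 0, 2))
        rows[5] = rows[5][:8] + (0,)  # EV-3 has no coverage
        counts = make_counts(rows)
        matrix = filtering.assemble_count_matrix(
            filtering.select_candidates(counts), counts
        )
        assert matrix["usable"].sum() == 5
        assert not matrix.loc[matrix["sample"] == "EV-3", "usable"].iloc[0]

    def test_empty_candidates_rejected(self):
        counts = make_counts(_six_sample_site(10, "A", "G", "+", (50, 40, 45), (0, 0, 0)))
        with pytest.raises(ValueError):
            filtering.assemble_count_matrix(counts.iloc[:0][filtering.SITE_KEY], counts)


def test_filter_order_does_not_matter(editing_dataset):
    """Discovery -> blacklist equals blacklist -> discovery."""
    counts, truth = editing_dataset
    blacklist = simulate.snp_blacklist_from_truth(truth)

    cand_then_bl = filtering.filter_known_variants(
        filtering.select_candidates(counts), blacklist
    )
    pre_filtered = filtering.filter_known_variants(counts, blacklist)
    bl_then_cand = filtering.select_candidates(pre_filtered)

    a = set(map(tuple, cand_then_bl[filtering.SITE_KEY].to_numpy()))
    b = set(map(tuple, bl_then_cand[filtering.SITE_KEY].to_numpy()))
    assert a == b


def test_truth_blacklist_removes_all_snp_contaminants(editing_dataset):
    counts, truth = editing_dataset
    blacklist = simulate.snp_blacklist_from_truth(truth)
    candidates = filtering.filter_known_variants(filtering.select_candidates(counts), blacklist)
    snp_keys = set(map(tuple, truth.loc[truth["is_snp"], ["chrom", "pos"]].to_numpy()))
    cand_keys = set(map(tuple, candidates[["chrom", "pos"]].to_numpy()))
    assert not (snp_keys & cand_keys)


def test_filters_never_alter_counts(editing_dataset):
    counts, _ = editing_dataset
    before = counts.copy()
    filtering.select_candidates(counts)
    filtering.per_sample_site_discovery(counts)
    pd.testing.assert_frame_equal(counts, before)


def test_annotate_sites_assigns_overlapping_genes():
    annotation = pd.DataFrame(
        {
            "gene_id": ["A", "B"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "+"],
            "gene_start": [0, 50],
            "gene_end": [100, 150],
            "utr_start": [0, 50],
            "utr_end": [100, 150],
        }
    )
    sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [30, 75, 500], "strand": ["+"] * 3})
    out = filtering.annotate_sites(sites, annotation)
    assert sorted(out.loc[out["pos"] == 75, "gene_id"]) == ["A", "B"]  # overlap -> both
    assert (out.loc[out["pos"] == 30, "gene_id"] == "A").all()
    assert 500 not in out["pos"].to_numpy()  # intergenic dropped
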