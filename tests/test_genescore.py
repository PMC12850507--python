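"""Gene scoring, rank-sum DE against an enumeration oracle, and the
network threshold intersection."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonotribe import genescore, simulate

ANNOT = pd.DataFrame(
    {
        "gene_id": ["A", "B"],
        "chrom": ["chr1", "chr1"],
        "strand": ["+", "+"],
        "gene_start": [0, 500],
        "gene_end": [400, 900],
        "utr_start": [200, 700],
        "utr_end": [400, 900],
    }
)


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "diff_freq"])


class TestScores:
    def test_two_sites_half_and_seventy_percent_score_one_point_two(self):
        sites = _sites([("chr1", 250, "+", 0.5), ("chr1", 300, "+", 0.7)])
        assignments = genescore.map_sites_to_genes(sites, ANNOT)
        scores = genescore.hypertribe_scores(assignments)
        assert scores.loc[scores["gene_id"] == "A", "score"].iloc[0] == pytest.approx(1.2)
        assert scores.loc[scores["gene_id"] == "A", "n_sites"].iloc[0] == 2

    def test_singleton_site_scores_its_difference(self):
        assignments = genescore.map_sites_to_genes(_sites([("chr1", 600, "+", 0.3)]), ANNOT)
        scores = genescore.hypertribe_scores(assignments)
        assert scores["score"].tolist() == [pytest.approx(0.3)]

    def test_gene_without_sites_absent(self):
        assignments = genescore.map_sites_to_genes(_sites([("chr1", 250, "+", 0.5)]), ANNOT)
        scores = genescore.hypertribe_scores(assignments)
        assert "B" not in scores["gene_id"].tolist()

    @settings(deadline=None, max_examples=50)
    @given(
        diffs=st.lists(st.floats(0.1, 1.0), min_size=1, max_size=12),
        split=st.integers(0, 12),
    )
    def test_score_additivity_over_batches(self, diffs, split):
        split = min(split, len(diffs))
        rows = [("chr1", 250 + i, "+", d) for i, d in enumerate(diffs)]
        total = genescore.hypertribe_scores(
            genescore.map_sites_to_genes(_sites(rows), ANNOT)
        )["score"].iloc[0]
        parts = 0.0
        for batch in (rows[:split], rows[split:]):
            if batch:
                parts += genescore.hypertribe_scores(
                    genescore.map_sites_to_genes(_sites(batch), ANNOT)
                )["score"].iloc[0]
        assert parts == pytest.approx(total, rel=1e-9)


def exact_rank_sum_p(xa, xb):
    """Two-sided rank-sum p by exhaustive enumeration of label assignments."""
    pooled = np.concatenate([xa, xb])
    ranks = pd.Series(pooled).rank().to_numpy()
    na = len(xa)
    w_obs = ranks[:na].sum()
    mean_w = ranks.sum() * na / len(pooled)
    stats_all = [
        ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), na)
    ]
    dev = np.abs(np.array(stats_all) - mean_w)
    return float(np.mean(dev >= abs(w_obs - mean_w) - 1e-12))


class TestRankSumDE:
    def test_eight_cell_matrix_matches_enumeration(self, rng):
        values = rng.normal(10, 2, size=(8, 5))
        matrix = pd.DataFrame(values, index=[f"c{i}" for i in range(8)],
                              columns=[f"g{i}" for i in range(5)])
        labels = pd.Series(["perturbed"] * 4 + ["control"] * 4, index=matrix.index)
        de = genescore.rank_sum_de(matrix, labels, "perturbed", "control", normalize=False)
        for gene in matrix.columns:
            expected = exact_rank_sum_p(values[:4, matrix.columns.get_loc(gene)],
                                        values[4:, matrix.columns.get_loc(gene)])
            assert de.loc[de["gene_id"] == gene, "p_value"].iloc[0] == pytest.approx(expected)

    def test_low_pct_gene_not_tested(self, rng):
        n = 40
        matrix = pd.DataFrame(
            {
                "rare": np.r_[np.ones(1), np.zeros(n - 1)],  # 2.5% expressed
                "common": rng.poisson(5, n) + 1.0,
            },
            index=[f"c{i}" for i in range(n)],
        )
        labels = pd.Series(["perturbed"] * 20 + ["control"] * 20, index=matrix.index)
        de = genescore.rank_sum_de(matrix, labels, "perturbed", "control")
        assert not de.loc[de["gene_id"] == "rare", "tested"].iloc[0]
        assert de.loc[de["gene_id"] == "common", "tested"].iloc[0]

    def test_label_swap_inverts_ratio_keeps_p(self, rng):
        matrix = pd.DataFrame(
            rng.poisson(8, size=(30, 6)) + 1.0, index=[f"c{i}" for i in range(30)],
            columns=[f"g{i}" for i in range(6)],
        )
        labels = pd.Series(["perturbed"] * 15 + ["control"] * 15, index=matrix.index)
        de_fwd = genescore.rank_sum_de(matrix, labels, "perturbed", "control")
        de_rev = genescore.rank_sum_de(matrix, labels, "control", "perturbed")
        np.testing.assert_allclose(de_fwd["rel_expr"], 1.0 / de_rev["rel_expr"], rtol=1e-6)
        np.testing.assert_allclose(de_fwd["p_value"], de_rev["p_value"], rtol=1e-12)

    def test_null_pvalues_approximately_uniform(self, rng):
        """Identical populations give a p-value distribution a KS test
        cannot distinguish from uniform at alpha = 0.01."""
        from scipy import stats as sps

        matrix = pd.DataFrame(
            rng.lognormal(2.0, 0.5, size=(120, 500)),
            index=[f"c{i}" for i in range(120)],
            columns=[f"g{i}" for i in range(500)],
        )
        labels = pd.Series(["perturbed"] * 60 + ["control"] * 60, index=matrix.index)
        de = genescore.rank_sum_de(matrix, labels, "perturbed", "control", normalize=False)
        ks_p = sps.kstest(de["p_value"], "uniform").pvalue
        assert ks_p > 0.01

    def test_small_group_rejected(self):
        matrix = pd.DataFrame(np.ones((4, 2)), index=list("abcd"), columns=["g1", "g2"])
        labels = pd.Series(["perturbed"] * 2 + ["control"] * 2, index=matrix.index)
        with pytest.raises(ValueError):
            genescore.rank_sum_de(matrix, labels, "perturbed", "control")


class TestNetwork:
    SCORES = pd.DataFrame({"gene_id": ["a", "b", "c"], "n_sites": [1, 1, 1], "score": [0.19, 0.25, 0.5]})

    def test_threshold_inclusivity(self):
        de = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "rel_expr": [0.90, 0.95, 0.99],
                "adj_p": [0.001, 0.01, 0.001],
            }
        )
        net = genescore.define_network(self.SCORES, de)
        # a: score 0.19 < 0.2 excluded; b: rel exactly 0.95 included; c: rel > 0.95 excluded
        assert net["gene_id"].tolist() == ["b"]

    def test_disjoint_tables_give_empty_network(self):
        de = pd.DataFrame({"gene_id": ["x"], "rel_expr": [0.5], "adj_p": [0.001]})
        assert len(genescore.define_network(self.SCORES, de)) == 0


def test_planted_network_recovered_with_high_precision_and_recall():
    """Genes that are both bound (score >= 0.2) and 20% down-regulated are
    recovered by the threshold intersection from 100 cells per group."""
    gene_ids = [f"G{i:03d}" for i in range(500)]
    targets = set(gene_ids[:50])  # bound AND down-regulated
    bound = set(gene_ids[:100])  # bound genes: only half are down-regulated
    matrix, labels = simulate.generate_expression(
        31, gene_ids, targets, n_cells_per_group=100, effect=0.8
    )
    scores = pd.DataFrame(
        {"gene_id": gene_ids, "n_sites": 1, "score": [0.5 if g in bound else 0.05 for g in gene_ids]}
    )
    de = genescore.rank_sum_de(matrix, labels, "perturbed", "control")
    net = genescore.define_network(scores, de)
    found = set(net["gene_id"])
    recall = len(found & targets) / len(targets)
    precision = len(found & targets) / max(len(found), 1)
    assert recall >= 0.90
    assert precision >= 0.80
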