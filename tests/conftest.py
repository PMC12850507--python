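import numpy as np
import pandas as pd
import pytest

from clonotribe import simulate


@pytest.fixture(scope="session")
def small_annotation():
    """Deterministic toy annotation + genome shared across tests."""
    return simulate.generate_annotation(seed=11, n_genes=20)


@pytest.fixture(scope="session")
def editing_dataset(small_annotation):
    annotation, genome = small_annotation
    cfg = simulate.EditSimConfig(seed=5, n_sites=80, frac_true_edits=0.3)
    counts, truth = simulate.generate_editing_dataset(cfg, annotation, genome)
    return counts, truth


def make_counts(rows):
    """Build a long site-count table from (chrom,pos,strand,ref,alt,sample,group,k,n) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "ref", "alt", "sample", "group", "k", "n"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
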