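import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lncguide import (
    GeneModel,
    GenomeSequence,
    SyntheticSpec,
    feature_matrix,
    generate_labeled_dataset,
    generate_toy_genome,
    grid_search_train,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_guide(rng, length=20):
    return "".join(rng.choice(list("ACGT"), length))


@pytest.fixture(scope="session")
def small_spec():
    """Reduced study conditions for fast model-dependent tests."""
    return SyntheticSpec(genome_length=60_000, n_genes=3, n_pos=60, n_neg=60, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_labeled_dataset(small_spec)


@pytest.fixture(scope="session")
def small_xy(small_dataset):
    X = feature_matrix(small_dataset.guides())
    y = small_dataset.labels()
    return X, y


@pytest.fixture(scope="session")
def toy_models(small_xy):
    """One trained model per mechanism on the reduced synthetic data, with
    a small grid to keep the suite fast."""
    X, y = small_xy
    grid = {"C": (1.0, 10.0), "gamma": (0.01, 0.1)}
    ko = grid_search_train(X, y, "CRISPRko", grid=grid, k_folds=5, seed=7)
    cri = grid_search_train(X, y, "CRISPRi", grid=grid, k_folds=5, seed=7)
    return {"CRISPRko": ko, "CRISPRi": cri}


@pytest.fixture(scope="session")
def toy_gene_setup():
    """A toy genome with genes, for design tests."""
    spec = SyntheticSpec(genome_length=60_000, n_genes=3, n_pos=60, n_neg=60, seed=7)
    genome, genes = generate_toy_genome(spec)
    return genome, genes
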