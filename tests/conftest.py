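"""Shared planted-data fixtures.

Everything is generated programmatically from fixed seeds; the expensive
objects (space, fitted mixture) are session-scoped so the suite fits in a
modest time budget.
"""

import numpy as np
import pytest

import foodlex as fl

MASTER_SEED = 12345


@pytest.fixture(scope="session")
def planted():
    """Default planted world: space + truth + seed lexicon + held-out words."""
    spec = fl.SyntheticSpec(seed=MASTER_SEED)
    space, cluster_truth, ed_truth = fl.generate_embedding_space(spec)
    lexicon, held_out = fl.generate_seed_lexicon(
        cluster_truth, ed_truth, fraction=0.5, seed=MASTER_SEED
    )
    return {
        "spec": spec,
        "space": space,
        "cluster_truth": cluster_truth,
        "ed_truth": ed_truth,
        "lexicon": lexicon,
        "held_out": held_out,
    }


@pytest.fixture(scope="session")
def seed_matrix(planted):
    """Seed surfaces, their vectors and binary labels, in sorted-word order."""
    space = planted["space"]
    words, X = space.subset(sorted(planted["lexicon"].surfaces))
    y = np.array([planted["ed_truth"][w] for w in words])
    return words, X, y


@pytest.fixture(scope="session")
def fitted_gmm(planted, seed_matrix):
    """A mixture fitted at the planted component count on the seed vectors."""
    _, X, _ = seed_matrix
    return fl.fit_gmm(X, K=planted["spec"].n_food_clusters, cov_type="full", seed=MASTER_SEED)


@pytest.fixture()
def tiny_space():
    """A hand-written 4-word, 3-dimensional space for exact-value tests."""
    words = ["apple", "banana", "carrot", "zero_adjacent"]
    vectors = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [1.0, 1.0, 0.0],
            [-1.0, 0.0, 0.0],
        ]
    )
    return fl.EmbeddingSpace(words, vectors)
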