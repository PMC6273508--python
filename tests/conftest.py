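import numpy as np
import pytest

from brs3d import fixtures, templates


@pytest.fixture(scope="session")
def toy_pool():
    """20 single-conformer toy molecules cycling through all families."""
    return fixtures.make_toy_pool(20, seed=0)


@pytest.fixture(scope="session")
def small_pool(toy_pool):
    return toy_pool[:8]


@pytest.fixture(scope="session")
def toy_library(small_pool):
    """k=4 template library from the 8-molecule pool."""
    return templates.build_template_library(small_pool, k=4)


@pytest.fixture(scope="session")
def pool_similarity(toy_pool):
    return templates.self_similarity_matrix(toy_pool)


@pytest.fixture(scope="session")
def pool_distances(pool_similarity):
    return templates.row_distance_matrix(pool_similarity)


@pytest.fixture(scope="session")
def classification_data():
    table, labels, informative = fixtures.make_classification_dataset(
        fixtures.DatasetSpec(
            seed=11, n_active=30, n_decoy=120, k=40, m_informative=6,
            shift=0.25, noise=0.05,
        )
    )
    return table.matrix, labels, informative
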