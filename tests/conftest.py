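import numpy as np
import pytest

import pf2sc as p


@pytest.fixture(scope="session")
def small_planted():
    """Small noiseless dataset with planted rank-3 structure, plus truth."""
    spec = p.SyntheticSpec(
        n_conditions=6, cells_per_condition=(20, 40), n_genes=30, rank=3, seed=0
    )
    return p.make_synthetic(spec)


@pytest.fixture(scope="session")
def small_fit(small_planted):
    ds, _ = small_planted
    return p.fit(ds, p.FitConfig(rank=3, seed=0))


@pytest.fixture(scope="session")
def small_fit_std(small_fit):
    return p.standardize(small_fit)


@pytest.fixture()
def toy_counts():
    """2 conditions x 2 cells, 3 genes of raw counts; hand-checkable."""
    m1 = np.array([[1.0, 0.0, 0.0], [0.5, 0.02, 0.06]])
    m2 = np.array([[0.3, 0.0, 0.01], [0.2, 0.0, 0.01]])
    return p.RaggedDataset(
        matrices=[m1, m2],
        condition_ids=["c1", "c2"],
        gene_ids=["g1", "g2", "g3"],
    )


def random_orthonormal(rng, rows, cols):
    q, _ = np.linalg.qr(rng.standard_normal((rows, cols)))
    return q
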