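import numpy as np
import pytest

import phoglysite as pg


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small labeled dataset with a strong class signal."""
    cfg = pg.SimulationConfig(
        n_proteins=6,
        length_range=(30, 80),
        positive_fraction=0.3,
        effect_size=1.0,
        seed=11,
    )
    return pg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_table(tiny_dataset):
    return pg.featurize_dataset(
        tiny_dataset.sites, tiny_dataset.pssms, tiny_dataset.structs
    )


@pytest.fixture(scope="session")
def imbalanced_dataset():
    """Benchmark-shaped dataset: 91 proteins, 1:29 class ratio, moderate
    class overlap — the regime where k-escalation cleaning terminates near
    the 2:1 target."""
    cfg = pg.SimulationConfig(length_range=(100, 800), seed=5)
    return pg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def imbalanced_table(imbalanced_dataset):
    ds = imbalanced_dataset
    return pg.featurize_dataset(ds.sites, ds.pssms, ds.structs)


def random_feature_table(
    rng: np.random.Generator, n_pos: int, n_neg: int, dim: int = 2
) -> pg.FeatureTable:
    """Gaussian two-class table for distance-based tests."""
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(n_pos, dim)),
            rng.normal(0.8, 1.2, size=(n_neg, dim)),
        ]
    )
    labels = np.array([1] * n_pos + [0] * n_neg)
    site_ids = [("p", i + 1) for i in range(n_pos + n_neg)]
    return pg.FeatureTable(
        X=X,
        labels=labels,
        site_ids=site_ids,
        column_names=[f"f{i}" for i in range(dim)],
    )
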