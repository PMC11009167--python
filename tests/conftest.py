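import logging

import numpy as np
import pandas as pd
import pytest

from celltreeage.simulate import SimConfig, simulate_cohort
from celltreeage.trees import CellTree, upgma, DistanceMatrix

logging.getLogger("celltreeage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four small samples with full truth + noisy observations."""
    cfg = SimConfig(n_samples=4, cells_per_sample=120, seed=7)
    mats, truths, meta = simulate_cohort(cfg)
    return cfg, mats, truths, meta


def random_ultrametric_tree(n_tips: int, rng: np.random.Generator) -> CellTree:
    """A random ultrametric tree via UPGMA of a random distance matrix."""
    a = rng.random((n_tips, n_tips))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"t{i}" for i in range(n_tips)]
    return upgma(DistanceMatrix(labels=labels, d=d))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_age_cohort():
    """30 default-configuration truth records (no UMI observation step).

    Shared by the age-signal checks; ages are the same uniform draw the
    cohort generator would use.
    """
    from celltreeage.simulate import simulate_lineage

    cfg = SimConfig(n_samples=30, seed=0)
    age_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    ages = age_rng.uniform(*cfg.age_range, cfg.n_samples)
    truths = []
    for k in range(cfg.n_samples):
        rng_k = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, k)))
        truths.append(simulate_lineage(float(ages[k]), cfg, rng_k, sample_id=f"S{k:02d}"))
    return ages, truths


@pytest.fixture(scope="session")
def synthetic_feature_cohort():
    """A feature table + metadata with a planted linear age signal.

    Used by the model-layer tests: 18 samples x 5 replicates, 31 metric
    columns of which a handful carry a noisy linear age dependence.
    """
    from celltreeage.features import FEATURE_NAMES

    rng = np.random.default_rng(99)
    n_samples, n_reps = 18, 5
    ages = rng.uniform(21, 82, n_samples)
    sexes = ["F" if i % 2 == 0 else "M" for i in range(n_samples)]
    rows = []
    for i in range(n_samples):
        for r in range(n_reps):
            vals = {}
            for j, f in enumerate(FEATURE_NAMES):
                if j < 5:  # informative metrics
                    vals[f] = 0.05 * ages[i] * (j + 1) + rng.normal(0, 0.8)
                else:
                    vals[f] = rng.normal(0, 1)
            rows.append({"sample_id": f"P{i:02d}", "replicate_id": r, **vals})
    features = pd.DataFrame(rows)
    metadata = pd.DataFrame({"sample_id": [f"P{i:02d}" for i in range(n_samples)],
                             "age": ages, "sex": sexes})
    return features, metadata
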