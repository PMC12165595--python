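import numpy as np
import pytest

from airwayspec.io import ESOPHAGUS, TRACHEA, AcquisitionMeta
from airwayspec.preprocess import FeatureVector
from airwayspec.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 900-spectrum cohort at a fixed seed (shared, read-only)."""
    cfg = SimulationConfig(seed=42)
    ds, truth = simulate_cohort(cfg)
    return cfg, ds, truth


@pytest.fixture
def small_cohort():
    """A 2-pair x 2 organ x 5-acquisition cohort for cheap end-to-end tests."""
    cfg = SimulationConfig(n_pairs=2, n_per_organ=5, seed=7)
    ds, truth = simulate_cohort(cfg)
    return cfg, ds, truth


def fv(x, y, pair_id=1, organ=TRACHEA, acq_index=1):
    """Shorthand feature-vector constructor for classifier tests."""
    return FeatureVector(
        r543=float(x), r578=float(y),
        meta=AcquisitionMeta(pair_id=pair_id, organ=organ, acq_index=acq_index),
    )


def random_feature_set(rng, n, cluster_gap=0.0):
    """n random labeled feature vectors; optional class mean separation."""
    pts, labels = [], []
    for i in range(n):
        organ = TRACHEA if i % 2 == 0 else ESOPHAGUS
        shift = -cluster_gap / 2 if organ == TRACHEA else cluster_gap / 2
        pts.append(
            fv(
                rng.normal(0.9 + shift, 0.05),
                rng.normal(0.9 + shift, 0.05),
                pair_id=1 + i // 100,
                organ=organ,
                acq_index=1 + i % 100,
            )
        )
        labels.append(organ)
    return pts, labels
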