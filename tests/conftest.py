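import numpy as np
import pandas as pd
import pytest

from rectomics.synthetic import PhantomConfig, generate_cohort, generate_feature_cohort, impute_cea
from rectomics.volumes import SegmentationMask, VolumeGrid


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three full phantoms (images + masks + table)."""
    cfg = PhantomConfig(n_subjects=3, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tabular_cohort():
    """Modelling-scale cohort: 200 subjects, 30 radiomics-like features."""
    cfg = PhantomConfig(n_subjects=200, seed=7)
    X, table = generate_feature_cohort(cfg)
    return X, impute_cea(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def ball_mask():
    """Rasterized ball of radius 10 mm on a 1 mm grid, with its spacing."""
    r = 10.0
    n = 25
    ax = (np.arange(n) - n // 2).astype(float)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (gx**2 + gy**2 + gz**2 <= r**2), (1.0, 1.0, 1.0)
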