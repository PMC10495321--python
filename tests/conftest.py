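"""Shared fixtures: small seeded synthetic datasets reused across test modules."""

import numpy as np
import pytest

from leafn.features import extract_table
from leafn.pipeline import preprocess_samples
from leafn.synthgen import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition tillering dataset (n=60, noise + illumination on)."""
    return generate_dataset(GeneratorConfig(n_samples=60, seed=42))


@pytest.fixture(scope="session")
def default_table(default_dataset):
    """Feature table + targets from the full preprocessing chain."""
    images, masks = preprocess_samples(default_dataset)
    table = extract_table(images, masks, [s.sample_id for s in default_dataset])
    y = np.array([s.n_value for s in default_dataset])
    return table, y


@pytest.fixture(scope="session")
def noiseless_table():
    """Noiseless dataset: leaf-mean channels exactly affine in N (raw images,
    ground-truth masks, no illumination)."""
    cfg = GeneratorConfig(n_samples=60, seed=1).noiseless()
    ds = generate_dataset(cfg)
    table = extract_table([s.image for s in ds], [s.true_mask for s in ds])
    y = np.array([s.n_value for s in ds])
    return table, y, ds
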