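"""Shared fixtures: tiny hand-built datasets and small planted-marker worlds."""

import numpy as np
import pytest

from pdxorigin.dataset import ExpressionMatrix, LabeledDataset
from pdxorigin.simulate import SyntheticConfig, generate_dataset


def make_dataset(values, labels, genes=None, samples=None, classes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return LabeledDataset(
        ExpressionMatrix(genes, samples, values), list(labels), classes or []
    )


@pytest.fixture
def tiny_ds():
    """2 genes x 3 samples, two classes."""
    return make_dataset(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], ["A", "A", "B"]
    )


@pytest.fixture(scope="session")
def planted_world():
    """4 classes x 15 samples, 100 genes, 3 markers per class, delta = 3."""
    cfg = SyntheticConfig(
        seed=11,
        class_names=("alpha", "beta", "gamma", "delta"),
        class_sizes=(15, 15, 15, 15),
        n_genes=100,
        markers_per_class=3,
        effect_size=3.0,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_3class():
    """3 classes, strong markers (delta = 4): SVM-separable planted data."""
    cfg = SyntheticConfig(
        seed=5,
        class_names=("a", "b", "c"),
        class_sizes=(30, 30, 30),
        n_genes=40,
        markers_per_class=2,
        effect_size=4.0,
    )
    return generate_dataset(cfg)
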