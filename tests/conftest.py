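import numpy as np
import pytest

from swarmselect.io_data import ExpressionDataset
from swarmselect.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """3 genes x 6 samples, gene 0 has class means 2 vs 5."""
    return ExpressionDataset(
        matrix=np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
                [2.0, 1.0, 2.0, 1.0, 2.0, 1.0],
            ]
        ),
        gene_ids=["g1", "g2", "g3"],
        sample_ids=[f"s{i}" for i in range(6)],
        labels=["A", "A", "A", "B", "B", "B"],
    )


@pytest.fixture
def planted_ds():
    """1000-gene dataset with 10 planted genes at effect size 2."""
    return generate_dataset(SyntheticSpec(
        n_genes=1000, n1=30, n2=30, n_informative=10,
        effect_size=2.0, noise_sd=1.0, seed=42,
    ))


@pytest.fixture
def small_planted_ds():
    """100-gene dataset with 5 strongly planted genes (fast end-to-end runs)."""
    return generate_dataset(SyntheticSpec(
        n_genes=100, n1=15, n2=15, n_informative=5,
        effect_size=4.0, noise_sd=1.0, seed=7,
    ))


def swap_classes(ds: ExpressionDataset) -> ExpressionDataset:
    """Same data with the two class tokens' roles exchanged."""
    return ExpressionDataset(
        matrix=ds.matrix.copy(),
        gene_ids=list(ds.gene_ids),
        sample_ids=list(ds.sample_ids),
        labels=list(ds.labels),
        class_names=(ds.class_names[1], ds.class_names[0]),
    )
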