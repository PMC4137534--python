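"""Microarray-like synthetic data with a planted differential signal.

Background genes are i.i.d. normal around a gene-specific baseline, identical
in both classes.  Planted genes get their class-2 ("tumor") mean shifted by
``effect_size * noise_sd``, so sign-sensitive statistics come out negative
for planted genes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import ExpressionDataset

DEFAULT_CLASS_NAMES = ("normal", "tumor")


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int
    n1: int
    n2: int
    n_informative: int
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    baseline_sd: float = 2.0  # spread of per-gene baseline means

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_informative < 0 or self.n_informative > self.n_genes:
            raise ValueError("need 0 <= n_informative <= n_genes")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each class needs at least 2 samples")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Generate a dataset and the sorted planted gene-index array.

    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n1 + spec.n2

    baseline = rng.normal(0.0, spec.baseline_sd, size=spec.n_genes)
    matrix = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, n_samples)
    )

    planted = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    # shift class-2 (tumor) columns of planted genes
    matrix[np.ix_(planted, np.arange(spec.n1, n_samples))] += (
        spec.effect_size * spec.noise_sd
    )

    width_g = max(4, len(str(spec.n_genes)))
    width_s = max(3, len(str(n_samples)))
    ds = ExpressionDataset(
        matrix=matrix,
        gene_ids=[f"G{i:0{width_g}d}" for i in range(spec.n_genes)],
        sample_ids=[f"S{j:0{width_s}d}" for j in range(n_samples)],
        labels=[DEFAULT_CLASS_NAMES[0]] * spec.n1 + [DEFAULT_CLASS_NAMES[1]] * spec.n2,
        class_names=DEFAULT_CLASS_NAMES,
    )
    return ds, planted


def planted_recovery_rate(ranking, planted) -> float:
    """Fraction of planted genes appearing in a ranking's top-m set."""
    planted_set = {int(i) for i in np.asarray(planted).ravel()}
    if not planted_set:
        raise ValueError("planted gene set is empty")
    top = {int(i) for i in np.asarray(ranking.top_m).ravel()}
    return len(top & planted_set) / len(planted_set)
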