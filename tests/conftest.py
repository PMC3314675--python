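import numpy as np
import pytest

from crossnorm import (
    CombinedDataset,
    ExpressionMatrix,
    SampleAnnotation,
    SyntheticConfig,
    simulate_linear,
)


def make_dataset(values1, values2, treatments1=None, treatments2=None):
    """Tiny CombinedDataset from raw per-platform arrays."""
    values1 = np.asarray(values1, dtype=float)
    values2 = np.asarray(values2, dtype=float)
    genes = [f"g{i}" for i in range(values1.shape[0])]
    ids1 = [f"s1_{j}" for j in range(values1.shape[1])]
    ids2 = [f"s2_{j}" for j in range(values2.shape[1])]
    treatments1 = treatments1 or ["A"] * len(ids1)
    treatments2 = treatments2 or ["A"] * len(ids2)
    records = [(s, "p1", t) for s, t in zip(ids1, treatments1)]
    records += [(s, "p2", t) for s, t in zip(ids2, treatments2)]
    return CombinedDataset(
        ExpressionMatrix(genes, ids1, values1),
        ExpressionMatrix(genes, ids2, values2),
        SampleAnnotation.from_records(records),
    )


@pytest.fixture
def small_linear():
    """A 60-gene, 4-replicate two-treatment linear dataset with truth."""
    cfg = SyntheticConfig(
        n_genes=60, n_per_group=4, seed=7, de_fraction=0.3,
        platform_shift_sd=0.6, interaction_fraction=0.2,
    )
    return simulate_linear(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
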