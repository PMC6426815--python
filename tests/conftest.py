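import numpy as np
import pandas as pd
import pytest

from taupattern.design import GROUP_ORDER
from taupattern.io import ExpressionMatrix


def make_design(n_per_group=(3, 3, 3, 3)) -> pd.DataFrame:
    rows = []
    for group, n in zip(GROUP_ORDER, n_per_group):
        genotype, treatment = group.split("_")
        for i in range(n):
            rows.append((f"{group}_{i + 1}", genotype, treatment))
    df = pd.DataFrame(rows, columns=["sample", "genotype", "treatment"])
    return df.set_index("sample")


def make_matrix(values: np.ndarray, n_per_group=(3, 3, 3, 3), genes=None) -> ExpressionMatrix:
    design = make_design(n_per_group)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if genes is None:
        genes = [f"TC{i + 1:06d}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=design.index), design)


@pytest.fixture
def balanced_design():
    return make_design((3, 3, 3, 3))


@pytest.fixture
def unbalanced_design():
    return make_design((6, 6, 5, 6))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
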