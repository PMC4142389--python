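import numpy as np
import pandas as pd
import pytest

from coexshift.expression_io import ExpressionMatrix
from coexshift.synthetic_data import SyntheticSpec, generate_expression


def make_matrix(n_genes: int, n_a: int, n_b: int, seed: int = 0,
                labels=("disease", "normal")) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    values = pd.DataFrame(
        rng.standard_normal((n_genes, n_a + n_b)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=samples,
    )
    groups = {s: (labels[0] if s.startswith("A") else labels[1]) for s in samples}
    return ExpressionMatrix(values=values, group_of=groups)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return make_matrix(6, 4, 5, seed=3)


@pytest.fixture
def study_matrix() -> ExpressionMatrix:
    """Default synthetic study: 60 genes, 12-gene block, 8 normal + 9 disease."""
    return generate_expression(SyntheticSpec(seed=11))


@pytest.fixture
def study_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=11)
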