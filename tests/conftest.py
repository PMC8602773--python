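import numpy as np
import pytest

from pseudopath import ExpressionMatrix, simulate_linear


@pytest.fixture
def tiny_expr():
    """3 cells x 4 genes with distinct, non-constant rows."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [2.0, 1.0, 4.0, 3.0],
        ]
    )
    return ExpressionMatrix(values, ["c1", "c2", "c3"], ["gA", "gB", "gC", "gD"])


@pytest.fixture(scope="session")
def linear_fixture():
    """The standard linear 3-stage fixture at its default parameters."""
    return simulate_linear(seed=7)
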