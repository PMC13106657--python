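import numpy as np
import pytest

from topconnmf import ExpressionMatrix, generate_timecourse


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expression(rng) -> ExpressionMatrix:
    """A tiny valid two-class expression matrix (8 samples x 12 features)."""
    g, s = 8, 12
    values = rng.random((g, s)) + 0.1
    return ExpressionMatrix(
        values=values,
        feature_ids=[f"f{j}" for j in range(s)],
        sample_class=["control", "diseased"] * (g // 2),
        sample_time=np.repeat([0, 1], g // 2),
    )


@pytest.fixture(scope="session")
def default_timecourse():
    """The default synthetic time-course fixture with its ground truth."""
    return generate_timecourse(seed=2024)
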