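import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from eracv.model import BlockSpec, ModelSpec, Term


@pytest.fixture
def two_block_spec():
    """Two blocks of two predictors each, linear terms only."""
    bs = BlockSpec([("a", (0, 1)), ("b", (2, 3))])
    return ModelSpec(bs, [Term("linear", "a"), Term("linear", "b")])


@pytest.fixture
def single_pred_spec():
    """Two one-predictor blocks: ERA degenerates to OLS."""
    bs = BlockSpec([("a", (0,)), ("b", (1,))])
    return ModelSpec(bs, [Term("linear", "a"), Term("linear", "b")])


@pytest.fixture
def make_data():
    """Factory for random regression data with a planted linear signal."""

    def _make(n=50, p=4, seed=0, noise=1.0, coef=None):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        if coef is None:
            coef = rng.standard_normal(p) * 0.4
        y = X @ coef + noise * rng.standard_normal(n)
        return X, y

    return _make
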