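import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from pcafe import ExpressionMatrix, normalize_samples
from pcafe.data_io import CASE, CONTROL


def labelled_matrix(values, n_case, n_control, prefix="F"):
    """Wrap a raw array as a labelled ExpressionMatrix (cases first)."""
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    assert s == n_case + n_control
    labels = np.array([CASE] * n_case + [CONTROL] * n_control, dtype=object)
    return ExpressionMatrix(
        values,
        [f"{prefix}{i:05d}" for i in range(n)],
        [f"S{j:03d}" for j in range(s)],
        labels=labels,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def normalized_matrix(rng):
    """Random normalized 100 x 20 matrix, 10 cases vs 10 controls."""
    return normalize_samples(labelled_matrix(rng.normal(size=(100, 20)), 10, 10))
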