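import numpy as np
import pytest

from sfssclass.datatypes import ExpressionMatrix


@pytest.fixture
def two_feature_matrix() -> ExpressionMatrix:
    """2 features x 4 samples, two classes of two; hand-checkable."""
    return ExpressionMatrix(
        ["f1", "f2"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1.0, 3.0, 5.0, 7.0], [2.0, 6.0, 4.0, 4.0]]),
        scale="log2",
        labels={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )


@pytest.fixture
def three_class_matrix() -> ExpressionMatrix:
    """2 features x 6 samples, three classes of two; hand-checkable."""
    return ExpressionMatrix(
        ["f1", "f2"],
        [f"s{i}" for i in range(1, 7)],
        np.array([[0.0, 2.0, 4.0, 6.0, 8.0, 10.0], [3.0, 5.0, 1.0, 3.0, 2.0, 4.0]]),
        scale="log2",
        labels={"s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "C", "s6": "C"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
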