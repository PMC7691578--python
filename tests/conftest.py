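import numpy as np
import pytest

from evosel.expression import ExpressionMatrix, LabelVector, Scale
from evosel.simulate import ExpressionSimDesign, simulate_expression


@pytest.fixture
def tiny_counts():
    """2 features x 3 samples counts matrix with easy arithmetic."""
    return ExpressionMatrix(
        ["fA", "fB"],
        ["s1", "s2", "s3"],
        np.array([[999.0, 0.0, 10.0], [999001.0, 1000.0, 90.0]]),
        Scale.counts,
    )


@pytest.fixture
def small_classes():
    """Separable 3-class dataset: 12 features, 60 samples, 2 informative/class."""
    design = ExpressionSimDesign(
        n_classes=3,
        samples_per_class=20,
        n_features=12,
        informative_per_class=2,
        effect_delta=3.0,
        seed=7,
    )
    return simulate_expression(design)


@pytest.fixture
def labels_ab():
    def make(n_a, n_b):
        ids = [f"s{i}" for i in range(n_a + n_b)]
        return LabelVector(ids, ["A"] * n_a + ["B"] * n_b)

    return make
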