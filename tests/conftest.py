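import numpy as np
import pytest

from possireg.data import DesignMatrix
from possireg.synthetic import GeneratorConfig, generate


@pytest.fixture
def make_design():
    """Factory building a DesignMatrix from named predictor columns and y."""

    def _make(predictors: dict[str, np.ndarray], y, response_name: str = "y") -> DesignMatrix:
        y = np.asarray(y, dtype=float)
        cols = ["Intercept", *predictors]
        X = np.column_stack([np.ones(len(y))] + [np.asarray(v, float) for v in predictors.values()])
        return DesignMatrix(
            columns=tuple(cols),
            X=X,
            y=y,
            response_name=response_name,
            groups={name: (name,) for name in predictors},
        )

    return _make


@pytest.fixture
def cohort20():
    """A 20-patient synthetic cohort with all blood-pressure levels present."""
    table = generate(GeneratorConfig(n=20, seed=42))
    assert set(table.data["BloodPressure"]) == {0, 1, 2}
    return table
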