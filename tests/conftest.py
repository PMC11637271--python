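import numpy as np
import pandas as pd
import pytest

from hernia_cea import LifeTable, default_parameters


@pytest.fixture(scope="session")
def params():
    """Shipped base-case parameterization (shared, read-only)."""
    return default_parameters()


@pytest.fixture()
def params_mut(params):
    """A deep copy safe to mutate within a test."""
    return params.copy()


@pytest.fixture(scope="session")
def zero_mortality_lt():
    """Life table with no background mortality (ex column only satisfies schema)."""
    ages = np.arange(18, 91, 5)
    return LifeTable(pd.DataFrame({"age": ages, "q": 0.0, "ex": 100.0 - ages}))


def annuity(rate: float, horizon: int, timing: str = "end") -> float:
    """Closed-form discounted annuity used as an independent oracle."""
    offset = {"start": 1.0, "mid": 0.5, "end": 0.0}[timing]
    return sum((1.0 + rate) ** (-(t - offset)) for t in range(1, horizon + 1))
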