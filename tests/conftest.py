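import numpy as np
import pandas as pd
import pytest

from interomics import OmicsLayer, generate_cohort

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced five-condition cohort used across module tests."""
    return generate_cohort(
        {"Control": 40, "FGR": 12, "FGR+HDP": 12, "PE": 20, "PTD": 20}, seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_layer(values, name="layer", kind="abundance", prefix="a"):
    """Wrap a 2-d array as an OmicsLayer with generated ids."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    df = pd.DataFrame(
        values,
        index=[f"S{i:03d}" for i in range(n)],
        columns=[f"{prefix}{j:03d}" for j in range(m)],
    )
    return OmicsLayer(name, df, kind)
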