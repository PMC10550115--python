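import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Project-wide seed for seeded stochastic tests.
SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def make_liver(coords, colours, liver_id="L001", fates=None):
    """Build a labelled-cell table from explicit coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    if fates is None:
        fates = ["unknown"] * n
    return pd.DataFrame(
        {
            "liver_id": liver_id,
            "cell_id": np.arange(n),
            "x_um": coords[:, 0],
            "y_um": coords[:, 1],
            "z_um": coords[:, 2],
            "colour": list(colours),
            "fate": list(fates),
        }
    )


@pytest.fixture
def liver_factory():
    return make_liver
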