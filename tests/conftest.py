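import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exact_4pl_series():
    """Noiseless 8-dose series from (bottom=0.2, top=1.0, ec50=300 nM, hill=1.5)."""
    from gbmscreen.dose_response import DoseResponseSeries, four_pl

    doses = 11.2 * 2.0 ** np.arange(8)
    v = four_pl(doses, 0.2, 1.0, 300.0, 1.5)
    return DoseResponseSeries("L001", "JQ1", doses, tuple(np.array([x, x, x]) for x in v))


@pytest.fixture
def sham_grid():
    """A drug combined with itself, each combination arm at half dose."""
    import pandas as pd

    from gbmscreen.synergy import CombinationGrid

    doses = np.array([25.0, 50.0, 100.0, 200.0, 400.0])
    dm, m = 100.0, 1.4
    fa = (doses / dm) ** m / (1.0 + (doses / dm) ** m)
    rows = pd.DataFrame(
        {
            "d1": np.concatenate([doses, np.zeros(5), doses / 2]),
            "d2": np.concatenate([np.zeros(5), doses, doses / 2]),
            "fa": np.concatenate([fa, fa, fa]),
        }
    )
    return CombinationGrid("drugA", "drugA-copy", 1.0, rows)
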