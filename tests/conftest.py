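import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lopforget.design import EXP1_DESIGN, GenerativeParams
from lopforget.simulate import simulate_study


@pytest.fixture(scope="session")
def exp1_trials() -> pd.DataFrame:
    """One simulated run of the 2 x 3 within-participant design."""
    return simulate_study(EXP1_DESIGN, GenerativeParams(seed=7))


@pytest.fixture(scope="session")
def splitplot_toy() -> pd.DataFrame:
    """Balanced 3-group x 2-level split-plot data, 12 subjects, fixed values.

    Small integers so every stratum sum of squares can be recomputed by hand
    from the textbook split-plot formulas.
    """
    rng = np.random.default_rng(42)
    rows = []
    for g, group in enumerate(["g1", "g2", "g3"]):
        for s in range(4):
            pid = f"{group}_s{s}"
            base = rng.integers(0, 5)
            for l, level in enumerate(["deep", "shallow"]):
                rows.append(
                    {
                        "participant_id": pid,
                        "delay_group": group,
                        "lop_condition": level,
                        "d_prime": float(base + g + 2 * l + rng.integers(0, 3)),
                    }
                )
    return pd.DataFrame(rows)
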