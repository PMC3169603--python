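import numpy as np
import pandas as pd
import pytest

from perffields.stats import arcsine_transform

LOCATIONS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cells(values_by_unit_loc, value_col="transformed"):
    """Accuracy-cell table from {(observer, distractor): {location: value}}."""
    rows = []
    for (obs, dist), by_loc in values_by_unit_loc.items():
        for loc, v in by_loc.items():
            rows.append(
                {
                    "observer_id": obs,
                    "distractor_tilt_deg": dist,
                    "target_location": loc,
                    value_col: v,
                }
            )
    return pd.DataFrame(rows)


def binomial_cells(rng, p_by_loc, n_per_cell, n_observers=4, distractors=(0.0, -45.0)):
    """Simulated transformed accuracies: binomial draws per unit x location."""
    rows = []
    for o in range(n_observers):
        for d in distractors:
            for loc in LOCATIONS:
                k = rng.binomial(n_per_cell, p_by_loc[loc])
                rows.append(
                    {
                        "observer_id": f"o{o}",
                        "distractor_tilt_deg": d,
                        "target_location": loc,
                        "transformed": arcsine_transform(k / n_per_cell),
                    }
                )
    return pd.DataFrame(rows)
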