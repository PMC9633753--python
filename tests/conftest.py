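import numpy as np
import pandas as pd
import pytest

from facediet.nutrition import DENSITY_NUTRIENTS, FoodCompositionTable
from facediet.synthio import CohortSpec, generate_cohort


def make_table(rows: dict[str, dict]) -> FoodCompositionTable:
    """Minimal composition table: every density defaults to zero."""
    base = {
        "portion_size_g": 100.0, "oil_class": "none", "is_cooking": False,
        "is_grain": False, "is_vegetable": False,
        "is_deep_yellow_vegetable": False, "is_animal_protein": False,
        **{n: 0.0 for n in DENSITY_NUTRIENTS},
    }
    frame = pd.DataFrame.from_dict(
        {name: {**base, **overrides} for name, overrides in rows.items()},
        orient="index",
    )
    frame.index.name = "item"
    return FoodCompositionTable(frame)


@pytest.fixture(scope="session")
def cohort60():
    """One mid-sized synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortSpec(n_subjects=60, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
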