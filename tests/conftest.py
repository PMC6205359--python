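import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pollsel as ps

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> ps.StudyTable:
    """One paper-scale cohort from the default scenario."""
    return ps.simulate_cohort(ps.default_config(), seed=42)


@pytest.fixture(scope="session")
def default_gradients(default_cohort) -> pd.DataFrame:
    return ps.estimate_gradients(default_cohort)


@pytest.fixture()
def toy_table() -> ps.StudyTable:
    """Small 2-population balanced table for unit tests (32 rows)."""
    rng = np.random.default_rng(7)
    rows = []
    i = 0
    for pop in ("A", "B"):
        for morph in ("L", "S"):
            for trt in ("C", "HP"):
                for _ in range(4):
                    rows.append(
                        {
                            "individual_id": f"id{i:03d}",
                            "population": pop,
                            "morph": morph,
                            "treatment": trt,
                            "flowering_onset": float(rng.integers(150, 165)),
                            "plant_height": round(30 + 5 * rng.standard_normal(), 1),
                            "n_flowers": float(rng.integers(5, 25)),
                            "corolla_tube_length": round(9 + rng.standard_normal(), 2),
                            "corolla_tube_width": round(3.3 + 0.3 * rng.standard_normal(), 2),
                            "fruit_production": float(rng.integers(0, 5)),
                            "seeds_per_fruit": round(float(rng.uniform(40, 110)), 1),
                            "female_fitness": round(float(rng.uniform(0, 1500)), 1),
                        }
                    )
                    i += 1
    return ps.StudyTable(pd.DataFrame(rows))
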