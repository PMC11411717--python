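import numpy as np
import pandas as pd
import pytest

from expolong import synth
from expolong.tables import FeatureTable


@pytest.fixture(scope="session")
def small_design():
    return synth.CohortDesign(seed=42, n_individuals=12, n_visits=4, n_batches=3)


@pytest.fixture(scope="session")
def small_panel():
    return synth.default_panel(20, 10, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_design, small_panel):
    return synth.generate_cohort(small_design, small_panel)


def random_two_mode_table(seed: int, n_base: int = 400, n_planted: int = 100) -> FeatureTable:
    """A random two-mode feature table with some cross-mode near-matches:
    planted partners get an adjusted-mass delta in ±0.003 Da and an RT
    delta in ±0.3 min, straddling the dedup tolerances."""
    rng = np.random.default_rng(seed)
    rows, areas = [], []
    for i in range(n_base):
        rows.append(
            {
                "feature_id": f"B{i:04d}",
                "mode": "ESI+" if rng.random() < 0.5 else "ESI-",
                "mz": rng.uniform(100, 700),
                "rt": rng.uniform(0.5, 16),
            }
        )
        areas.append(10 ** rng.normal(5, 0.5, size=8))
    for i in range(n_planted):
        src = rows[rng.integers(0, n_base)]
        other = "ESI-" if src["mode"] == "ESI+" else "ESI+"
        adj = src["mz"] + (-1 if src["mode"] == "ESI+" else 1) * 1.007276
        delta = rng.uniform(-0.003, 0.003)
        mz = adj + delta + (1 if other == "ESI+" else -1) * 1.007276
        rows.append(
            {
                "feature_id": f"T{i:04d}",
                "mode": other,
                "mz": mz,
                "rt": src["rt"] + rng.uniform(-0.3, 0.3),
            }
        )
        areas.append(10 ** rng.normal(5, 0.5, size=8))
    features = pd.DataFrame(rows).set_index("feature_id")
    features["rt"] = features["rt"].clip(lower=0.1)
    area_frame = pd.DataFrame(
        np.array(areas), index=features.index, columns=[f"S{j}" for j in range(8)]
    )
    return FeatureTable(features, area_frame)
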