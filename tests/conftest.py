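import numpy as np
import pandas as pd
import pytest

from phylloside.simulate import StudyDesign, simulate_study
from phylloside.tables import CountTable, SampleSheet, rarefy


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(("t1", "t2"), ("s1", "s2"), np.array([[3, 0], [1, 2]]))


@pytest.fixture
def toy_sheet() -> SampleSheet:
    rows = []
    for sp in ("oak", "fern"):
        for ind in (0, 1, 2):
            for side in ("upper", "lower"):
                rows.append(
                    {
                        "sample_id": f"{sp}{ind}_{side}",
                        "plant_species": sp,
                        "plant_individual": f"{sp}{ind}",
                        "leaf_side": side,
                        "ph": 6.0 + (0.2 if side == "upper" else 0.0),
                        "stomatal_density": 1.0 if side == "upper" else 120.0,
                        "latitude": 37.87 + ind * 1e-4,
                        "longitude": -122.23 + ind * 1e-4,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_study():
    """Reduced-frame simulated study shared across unit tests (speed)."""
    design = StudyDesign(
        n_species=8, n_individuals_per_species=3, n_taxa=150,
        reads_per_sample=6000, seed=3,
    )
    return simulate_study(design)


@pytest.fixture(scope="session")
def small_study_rarefied(small_study):
    table, sheet, truth = small_study
    rare, _ = rarefy(table, depth=2000, seed=1)
    sheet_r = SampleSheet(sheet.aligned_to(rare.sample_ids).reset_index(drop=True))
    return rare, sheet_r, truth
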