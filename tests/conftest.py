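import numpy as np
import pandas as pd
import pytest

import doseqtl as dq


@pytest.fixture(scope="session")
def small_map():
    """5 chromosomes x 50 cM at 5 cM spacing: 11 markers each, 55 total."""
    return dq.make_marker_map([50.0] * 5, 5.0)


@pytest.fixture(scope="session")
def small_panel(small_map):
    """200 segregants on the small map."""
    return dq.simulate_genotypes(small_map, 200, seed=11)


@pytest.fixture(scope="session")
def study_panel():
    """Study-scale panel: 1008 segregants, 16 x 100 cM at 2 cM (816 markers)."""
    mm = dq.make_marker_map([100.0] * 16, 2.0)
    return dq.simulate_genotypes(mm, 1008, seed=23)


@pytest.fixture(scope="session")
def study_architecture(study_panel):
    return dq.study_architecture(study_panel.markers)


def make_phenotype_table(strains, radii, dose, replicate=1, layout="A"):
    """Single-replicate long-format phenotype table from raw values."""
    return pd.DataFrame(
        {
            "strain": np.asarray(strains, dtype=object),
            "dose_uM": float(dose),
            "replicate": replicate,
            "layout": layout,
            "radius": np.asarray(radii, dtype=float),
        }
    )
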