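import numpy as np
import pandas as pd
import pytest

from dsbfold.proteome import QuantitativeProteome
from dsbfold.synthetic import SyntheticSpec, ground_truth_condition


@pytest.fixture(scope="session")
def gt_condition():
    """One seeded ground-truth kinetic condition shared across tests."""
    return ground_truth_condition(SyntheticSpec(seed=11))


@pytest.fixture()
def small_proteome():
    """Hand-built proteome: DsbA at 696 ppm of 1e6 total copies."""
    abundances = pd.Series(
        {
            "P0AEG4": 696.0,  # DsbA
            "P0AEG6": 144.0,  # DsbC
            "P77202": 27.0,  # DsbG
            "FILLER": 1e6 - 696.0 - 144.0 - 27.0,
        }
    )
    return QuantitativeProteome(
        condition_label="glucose", abundances=abundances, growth_rate=0.58
    )


@pytest.fixture()
def bond_frame():
    def make(rows):
        return pd.DataFrame(rows, columns=["protein_id", "cys_a", "cys_b"])

    return make
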