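import numpy as np
import pandas as pd
import pytest

import coagcomp as cc


@pytest.fixture
def complement_panel():
    """Two patients over the 8 complement analytes, already normalized:
    patient 1 has every activator at its column max (1) and every inhibitor
    at 0; patient 2 the reverse of activators (0.5) and inhibitors at max."""
    return pd.DataFrame(
        {
            "C3a": [1.0, 0.5],
            "C4a": [1.0, 0.5],
            "C5a": [1.0, 0.5],
            "MASP2": [1.0, 0.5],
            "C7": [1.0, 0.5],
            "C1q": [0.0, 1.0],
            "FI": [0.0, 1.0],
            "C4": [0.0, 1.0],
        }
    )


@pytest.fixture
def cohort2_small():
    return cc.gen_cohort2(n_patients=112, seed=7)


@pytest.fixture
def cohort3_small():
    return cc.gen_cohort3(n_patients=2025, seed=7)


@pytest.fixture
def panel_columns(cohort2_small):
    return [c for c in cohort2_small.columns if c in cc.DEFAULT_CATALOG]
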