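import numpy as np
import pandas as pd
import pytest

from lipscreen import synthetic_data as sd
from lipscreen.image_quant import SegmentationParams


@pytest.fixture
def small_layout():
    return sd.make_plate_layout(100, 20, seed=1, plate_id="T01")


@pytest.fixture
def noiseless_params():
    return sd.ImagingParams(noise_sd=0.0, rng_seed=7)


@pytest.fixture
def default_params():
    return sd.ImagingParams(rng_seed=7)


@pytest.fixture
def noiseless_seg():
    # no smoothing: in a noise-free image smoothing only spreads support
    return SegmentationParams(smoothing_radius=0.0)


def make_truth_row(
    row=0, col=0, cells=10, quench=0.0, toxicity=1.0, density=4.0, role="compound"
):
    return pd.Series(
        {
            "row": row,
            "col": col,
            "role": role,
            "compound_id": "CPD00001" if role == "compound" else None,
            "true_cell_count": cells,
            "quench_fraction": quench,
            "toxicity_factor": toxicity,
            "droplet_density": density,
        }
    )


@pytest.fixture
def truth_row():
    return make_truth_row()
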