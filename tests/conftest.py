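import numpy as np
import pytest

from rgcspeed import stimuli as st
from rgcspeed import synthetic_retina as sr

TABLE_SPEEDS = np.array([0.25, 0.5, 1.0, 2.0, 4.0])


@pytest.fixture(scope="session")
def small_grating():
    return st.make_drifting_grating(1.8, 1.0, duration=3.0, size_px=32)


@pytest.fixture(scope="session")
def small_checkerboard():
    # 60 s at block resolution: enough spikes for coarse STA checks.
    return st.make_checkerboard(duration=60.0, upsample=False, seed=11)


@pytest.fixture(scope="session")
def long_checkerboard():
    # Full-length reverse-correlation run at block resolution (35 x 35).
    return st.make_checkerboard(duration=1200.0, upsample=False, seed=5)


@pytest.fixture(scope="session")
def single_cell_population():
    pop = sr.make_ground_truth_population(
        n_cells=1, field_size=35 / 20.0, rf_radius_mean=0.12,
        rf_radius_sd=0.0, baseline_rate=1.0, gain=60.0, seed=2,
    )
    pop[0].center_xy = (0.9, 0.8)
    return pop


@pytest.fixture(scope="session")
def tuned_cell():
    return sr.GroundTruthCell(
        cell_id=0, center_xy=(0.5, 0.5), a=0.05, b=0.05, angle=0.0,
        polarity=-1, temporal_params=(1.0, 0.5, 4.0, 7.0, 5.0),
        baseline_rate=0.5, gain=30.0, tuning_params=(20.0, 1.0, 1.2, 0.1),
    )


@pytest.fixture(scope="session")
def grating_conditions():
    return [
        {"kind": "grating", "sf0": 1.0, "speed": float(v)}
        for v in TABLE_SPEEDS
    ]
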