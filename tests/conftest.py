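import numpy as np
import pytest

from rilate import EventModel, ThermalFrameStack, table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture()
def small_stack():
    """Tiny hand-built stack: 3 frames of 6x5 grids, band rows 2..3."""
    rng = np.random.default_rng(1234)
    frames = 20.0 + rng.uniform(0, 5, size=(3, 6, 5))
    frames[:, 2:4, :] = 90.0  # branch band is hot
    return ThermalFrameStack(
        frames=frames,
        timestamps_s=np.array([0.0, 0.5, 1.0]),
        calibration_um=100.0,
        branch_band=(2, 3),
        column_roi=(0, 4),
    )


@pytest.fixture()
def noiseless_model():
    """Deterministic sealing event with known closed-form extents."""
    return EventModel(noise_sd=0.0, frontier_sd=0.0, seed=11)
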