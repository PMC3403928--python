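import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from popmarker import SimulationGrid, SingleCellModel


@pytest.fixture(scope="session")
def decay_model() -> SingleCellModel:
    """Scalar exponential decay dx/dt = -k x, x(0) = x0."""
    return SingleCellModel(
        name="decay",
        state_names=["x"],
        parameter_names=["k", "x0"],
        rhs=lambda x, p: np.array([-p[0] * x[0]]),
        initial_map=lambda p: np.array([p[1]]),
    )


@pytest.fixture(scope="session")
def turnover_model() -> SingleCellModel:
    """Linear production/degradation dx/dt = ks - kd x."""
    return SingleCellModel(
        name="turnover",
        state_names=["x"],
        parameter_names=["ks", "kd"],
        rhs=lambda x, p: np.array([p[0] - p[1] * x[0]]),
        initial_map=lambda p: np.array([0.0]),
    )


@pytest.fixture(scope="session")
def fine_grid() -> SimulationGrid:
    return SimulationGrid(t_end=1.0, n_points=101, rel_tol=1e-10, abs_tol=1e-12)
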