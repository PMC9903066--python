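import numpy as np
import pytest
from hypothesis import settings

import teerkit as tk

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid():
    return tk.default_frequency_grid()


@pytest.fixture(scope="session")
def small_grid():
    return tk.make_frequency_grid(1e3, 1e6, 13)


@pytest.fixture(scope="session")
def chip_params():
    return tk.ChipCircuitParams(r_series=25_000.0, r_barrier=2_000.0, q_cpe=1e-8, alpha=0.85)


@pytest.fixture(scope="session")
def parasitics():
    return tk.ParasiticParams(r_lead=100.0, c_par=100e-12)


@pytest.fixture()
def noiseless_model(grid, parasitics):
    """Error model estimated from noiseless boards through the parasitics."""
    comp = tk.simulate_compensation_boards(parasitics, grid=grid)
    return tk.estimate_error_model(comp)
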