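import numpy as np
import pytest

from rbflow.model import (
    TAC,
    ContinuousCurve,
    KineticParams,
    default_grid,
    frame_average,
    tissue_curve,
)
from rbflow.qa import gamma_variate
from rbflow.synthetic import SyntheticStudyConfig, _bolus_with_recirc


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def bolus_curve(grid):
    """Nominal arterial bolus with recirculation plateau, 0.1 s sampling."""
    t = np.arange(0, grid.end + 1e-9, 0.1)
    return ContinuousCurve(0.1, _bolus_with_recirc(t, 100.0, 5.0, 3.0, 8.0, 0.15, 40.0))


@pytest.fixture(scope="session")
def bolus_tac(grid, bolus_curve):
    return frame_average(bolus_curve, grid)


@pytest.fixture(scope="session")
def tissue_tac(grid, bolus_curve):
    """Noise-free tissue response, K1 = 0.6, DV = 1.0."""
    return frame_average(tissue_curve(KineticParams(k1=0.6, dv=1.0), bolus_curve), grid)


@pytest.fixture
def clean_config():
    """Model-consistent noise-free study: no noise, jitter, RV spillover or delay."""
    return SyntheticStudyConfig(
        n_sectors=32,
        noise=0.0,
        jitter_cv=0.0,
        bolus_jitter_cv=0.0,
        beta_scan_jitter_sd=0.0,
        rvbv_septal=0.0,
        transport_delay_s=0.0,
    )
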