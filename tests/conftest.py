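import numpy as np
import pytest

from secophen.data_io import CaseControlDataset
from secophen.simulate import SimulationParams, calibrate_gamma0, simulate_case_control

LOG2 = float(np.log(2.0))
LOG15 = float(np.log(1.5))

# frozen 12-subject dataset used by the brute-force and grid-search oracles
FIX12_X = np.array([0, 1, 2, 0, 1, 2, 0, 1, 1, 2, 0, 0])
FIX12_D = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
FIX12_Y = np.array(
    [0.82, -0.31, 1.24, 0.05, 1.91, 2.13, -0.54, 0.37, 1.02, 0.66, -1.20, 0.11]
)


@pytest.fixture(scope="session")
def fixture12() -> CaseControlDataset:
    return CaseControlDataset(
        d=FIX12_D, y=FIX12_Y, x=FIX12_X, level_values=np.array([0.0, 1.0, 2.0])
    )


def paper_params(beta1=0.0, gamma1=0.0, gamma2=LOG2, rate=0.05, seed=None, **kw):
    """Simulation settings used throughout: beta0 = sigma2 = 1, MAF 0.3."""
    return SimulationParams(
        beta0=1.0, beta1=beta1, sigma2=1.0, gamma1=gamma1, gamma2=gamma2,
        maf=0.3, target_rate=rate, seed=seed, **kw,
    )


@pytest.fixture(scope="session")
def null_dataset():
    """One dataset simulated under the global null (beta1 = gamma1 = 0)."""
    p = paper_params(seed=101)
    return simulate_case_control(p.with_gamma0(calibrate_gamma0(p)))


@pytest.fixture(scope="session")
def alt_dataset():
    """One dataset at the alternative (beta1 = -0.12, gamma1 = log 1.5)."""
    p = paper_params(beta1=-0.12, gamma1=LOG15, seed=202)
    return simulate_case_control(p.with_gamma0(calibrate_gamma0(p)))
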