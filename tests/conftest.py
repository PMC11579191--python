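import numpy as np
import pytest

from multidose import DoseRegimen, PBFTPKRegimen, PKParameters, make_equidose


@pytest.fixture
def oral_params() -> PKParameters:
    """Oral kinetics used throughout the worked examples:
    ka=0.42/h, ke=0.4/h, gamma=0.00449/mL."""
    return PKParameters(ka=0.42, ke=0.4, gamma=0.00449)


@pytest.fixture
def flipflop_params() -> PKParameters:
    """Flip-flop ordering: absorption slower than elimination."""
    return PKParameters(ka=0.2, ke=0.8, gamma=0.003)


@pytest.fixture
def irregular_bolus_regimen() -> DoseRegimen:
    """Irregular IV bolus schedule: delta=[600,600,700,500,400,300] mg/mL,
    tau=[4,4,8,4,6,4] h."""
    return DoseRegimen((4, 4, 8, 4, 6, 4), (600, 600, 700, 500, 400, 300))


@pytest.fixture
def irregular_fat_regimen() -> PBFTPKRegimen:
    """Irregular finite-absorption schedule: d=[600,600,400,700] mg,
    tau=[6,4,5,5] h, absorption cutoff 2 h after each dose."""
    return PBFTPKRegimen(DoseRegimen((6, 4, 5, 5), (600, 600, 400, 700)), (2, 2, 2, 2))


@pytest.fixture
def equi_fat_regimen() -> PBFTPKRegimen:
    """Equi-dose finite-absorption schedule: 600 mg every 5 h, 2 h absorption."""
    return PBFTPKRegimen.equidose(600, 5, 2, 8)


def max_rel_dev(a: np.ndarray, b: np.ndarray) -> float:
    """Max |a-b| scaled by the trajectory's own magnitude."""
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-300)
    return float(np.max(np.abs(np.asarray(a) - np.asarray(b))) / scale)
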