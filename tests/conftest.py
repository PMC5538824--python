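import numpy as np
import pytest

from cabuffer import synthetic_data as sd
from cabuffer.chem_equilibrium import SolutionComposition
from cabuffer.fura_calibration import CalibrationResult


@pytest.fixture(scope="session")
def cal() -> CalibrationResult:
    """The simulator's rig calibration (Kd_eff = 2.5 uM)."""
    return sd.DEFAULT_CALIBRATION


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def r_def_recipe() -> SolutionComposition:
    """The defined-Ca2+ calibration solution (totals in mM, pH 7.2)."""
    return SolutionComposition(
        compounds={
            "KCl": 129.5,
            "KOH": 13.0,
            "NaCl": 10.3,
            "NaOH": 4.7,
            "MgCl2": 1.0,
            "HEPES": 5.0,
            "EGTA": 4.0,
            "CaCl2": 2.7,
            "fura-2": 0.05,
        },
        ph=7.2,
        temperature_c=22.0,
    )
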