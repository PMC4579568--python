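import numpy as np
import pytest

from dyneinflex import LatticeParams, MechanicalParams, MotorGeometry


@pytest.fixture(scope="session")
def geom() -> MotorGeometry:
    return MotorGeometry()


@pytest.fixture(scope="session")
def mech() -> MechanicalParams:
    return MechanicalParams()


@pytest.fixture(scope="session")
def mech_no_tether() -> MechanicalParams:
    return MechanicalParams(tether_stiffness=0.0)


@pytest.fixture(scope="session")
def lattice() -> LatticeParams:
    return LatticeParams()


def block_se(x: np.ndarray, block: int = 100) -> float:
    """Standard error of the mean of a (possibly autocorrelated) sample,
    estimated from the scatter of non-overlapping block means."""
    x = np.asarray(x, dtype=float)
    nb = x.size // block
    means = x[: nb * block].reshape(nb, block).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))
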