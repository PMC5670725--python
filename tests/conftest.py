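import numpy as np
import pytest

from itvsim import (
    AcquisitionConfig,
    MotionTrajectory,
    PhantomSpec,
    rasterize_phantom,
    simulate_phase_stack,
)


@pytest.fixture(scope="session")
def static_spec() -> PhantomSpec:
    """Grid sized for the motionless default phantom."""
    return PhantomSpec.for_motion(MotionTrajectory(amplitude_si=0.0))


@pytest.fixture(scope="session")
def static_image(static_spec):
    return rasterize_phantom(static_spec)


@pytest.fixture(scope="session")
def stack_a10():
    """Phase-sorted stack of the 1 cm amplitude (2 cm range) phantom."""
    traj = MotionTrajectory(amplitude_si=1.0)
    spec = PhantomSpec.for_motion(traj)
    return simulate_phase_stack(spec, traj, AcquisitionConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20170915)
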