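import numpy as np
import pytest

from stalkpull.trace_io import PullTrace

# published mean trajectory, used as a convenient known curve in tests
TRAJ = (-0.0028, 0.3989, 2.4187)


def q(theta):
    a, b, c = TRAJ
    theta = np.asarray(theta, dtype=float)
    return a * theta**2 + b * theta + c


def make_trace(plant_id="P1", scale=1.0, break_angle=None, step=5.0, metadata=None):
    """Noiseless trace following the known quadratic, optionally broken."""
    angles = np.arange(0.0, 90.0 + 0.5 * step, step)
    if break_angle is not None:
        angles = angles[angles <= break_angle]
    forces = scale * q(angles)
    if break_angle is not None:
        angles = np.append(angles, break_angle)
        forces = np.append(forces, 0.4 * forces.max())
    return PullTrace(
        plant_id=plant_id,
        angle_deg=angles,
        force_N=forces,
        displacement_cm=1.3 * angles,
        metadata=metadata or {},
    )


@pytest.fixture
def baseline_trace():
    return make_trace()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
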