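import numpy as np
import pytest

from eelflume.synthetic import default_camera_rig


@pytest.fixture(scope="session")
def rig():
    """Three synthetic pinhole cameras with exact DLT coefficients."""
    return default_camera_rig()


@pytest.fixture(scope="session")
def flume_points():
    """Non-coplanar calibration points spanning the working volume."""
    return np.array(
        [[x, y, z] for x in (-0.06, 0.0, 0.06) for y in (-0.06, 0.06)
         for z in (0.02, 0.10, 0.18)]
    )
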