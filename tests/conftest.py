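import numpy as np
import pytest

import popgrad as pg


@pytest.fixture
def kernels():
    return pg.KernelParams()


@pytest.fixture
def escape():
    return pg.EscapeParams()


@pytest.fixture
def toy_setup():
    """Small system with appreciable firing: 3 afferents, 20-step grid."""
    ker = pg.KernelParams()
    esc = pg.EscapeParams(rho0=0.05, theta=0.3, delta_u=0.3, dt=1.0)
    pat = pg.generate_frozen_pattern(3, 250.0, 20.0, seed=42)
    w = np.array([0.4, -0.2, 0.3])
    return ker, esc, pat, w
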