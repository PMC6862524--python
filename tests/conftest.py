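import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aggfold.model import BOMBININ_H2
from aggfold.synthetic import build_bent_conformer, build_ideal_helix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ideal_helix():
    return build_ideal_helix(BOMBININ_H2)


@pytest.fixture(scope="session")
def bent_conformer(ideal_helix):
    return build_bent_conformer(ideal_helix, (10, 11), 120.0)


@pytest.fixture(scope="session")
def extended_chain():
    """Fully extended chain (phi=-120, psi=+120): no helical content."""
    from aggfold.synthetic import _add_o_cb, _build_backbone
    from aggfold.trajectory import Conformation

    n = len(BOMBININ_H2)
    phi = np.full(n, -120.0)
    psi = np.full(n, 120.0)
    omega = np.full(n, 180.0)
    backbone = _build_backbone(n, phi, psi, omega)
    return Conformation(BOMBININ_H2, _add_o_cb(backbone, psi))
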