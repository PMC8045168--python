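import numpy as np
import pytest

from acroplan import synthetic_anatomy as sa


@pytest.fixture(scope="session")
def cylinder():
    """Solid circular cylinder r=5, L=40 along +z, with landmarks."""
    return sa.make_solid_cylinder(5.0, 40.0, n_ring=128)


@pytest.fixture(scope="session")
def elliptic_rod():
    """Solid elliptic rod a=8, b=4, L=40 along +z, with landmarks."""
    return sa.make_elliptic_rod(8.0, 4.0, 40.0, n_ring=96)


@pytest.fixture(scope="session")
def acromion_subject():
    """One deterministic synthetic acromion with ground truth."""
    params = sa.AcromionParams(seed=3, hint_downdip_err_deg=3.0, hint_medlat_err_deg=-5.0)
    return sa.generate_acromion(params)


@pytest.fixture(scope="session")
def curved_rod():
    """Curved solid rod (60 deg arc) without taper/tilt frills: breach-test shape."""
    params = sa.AcromionParams(
        a_distal=6.0, b_distal=3.5, length=36.0, arc_angle_deg=60.0,
        taper=0.0, alpha_tilt_deg=2.0, noise_amp=0.02, seed=0,
        n_ring=48, n_sections=36)
    return sa.generate_acromion(params)
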