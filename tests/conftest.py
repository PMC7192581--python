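import numpy as np
import pytest

import spherotfm as sp


@pytest.fixture(scope="session")
def collagen12():
    return sp.get_preset("collagen-1.2")


@pytest.fixture(scope="session")
def table_2k():
    """Shared reduced lookup (1-2000 Pa) with accumulated curves."""
    return sp.build_lookup(n=40, p_min=1.0, p_max=2000.0)


@pytest.fixture(scope="session")
def default_scene():
    """Reference bead scene at the experimental imaging conditions."""
    return sp.generate_scene(seed=3)


@pytest.fixture(scope="session")
def profile_500(collagen12):
    """Simulated equilibrium at 500 Pa, default domain."""
    return sp.solve_contraction(500.0, sp.SphericalDomain(), collagen12)
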