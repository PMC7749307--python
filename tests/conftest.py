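import numpy as np
import pytest

from nempol.collisions import CollisionRuleParams, build_collision_table, default_kernel_prefactor
from nempol.mode_system import ModelParams, table_for

SIGMA = 0.2


@pytest.fixture(scope="session")
def prefactor():
    return default_kernel_prefactor()


@pytest.fixture(scope="session")
def table_psi0(prefactor):
    """Collision table of the purely nematic rule (psi=0) at sigma=0.2."""
    return build_collision_table(
        10, CollisionRuleParams(psi=0.0, sigma_c=SIGMA, kernel_prefactor=prefactor))


@pytest.fixture(scope="session")
def table_bias(prefactor):
    """Collision table at moderate polar bias psi = 0.075 pi."""
    return build_collision_table(
        10, CollisionRuleParams(psi=0.075 * np.pi, sigma_c=SIGMA,
                                kernel_prefactor=prefactor))


@pytest.fixture(scope="session")
def table_polar(prefactor):
    """Collision table of the fully polar rule (psi = pi/2)."""
    return build_collision_table(
        10, CollisionRuleParams(psi=np.pi / 2, sigma_c=SIGMA,
                                kernel_prefactor=prefactor))


def make_params(rho_bar, psi=0.0, kc=10, sigma=SIGMA):
    return ModelParams(rho_bar=rho_bar, sigma=sigma, psi=psi, kc=kc)
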