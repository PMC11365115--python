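"""Shared (session-scoped) SCFT results: these are the expensive solves
reused by the membrane-property and acceptance tests."""

import pytest

from rimpore.scft import ChainModel
from rimpore.membrane import (
    bending_modulus,
    line_tension,
    tensionless_bilayer,
)

TWO_D_OVER_D = 2.75  # membrane separation in thickness units


@pytest.fixture(scope="session")
def chain_default():
    return ChainModel()  # f = 0.8, chiN = 30, alpha = 0.1, ds = 0.005


@pytest.fixture(scope="session")
def flat_default(chain_default):
    """Tensionless flat bilayer at the default parameters."""
    return tensionless_bilayer(chain_default)


@pytest.fixture(scope="session")
def kappa_fit(chain_default, flat_default):
    """Bending modulus with its curvature-fit diagnostics."""
    return bending_modulus(chain_default, flat_default, return_fit=True)


@pytest.fixture(scope="session")
def chain_2d():
    return ChainModel(contour_step=0.01)


@pytest.fixture(scope="session")
def flat_2d(chain_2d):
    """Flat reference at the contour step used by the 2D cross-sections."""
    return tensionless_bilayer(chain_2d)


@pytest.fixture(scope="session")
def line_tensions_default(chain_2d, flat_2d):
    """The three line tensions at f=0.8, chiN=30, 2d = 2.75 D."""
    d = TWO_D_OVER_D * flat_2d.D / 2.0
    out = {}
    for kind, dd in (("e", 0.0), ("h", d), ("p", d)):
        out[kind] = line_tension(kind, chain_2d, dd, flat=flat_2d)
    out["d"] = d
    return out
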