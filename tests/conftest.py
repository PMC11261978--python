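"""Shared fixtures: the typical-cell parameter medians at 1 uM background."""

import numpy as np
import pytest

from chemosense import (KinaseParams, PhysicalConstants, SwimSignalParams)

KD_ROUNDED = 1.2e5


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants(kD=KD_ROUNDED)


@pytest.fixture(scope="session")
def kinase_1uM():
    """Population-median kinase parameters at a 1 uM background."""
    return KinaseParams(G_r=2.28 / KD_ROUNDED, tau_2=7.4, tau_1=0.0,
                        D_n=8.1e-4, tau_n=8.7, a0=0.3)


@pytest.fixture(scope="session")
def swim_1uM():
    """Population-median swimming statistics, shallow gradient, 1 uM."""
    return SwimSignalParams(sigma_v2=146.0, tau_v=1.19, P_run=0.85,
                            g=0.05, c0=1.0)


def gamma_r_to_g(gamma_r, sigma_v2=146.0, tau_v=1.19, r0=KD_ROUNDED):
    """Gradient steepness (1/mm) that yields a requested arrival SNR."""
    g_um = np.sqrt(gamma_r / (2.0 * r0 * sigma_v2 * tau_v ** 3))
    return g_um * 1e3
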