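"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from coopfold import itc_binding as itc
from coopfold.saxs_analysis import debye_profile
from coopfold.synthetic_data import (
    make_globular_body,
    make_rigid_plus_tail_system,
    make_toy_structures,
)


@pytest.fixture(scope="session")
def sphere_body():
    """2000 beads uniform in a 20 A sphere (seeded)."""
    return make_globular_body(20.0, 2000, seed=11)


@pytest.fixture(scope="session")
def sphere_profile(sphere_body):
    q = np.linspace(0.005, 0.3, 120)
    return debye_profile(sphere_body, q)


@pytest.fixture(scope="session")
def analytic_sphere_profile():
    """Noise-free analytic sphere form factor, R = 20 A, out to qRg ~ 7.7."""
    from coopfold.saxs_analysis.profiles import ScatteringProfile

    radius = 20.0
    q = np.linspace(0.002, 0.5, 800)
    qr = q * radius
    i = (3.0 * (np.sin(qr) - qr * np.cos(qr)) / qr**3) ** 2
    return ScatteringProfile(q=q, i=i), radius


@pytest.fixture(scope="session")
def tail_system():
    """Rigid body + 22-bead tails, 50 conformers, noisy 0.7/0.3 mixture."""
    return make_rigid_plus_tail_system(
        body_radius=15.0, n_body=80, n_tail=22, n_conformers=50, seed=5
    )


@pytest.fixture(scope="session")
def toy_structures():
    return make_toy_structures(seed=3)


@pytest.fixture()
def wild_type_protocol():
    """Desk-scale protocol at fittable steepness (K_A * A^2 ~ 100)."""
    return itc.TitrationProtocol(
        cell_volume_ul=200.0,
        cell_conc=1.8e-6,
        syringe_conc=8.6e-6,
        injection_volumes_ul=(2.0,) * 25,
    )
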