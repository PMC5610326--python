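"""Vertical (edge-lining) monolayer region: reference cylinder, boundary
conditions, mode structure, belt-rim director, and agreement with the
independent discretized-functional minimization (which keeps the lateral
stretch beta as a free field)."""

import numpy as np
import pytest

from poredge.discretized import minimize_monolayer_fd
from poredge.monolayer import (
    belt_director,
    equilibrium_cylinder,
    monolayer_energy,
    solve_monolayer,
)
from poredge.parameters import default_environment, get_lipid

ENV = default_environment()


@pytest.mark.parametrize(
    "h, R_v, M_v",
    [(2.0, 2.0, 3.0), (1.45, 1.45, 2.175), (2.0, 1e6, 1e6 + 2.0 - 2e-6)],
)
def test_equilibrium_cylinder(h, R_v, M_v):
    lipid = get_lipid("reference").with_(h=h)
    assert equilibrium_cylinder(lipid, R_v) == pytest.approx(M_v, rel=1e-9)


def test_equilibrium_cylinder_rejects_thin_cylinder():
    lipid = get_lipid("reference")
    with pytest.raises(ValueError):
        equilibrium_cylinder(lipid, 0.9)  # R_v <= h/2


def test_belt_director_values():
    assert belt_director(0.0, 2.0) == 0.0
    assert belt_director(1e-9, 2.0) == pytest.approx(0.0, abs=1e-8)
    assert belt_director(1.25, 2.0) == pytest.approx(-0.857493, abs=1e-5)
    assert belt_director(2.0, 2.0) == pytest.approx(-1.0)


def test_boundary_conditions_and_beta():
    lipid = get_lipid("reference")
    r, R0, Z0, v0 = 1.0, 2.2, 1.6, -0.7
    sol = solve_monolayer(lipid, ENV, r, 0.0, R0, Z0, v0)
    assert sol.v(0.0) == pytest.approx(0.0, abs=1e-9)
    assert sol.R(0.0) == pytest.approx(r, abs=1e-9)
    assert sol.v(Z0) == pytest.approx(v0, abs=1e-9)
    assert sol.R(Z0) == pytest.approx(R0, abs=1e-9)
    z = np.linspace(0, Z0, 20)
    assert np.all(sol.beta(z) == 0.0)


def test_mode_structure_four_real_dof():
    lipid = get_lipid("reference")
    sol = solve_monolayer(lipid, ENV, 1.3, 0.0, 2.3, 1.9, -0.6)
    assert sol.system.n_real == 4
    # exponents come in sign-symmetric (complex) pairs
    qs = sorted(abs(q) for q in sol.system.qs)
    assert qs[0] == pytest.approx(qs[-1], rel=1e-8)


def test_large_radius_limit_is_bare_cylinder():
    # with matching boundary data the wall stays an undeformed cylinder as
    # r -> infinity, and the energy reduces to the bare equatorial splay
    lipid = get_lipid("reference")
    r = 400.0
    Z0 = lipid.h
    sol = solve_monolayer(lipid, ENV, r, 0.0, r + 1e-9, Z0, 0.0)
    z = np.linspace(0, Z0, 30)
    assert np.max(np.abs(sol.v(z))) < 5e-3
    assert np.max(np.abs(sol.u(z))) < 5e-3
    bare = 4 * np.pi * r * (lipid.B / 2) * (1 / r) ** 2 * Z0
    assert monolayer_energy(sol) == pytest.approx(bare, rel=0.05)


def test_hydrophobic_continuously_matches_hydrophilic_at_vanishing_belt():
    lipid = get_lipid("reference")
    r, R0, Z0, v0 = 0.8, 1.7, 1.7, -0.55
    W0 = monolayer_energy(solve_monolayer(lipid, ENV, r, 0.0, R0, Z0, v0))
    WL = monolayer_energy(
        solve_monolayer(lipid, ENV, r, 1e-3, R0, Z0, v0, mode="hydrophobic")
    )
    assert abs(WL - W0) < 0.1


@pytest.mark.parametrize(
    "name, r, L, R0, Z0, v0",
    [
        ("reference", 1.0, 0.0, 2.2, 1.6, -0.7),
        ("reference", 2.0, 0.0, 2.6, 1.5, -0.5),
        ("reference", 0.675, 1.2, 1.1, 1.9, -0.8),
        ("DOPC", 1.5, 0.0, 2.3, 1.2, -0.5),
    ],
)
def test_agrees_with_discretized_functional(name, r, L, R0, Z0, v0):
    lipid = get_lipid(name)
    mode = "hydrophilic" if L == 0.0 else "hydrophobic"
    sol = solve_monolayer(lipid, ENV, r, L, R0, Z0, v0, mode=mode)
    W = monolayer_energy(sol)
    fd = minimize_monolayer_fd(lipid, ENV, r, L, R0, Z0, v0, mode=mode)
    assert W == pytest.approx(fd.energy, rel=0.01)
    # beta vanishes at the discretized minimum without being imposed
    assert np.max(np.abs(fd.beta)) < 1e-8
    # field agreement within 1% of amplitude
    idx = slice(0, len(fd.z), 101)
    assert np.allclose(sol.v(fd.z[idx]), fd.v[idx], atol=0.01 * max(np.max(np.abs(fd.v)), 0.1))
    assert np.allclose(sol.u(fd.z[idx]), fd.u[idx], atol=0.01 * max(np.max(np.abs(fd.u)), 0.1))


def test_energy_components_sum():
    lipid = get_lipid("reference")
    sol = solve_monolayer(lipid, ENV, 1.0, 0.0, 2.2, 1.6, -0.7)
    W, comps = monolayer_energy(sol, components=True)
    assert W == pytest.approx(sum(comps.values()), abs=1e-9)
    assert comps["stretch"] == 0.0  # beta == 0 exactly
    assert comps["tension"] == 0.0  # sigma0 = 0


def test_geometry_validation():
    lipid = get_lipid("reference")
    with pytest.raises(ValueError):
        solve_monolayer(lipid, ENV, 1.0, 0.5, 2.0, 1.6, -0.7, mode="hydrophilic")
    with pytest.raises(ValueError):
        solve_monolayer(lipid, ENV, 1.0, 2.5, 2.0, 3.0, -0.7, mode="hydrophobic")
    with pytest.raises(ValueError):
        solve_monolayer(lipid, ENV, 1.0, 0.0, 2.0, 0.0, -0.7)
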