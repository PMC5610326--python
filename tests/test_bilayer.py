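"""Horizontal (quasi-flat) bilayer region: characteristic roots, decaying
solutions, and agreement with the independent discretized-functional
minimization."""

import numpy as np
import pytest

from poredge.bilayer import bilayer_energy, characteristic_roots, solve_bilayer
from poredge.discretized import minimize_bilayer_fd
from poredge.parameters import available_lipids, default_environment, get_lipid

ENV = default_environment()


def quartic_residual(lipid, p, sigma=0.0):
    h2, l2, A, s = lipid.h**2, lipid.l2, lipid.A, 1.0 + sigma
    return s * h2 * (A * h2 + 4 * l2) * p**4 - 4 * (A * (h2 - l2) - sigma * h2) * p**2 + 4 * A


@pytest.mark.parametrize("name", ["reference", "DOPC", "POPC", "DMPC", "reference_h3"])
def test_roots_complex_pair_and_on_quartic(name):
    lipid = get_lipid(name)
    p1, p2 = characteristic_roots(lipid, 0.0)
    # inner discriminant is negative for physical lipids: conjugate-related pair
    assert abs(p1.imag) > 1e-6 and abs(p2.imag) > 1e-6
    assert p1**2 == pytest.approx(np.conj(p2**2), rel=1e-12)
    scale = abs(quartic_residual(lipid, 0.0)) + 1.0
    assert abs(quartic_residual(lipid, p1)) / scale < 1e-10
    assert abs(quartic_residual(lipid, p2)) / scale < 1e-10


def test_undeformed_state_is_trivial():
    lipid = get_lipid("reference")
    sol = solve_bilayer(lipid, ENV, R0=2.0, Z0=lipid.h, n0=0.0)
    rho = np.linspace(2.0, 20.0, 50)
    assert np.allclose(sol.n(rho), 0.0, atol=1e-12)
    assert np.allclose(sol.alpha(rho), 0.0, atol=1e-12)
    assert np.allclose(sol.H(rho), lipid.h, atol=1e-12)
    assert bilayer_energy(sol) == pytest.approx(0.0, abs=1e-12)


def test_boundary_conditions_and_decay():
    lipid = get_lipid("reference")
    R0, Z0, n0 = 2.0, 1.8, -0.3
    sol = solve_bilayer(lipid, ENV, R0, Z0, n0)
    assert sol.n(R0) == pytest.approx(n0, abs=1e-9)
    assert sol.H(R0) == pytest.approx(Z0, abs=1e-9)
    # fields are real and decay toward the flat state
    assert abs(sol.n(R0 + 20.0)) < 1e-2
    assert abs(sol.n(R0 + 40.0)) < 1e-4
    assert sol.H(R0 + 40.0) == pytest.approx(lipid.h, abs=1e-4)


def test_envelope_decays():
    lipid = get_lipid("reference")
    sol = solve_bilayer(lipid, ENV, 2.0, 1.8, -0.3)
    rho = np.linspace(2.0, 42.0, 4000)
    n = np.abs(sol.n(rho))
    # local maxima of |n| (the oscillation envelope) strictly decrease
    idx = [i for i in range(1, len(n) - 1) if n[i] >= n[i - 1] and n[i] >= n[i + 1]]
    peaks = n[idx]
    assert len(peaks) >= 3
    assert np.all(np.diff(peaks) < 0)


@pytest.mark.parametrize(
    "name, R0, Z0, n0",
    [
        ("reference", 2.0, 1.8, -0.3),
        ("reference", 3.0, 2.1, 0.45),
        ("DOPC", 2.2, 1.3, 0.5),  # J0 != 0 exercises the linear splay term
        ("DMPC", 1.5, 1.2, 0.35),
    ],
)
def test_agrees_with_discretized_functional(name, R0, Z0, n0):
    lipid = get_lipid(name)
    sol = solve_bilayer(lipid, ENV, R0, Z0, n0)
    W = bilayer_energy(sol)
    fd = minimize_bilayer_fd(lipid, ENV, R0, Z0, n0)
    assert W == pytest.approx(fd.energy, rel=0.01)
    # pointwise field agreement within 1% of the amplitude
    idx = slice(0, len(fd.rho), 117)
    scale = np.max(np.abs(fd.n))
    assert np.allclose(sol.n(fd.rho[idx]), fd.n[idx], atol=0.01 * scale)


def test_energy_quadratic_form_psd_at_zero_spontaneous_curvature():
    lipid = get_lipid("reference")
    h = lipid.h

    def W(n0, dz):
        return bilayer_energy(solve_bilayer(lipid, ENV, 2.0, h + dz, n0))

    e = 0.1
    q11 = W(e, 0.0) / e**2
    q22 = W(0.0, e) / e**2
    q12 = (W(e, e) - W(e, 0.0) - W(0.0, e)) / (2 * e * e)
    M = np.array([[q11, q12], [q12, q22]])
    assert np.all(np.linalg.eigvalsh(M) > 0)


def test_invalid_inputs():
    lipid = get_lipid("reference")
    with pytest.raises(ValueError):
        solve_bilayer(lipid, ENV, R0=-1.0, Z0=2.0, n0=0.1)
    with pytest.raises(ValueError):
        solve_bilayer(lipid, ENV, R0=2.0, Z0=2.0, n0=1.5)
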