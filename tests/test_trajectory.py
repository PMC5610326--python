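"""Trajectory scans, landscape features, line-tension curve, and the
classical thin-film relations."""

import numpy as np
import pytest

from poredge.parameters import default_environment, get_lipid, line_tension_to_pN
from poredge.trajectory import (
    classical_energy,
    closure_rate,
    critical_radius,
    optimal_trajectory,
    scan_belt_height,
)

ENV = default_environment()


def test_gamma_equals_energy_over_perimeter(reference_landscape):
    for p in reference_landscape.points[::7]:
        assert p.gamma == pytest.approx(
            line_tension_to_pN(p.W / (2 * np.pi * p.r)), rel=1e-12
        )
        assert (p.regime == "hydrophilic") == (p.L_optimal == 0.0)


def test_trajectory_is_continuous(reference_landscape):
    r, W, _, _ = reference_landscape.as_arrays()
    dW = np.abs(np.diff(W)) / np.diff(r)
    assert np.max(dW) < 120.0  # bounded slope, no jumps


def test_small_radius_hydrophobic_branch_is_quadratic(reference_landscape):
    r, W, _, L = reference_landscape.as_arrays()
    sel = (r <= 0.4) & (L > 0)
    assert np.sum(sel) >= 4
    coef = np.polyfit(r[sel], W[sel], 2)
    resid = W[sel] - np.polyval(coef, r[sel])
    ss = 1 - np.sum(resid**2) / np.sum((W[sel] - W[sel].mean()) ** 2)
    assert ss > 0.99


def test_large_radius_branch_is_linear(lipid_trajectories):
    for traj in lipid_trajectories.values():
        r, W, g, _ = traj.as_arrays()
        sel = r >= 15.0
        coef = np.polyfit(r[sel], W[sel], 1)
        resid = W[sel] - np.polyval(coef, r[sel])
        ss = 1 - np.sum(resid**2) / np.sum((W[sel] - W[sel].mean()) ** 2)
        assert ss > 0.999
        # gamma saturates: last two grid values within 5%
        assert abs(g[-1] - g[-2]) / g[-1] < 0.05


def test_belt_scan_two_minima_near_transition(degeneracy_scan):
    r_eq, scan = degeneracy_scan
    assert 0.5 < r_eq < 0.9
    assert len(scan.minima) >= 2
    (L1, W1), (L2, W2) = scan.minima[0], scan.minima[1]
    assert L1 < 0.3  # hydrophilic-side minimum at (nearly) vanishing belt
    assert 0.8 < L2 < 1.6  # hydrophobic-defect minimum
    assert abs(W1 - W2) < 0.5  # degenerate by construction of r_eq
    assert scan.barrier is not None and 0.2 < scan.barrier < 4.5


def test_belt_scan_insensitive_to_grid_refinement():
    lipid = get_lipid("reference")
    h = lipid.h
    coarse = scan_belt_height(lipid, ENV, 0.675, L_grid=np.arange(0, 0.951 * h, 0.1))
    fine = scan_belt_height(lipid, ENV, 0.675, L_grid=np.arange(0, 0.951 * h, 0.05))
    Lc = max(coarse.minima, key=lambda m: m[0])[0]
    Lf = max(fine.minima, key=lambda m: m[0])[0]
    assert abs(Lc - Lf) < 0.05  # refined minima move by less than step/2


def test_belt_height_shrinks_with_radius(reference_landscape):
    r, _, _, L = reference_landscape.as_arrays()
    hydrophobic = L > 0
    # optimal belt exists only below the transition and its height grows as
    # the pore shrinks toward the intact bilayer
    assert r[hydrophobic].max() < 0.8
    small = L[np.isclose(r, 0.1)][0]
    large = L[np.isclose(r, 0.6)][0]
    assert small > large


def test_metastable_minimum_location(reference_landscape):
    f = reference_landscape.features
    assert f.r_metastable is not None
    assert 1.5 < f.r_metastable < 2.5
    assert f.barrier_forward > f.barrier_reverse > 0


def test_spontaneous_curvature_lowers_gamma0(env):
    # positive monolayer spontaneous curvature relaxes the dominant
    # meridional splay of the rim: gamma0 decreases with J0, with a spread
    # of ~12.5 pN between J0 = -0.1 and +0.1 nm^-1
    r_grid = np.array([20.0, 30.0, 40.0, 50.0])
    g0 = {}
    for name in ("reference_J0-0.1", "reference", "reference_J0+0.1"):
        g0[name] = optimal_trajectory(get_lipid(name), env, r_grid).features.gamma0
    assert g0["reference_J0-0.1"] > g0["reference"] > g0["reference_J0+0.1"]
    assert g0["reference_J0-0.1"] - g0["reference_J0+0.1"] == pytest.approx(
        12.5, rel=0.25
    )


def test_gamma0_scaling_with_splay_modulus_and_thickness(env):
    # gamma0 scales roughly with B/h: equal-B/h lipids lie much closer to
    # the reference than a lipid with B scaled by 1.5 at fixed h
    r_grid = np.array([20.0, 30.0, 40.0, 50.0])
    g0 = {}
    for name in ("reference", "reference_B5.3_h1.3", "reference_B12_h3",
                 "reference_B12"):
        g0[name] = optimal_trajectory(get_lipid(name), env, r_grid).features.gamma0
    ref = g0["reference"]
    dB = abs(g0["reference_B12"] - ref)
    assert abs(g0["reference_B5.3_h1.3"] - ref) < 0.5 * dB
    assert abs(g0["reference_B12_h3"] - ref) < 0.5 * dB
    # scaling B alone scales gamma0 roughly proportionally
    assert 1.25 < g0["reference_B12"] / ref < 1.75


def test_xi_h_shifts_transition_slightly(env):
    r_grid = np.arange(0.3, 1.21, 0.05)
    lipid = get_lipid("reference")
    envs = {x: default_environment(xi_h_nm=x) for x in (1.0, 1.5)}
    feats = {}
    for x, e in envs.items():
        traj = optimal_trajectory(lipid, e, r_grid, belt_scan_rmax=1.0, L_step=0.15)
        feats[x] = traj.features
    shift = feats[1.5].r_transition - feats[1.0].r_transition
    assert 0.0 < shift < 0.3  # about +0.1 nm
    # barriers are weakly sensitive to the hydrophobic decay length
    rel = abs(feats[1.5].barrier_forward - feats[1.0].barrier_forward)
    rel /= feats[1.0].barrier_forward
    assert rel < 0.10


# ---------------------------------------------------------------------------
# classical relations & closure rate
# ---------------------------------------------------------------------------


def test_critical_radius():
    assert critical_radius(11.0, 7.0) == pytest.approx(1.571, abs=0.01)
    assert critical_radius(20.0, 10.0) == pytest.approx(2.0)
    assert np.isinf(critical_radius(10.0, 0.0))
    with pytest.raises(ValueError):
        critical_radius(-1.0, 5.0)


def test_classical_energy_linear_at_zero_tension():
    r = np.linspace(0.5, 5, 10)
    E = classical_energy(r, 10.0, 0.0)
    assert np.allclose(E / r, E[0] / r[0])
    # with tension, maximum at r* = gamma/sigma0
    E2 = classical_energy(r, 10.0, 5.0)
    istar = np.argmax(E2)
    assert r[istar] == pytest.approx(2.0, abs=0.5)


def test_closure_rate_constant_gamma():
    r = np.linspace(0.5, 5, 20)
    v = closure_rate(r, 10.0, eta_Pa_s=1.0, h_nm=2.0)
    assert np.allclose(v, -1e-3 * 10.0 / 8.0)


def test_closure_rate_recovers_constant_speed_solution():
    # gamma(r) = 4 V h eta + C / r  gives dr/dt = -V for all r
    V, eta, h, C = 2.0, 1.0, 2.0, 5.0
    r = np.linspace(0.5, 10, 400)
    gamma = 4 * V * h * eta * 1e3 + C / r  # pN units; 1e3 converts back
    v = closure_rate(r, gamma, eta, h)
    assert np.allclose(v[5:-5], -V, rtol=1e-3)


def test_closure_rate_spline_derivative_matches_finite_differences():
    r = np.linspace(1.0, 10, 200)
    gamma = 10 + 3 * np.exp(-r) + 0.5 * r
    v = closure_rate(r, gamma, 1.0, 2.0)
    dgdr = np.gradient(gamma, r)
    v_fd = -1e-3 * (gamma + r * dgdr) / 8.0
    assert np.allclose(v[2:-2], v_fd[2:-2], rtol=0.01)
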