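"""Pore-formation trajectory: optimal belt height, energy landscape,
line tension, and the classical pore-energy relations.

The pore state is described by two generalized coordinates: the waist
radius r and the belt half-height L.  For each r the energy is minimized
over L (the junction circle being optimized at every evaluation), which
yields the optimal trajectory W(r), the line tension gamma(r) =
W(r)/(2 pi r), and the landscape features: the hydrophobic-to-hydrophilic
transition radius (maximum of W), the metastable hydrophilic pore
(local minimum of W at a few nm), the barriers between these states, and
the large-radius asymptote gamma_0 of the line tension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import EnergyBreakdown, optimize_junction
from .parameters import (
    EnvironmentParameters,
    LipidParameters,
    line_tension_to_pN,
    tension_to_internal,
)

__all__ = [
    "TrajectoryPoint",
    "BeltScan",
    "LandscapeFeatures",
    "TrajectoryResult",
    "scan_belt_height",
    "optimal_at_radius",
    "optimal_trajectory",
    "line_tension_curve",
    "equal_energy_radius",
    "classical_energy",
    "critical_radius",
    "closure_rate",
]


@dataclass
class TrajectoryPoint:
    r: float  # nm
    L_optimal: float  # nm
    regime: str  # "hydrophobic" | "hydrophilic"
    W: float  # k_BT
    gamma: float  # pN
    breakdown: EnergyBreakdown = field(repr=False, default=None)


@dataclass
class BeltScan:
    """Junction-optimized W as a function of belt half-height L at fixed r."""

    r: float
    L: np.ndarray
    W: np.ndarray
    minima: list  # [(L_min, W_min)], refined, ascending in L
    barrier: float | None  # barrier between the two lowest minima, k_BT

    @property
    def L_optimal(self) -> float:
        return min(self.minima, key=lambda m: m[1])[0]


@dataclass
class LandscapeFeatures:
    r_transition: float | None = None  # argmax of W(r), nm
    W_transition: float | None = None
    barrier_forward: float | None = None  # W(max) - W(r->0), k_BT
    r_metastable: float | None = None
    W_metastable: float | None = None
    barrier_reverse: float | None = None  # W(max) - W(metastable)
    depth_metastable: float | None = None  # alias of barrier_reverse
    gamma0: float | None = None  # large-r asymptote from the W(r) slope, pN
    gamma0_at_rmax: float | None = None  # gamma at the largest radius, pN
    gamma_min: float | None = None  # min of gamma over hydrophilic branch, pN
    r_at_gamma_min: float | None = None


@dataclass
class TrajectoryResult:
    lipid: LipidParameters
    env: EnvironmentParameters
    points: list  # [TrajectoryPoint]
    features: LandscapeFeatures

    def as_arrays(self):
        r = np.array([p.r for p in self.points])
        W = np.array([p.W for p in self.points])
        g = np.array([p.gamma for p in self.points])
        L = np.array([p.L_optimal for p in self.points])
        return r, W, g, L


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


class _Warm:
    """Warm-start cache of junction geometries along a scan."""

    def __init__(self):
        self.geo = {}

    def init_for(self, key, r, L):
        g = self.geo.get(key)
        if g is None:
            return None
        dR, Z0 = g
        return (r + dR, max(Z0, L + 1e-3))

    def store(self, key, bd):
        self.geo[key] = (bd.geometry.R0 - bd.geometry.r, bd.geometry.Z0)


def _optimize(lipid, env, r, L, warm: _Warm | None, key):
    init = warm.init_for(key, r, L) if warm is not None else None
    bd = optimize_junction(lipid, env, r, L, init=init)
    if warm is not None and np.isfinite(bd.W_total):
        warm.store(key, bd)
    return bd


def scan_belt_height(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    r: float,
    L_grid=None,
    refine: bool = True,
) -> BeltScan:
    """W(L) at fixed radius, with junction optimization at every L.

    Returns all local minima (the hydrophilic state L = 0 and, where
    present, the hydrophobic-defect state at finite L) with parabolic
    refinement, and the barrier separating the two lowest minima.
    """
    h = lipid.h
    if L_grid is None:
        L_grid = np.arange(0.0, 0.951 * h, 0.05)
    L_grid = np.asarray(L_grid, dtype=float)
    if L_grid[0] != 0.0:
        raise ValueError("L_grid must include L = 0")
    warm = _Warm()
    W = np.empty_like(L_grid)
    for i, L in enumerate(L_grid):
        W[i] = _optimize(lipid, env, r, float(L), warm, "scan").W_total

    minima = []
    n = len(L_grid)
    for i in range(n):
        left = W[i - 1] if i > 0 else np.inf
        right = W[i + 1] if i < n - 1 else np.inf
        if W[i] <= left and W[i] <= right:
            Lm, Wm = float(L_grid[i]), float(W[i])
            if refine and 0 < i < n - 1:
                # parabolic vertex, then one true evaluation there
                dL = L_grid[i + 1] - L_grid[i]
                denom = W[i - 1] - 2 * W[i] + W[i + 1]
                if denom > 0:
                    Lv = L_grid[i] + 0.5 * dL * (W[i - 1] - W[i + 1]) / denom
                    Lv = float(np.clip(Lv, L_grid[i - 1], L_grid[i + 1]))
                    Wv = _optimize(lipid, env, r, Lv, warm, "scan").W_total
                    if Wv < Wm:
                        Lm, Wm = Lv, float(Wv)
            minima.append((Lm, Wm))
    minima.sort()
    barrier = None
    if len(minima) >= 2:
        (L1, W1), (L2, W2) = minima[0], minima[1]
        sel = (L_grid >= L1) & (L_grid <= L2)
        ridge = float(np.max(W[sel]))
        barrier = ridge - max(W1, W2)
    return BeltScan(r=r, L=L_grid, W=W, minima=minima, barrier=barrier)


def optimal_at_radius(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    r: float,
    L_step: float = 0.1,
    scan_belt: bool = True,
    warm: _Warm | None = None,
) -> TrajectoryPoint:
    """Energy minimized over the belt height at fixed radius."""
    if warm is None:
        warm = _Warm()
    bd_phil = _optimize(lipid, env, r, 0.0, warm, "phil")
    best_bd, best_L = bd_phil, 0.0
    if scan_belt:
        h = lipid.h
        grid = np.arange(L_step, 0.981 * h, L_step)
        Ws = []
        for L in grid:
            bd = _optimize(lipid, env, r, float(L), warm, "belt")
            Ws.append(bd.W_total)
            if bd.W_total < best_bd.W_total:
                best_bd, best_L = bd, float(L)
        # parabolic refinement around an interior belt minimum
        Ws = np.array(Ws)
        if best_L > 0 and len(Ws) >= 3:
            i = int(np.argmin(Ws))
            if 0 < i < len(grid) - 1:
                denom = Ws[i - 1] - 2 * Ws[i] + Ws[i + 1]
                if denom > 0:
                    Lv = grid[i] + 0.5 * L_step * (Ws[i - 1] - Ws[i + 1]) / denom
                    bd = _optimize(lipid, env, r, float(Lv), warm, "belt")
                    if bd.W_total < best_bd.W_total:
                        best_bd, best_L = bd, float(Lv)
    gamma = line_tension_to_pN(best_bd.W_total / (2.0 * np.pi * r))
    regime = "hydrophilic" if best_L == 0.0 else "hydrophobic"
    return TrajectoryPoint(
        r=r, L_optimal=best_L, regime=regime, W=best_bd.W_total,
        gamma=gamma, breakdown=best_bd,
    )


def default_r_grid(r_max: float = 50.0) -> np.ndarray:
    """Radius grid, dense through the transition/metastable region."""
    parts = [
        np.arange(0.05, 0.80, 0.05),
        np.arange(0.80, 4.001, 0.10),
        np.arange(4.5, 10.01, 0.5),
        np.array([12.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0]),
    ]
    g = np.concatenate(parts)
    return g[g <= r_max + 1e-9]


def optimal_trajectory(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    r_grid=None,
    belt_scan_rmax: float | None = None,
    L_step: float = 0.1,
) -> TrajectoryResult:
    """Optimal pore-formation trajectory W(r) with landscape features.

    The belt height is scanned for r up to ``belt_scan_rmax`` (default:
    the monolayer thickness); beyond that the defect branch is far above
    the hydrophilic one and L = 0 is used directly.
    """
    if r_grid is None:
        r_grid = default_r_grid()
    r_grid = np.asarray(sorted(r_grid), dtype=float)
    if belt_scan_rmax is None:
        belt_scan_rmax = max(1.0, 0.55 * lipid.h)
    warm = _Warm()
    points = []
    for r in r_grid:
        points.append(
            optimal_at_radius(
                lipid, env, float(r), L_step=L_step,
                scan_belt=(r <= belt_scan_rmax), warm=warm,
            )
        )
    features = _extract_features(lipid, env, points, warm)
    return TrajectoryResult(lipid=lipid, env=env, points=points, features=features)


def _parabolic_vertex(x, y, i):
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return x[i], y[i]
    dx = 0.5 * (x[i + 1] - x[i - 1]) / 2.0
    xv = x[i] - 0.5 * ((x[i + 1] - x[i - 1]) / 2.0) * (y[i + 1] - y[i - 1]) / denom
    # general non-uniform fit
    X = np.array([x[i - 1], x[i], x[i + 1]])
    c = np.polyfit(X, [y[i - 1], y[i], y[i + 1]], 2)
    if c[0] != 0:
        xv = -c[1] / (2 * c[0])
        if X[0] <= xv <= X[2]:
            return float(xv), float(np.polyval(c, xv))
    return float(x[i]), float(y[i])


def _extract_features(lipid, env, points, warm) -> LandscapeFeatures:
    f = LandscapeFeatures()
    r = np.array([p.r for p in points])
    W = np.array([p.W for p in points])
    g = np.array([p.gamma for p in points])

    # transition: genuine local maximum of W on the small-r part
    small = r <= min(4.0, r.max())
    idx = np.where(small)[0]
    if len(idx) >= 3:
        i = idx[np.argmax(W[idx])]
        if 0 < i < len(r) - 1 and W[i] >= W[i - 1] and W[i] >= W[i + 1]:
            rv, Wv = _parabolic_vertex(r, W, i)
            f.r_transition, f.W_transition = rv, Wv
            f.barrier_forward = Wv  # intact bilayer reference W(0) = 0
    # metastable: local minimum beyond the transition
    if f.r_transition is not None:
        for i in range(1, len(r) - 1):
            if r[i] <= f.r_transition:
                continue
            if W[i] <= W[i - 1] and W[i] <= W[i + 1]:
                rv, Wv = _parabolic_vertex(r, W, i)
                depth = f.W_transition - Wv
                if depth > 0.25:  # quadrature noise floor
                    f.r_metastable, f.W_metastable = rv, Wv
                    f.barrier_reverse = depth
                    f.depth_metastable = depth
                break
    # gamma minimum over the hydrophilic branch
    mask = np.array([p.regime == "hydrophilic" for p in points])
    if f.r_transition is not None:
        mask &= r > f.r_transition
    hi = np.where(mask)[0]
    if len(hi) >= 3:
        j = hi[np.argmin(g[hi])]
        if hi[0] < j < hi[-1]:
            rv, gv = _parabolic_vertex(r, g, j)
            f.gamma_min, f.r_at_gamma_min = gv, rv
        else:
            f.gamma_min, f.r_at_gamma_min = float(g[j]), float(r[j])
    # asymptotic line tension from the slope of W(r) over the top range
    fit = r >= min(20.0, 0.4 * r.max())
    if np.sum(fit) >= 3:
        slope = np.polyfit(r[fit], W[fit], 1)[0]
        f.gamma0 = line_tension_to_pN(slope / (2.0 * np.pi))
        f.gamma0_at_rmax = float(g[-1])
    return f


def line_tension_curve(points):
    """(r, gamma_pN) arrays from trajectory points."""
    r = np.array([p.r for p in points])
    g = np.array([p.gamma for p in points])
    return r, g


def equal_energy_radius(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    bracket=(0.5, 0.9),
    xtol: float = 1e-3,
):
    """Radius where the hydrophilic pore and hydrophobic defect are
    degenerate (the two minima of W(L) have equal energies), plus the
    belt-height scan at that radius.

    Returns (r_eq, BeltScan).
    """
    from scipy.optimize import brentq

    warm = _Warm()

    def defect_minimum(r):
        h = lipid.h
        best = None
        for L in np.arange(0.5 * h, 0.981 * h, 0.05):
            bd = _optimize(lipid, env, r, float(L), warm, "defect")
            if best is None or bd.W_total < best:
                best = bd.W_total
        return best

    def diff(r):
        Wp = _optimize(lipid, env, r, 0.0, warm, "phil").W_total
        return Wp - defect_minimum(r)

    r_eq = brentq(diff, *bracket, xtol=xtol)
    scan = scan_belt_height(lipid, env, float(r_eq))
    return float(r_eq), scan


# ---------------------------------------------------------------------------
# classical (thin-film) relations and closure dynamics
# ---------------------------------------------------------------------------


def classical_energy(r_nm, gamma_pN: float, sigma0_mN_per_m: float = 0.0):
    """Thin-film pore energy E(r) = 2 pi r gamma - pi r^2 sigma0, k_BT.

    Accepts a constant gamma (classical model) or an array matching r
    (generalized, radius-dependent line tension).
    """
    from .parameters import pN_to_line_tension

    r = np.asarray(r_nm, dtype=float)
    gam = pN_to_line_tension(np.asarray(gamma_pN, dtype=float))
    sig = tension_to_internal(sigma0_mN_per_m)
    E = 2.0 * np.pi * r * gam - np.pi * r * r * sig
    return E if E.shape else float(E)


def critical_radius(gamma_pN: float, sigma0_mN_per_m: float) -> float:
    """Classical critical radius r* = gamma / sigma0, nm.

    Infinite (returned as ``inf``) at zero lateral tension.
    """
    if gamma_pN < 0 or sigma0_mN_per_m < 0:
        raise ValueError("gamma and sigma0 must be non-negative")
    if sigma0_mN_per_m == 0.0:
        return float("inf")
    # pN / (mN/m) = 1e-12 N / (1e-3 N/m) = 1e-9 m = 1 nm
    return gamma_pN / sigma0_mN_per_m


def closure_rate(r_nm, gamma_pN, eta_Pa_s: float, h_nm: float):
    """Deterministic pore closure rate dr/dt, nm/ns.

    For a radius-dependent line tension the driving force is
    d(2 pi r gamma)/dr, giving

        dr/dt = -(gamma(r) + r dgamma/dr) / (4 eta h),

    which reduces to the constant-rate classical expression for constant
    gamma.  The derivative is taken from a cubic-spline representation of
    gamma(r).
    """
    from scipy.interpolate import CubicSpline

    r = np.asarray(r_nm, dtype=float)
    g = np.asarray(gamma_pN, dtype=float)
    if eta_Pa_s <= 0:
        raise ValueError("viscosity must be positive")
    if g.ndim == 0 or g.size == 1:
        val = -1e-3 * float(g) / (4.0 * eta_Pa_s * h_nm)
        return np.full_like(r, val) if r.shape else val
    cs = CubicSpline(r, g)
    dgdr = cs(r, 1)
    return -1e-3 * (g + r * dgdr) / (4.0 * eta_Pa_s * h_nm)
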