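"""Conjugation of the pore-edge regions and junction optimization.

A pore state is parametrized by the waist radius r and belt half-height L
(L = 0 for a hydrophilic pore).  For given (r, L) the two elastic regions
are conjugated along the junction circles {R0, +/-Z0} by continuity of the
neutral surfaces and of the director,

    H(R0) = Z0,   R(Z0) = R0,   n(R0) - v(Z0) = 1,

which leaves one free director value at the junction, theta = n(R0).

Junction-director closure
-------------------------
The continuity condition above is the linearization (chord) of the exact
quarter-turn matching n^2 + v^2 = 1 between the two segment
parametrizations.  Minimizing the quadratic energy over an unrestricted
theta admits an unphysical branch in which the vertical segment performs
the entire turn (v -> -1) while everting (u' ~ -v), which the truncated
functional prices far below the exact one -- the small-deviation premise
of the segmentation is then violated on both counts (see the methods
note, and tests comparing against the discretized functional).  The
closure used here therefore restricts theta to the trust region of the
segmentation: the bilayer deviation may not exceed half of the
(linearized) turn, |theta| <= 1/2, and the wall may not rotate the
director at the junction beyond the larger of half the turn and the value
already enforced at the belt rim,

    theta = clip(theta*, 1 - max(1/2, |v_rim|), 1/2),

where theta* is the unconstrained quadratic vertex and v_rim the belt-rim
director (0 for a hydrophilic pore).  The rule is continuous in L and
reduces to the symmetric split theta = 1/2 for hydrophilic pores.

The junction circle (R0, Z0) is then optimized by gradient descent with
backtracking and Newton polishing until the central-difference gradient
norm falls below 1e-7 k_BT/nm.

Total energy (relative to the intact bilayer):

    W = W_b + W_m + W_h - 2 pi r^2 sigma0          (W_h = 0 for L = 0)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .belt import belt_energy_rl
from .bilayer import bilayer_energy, solve_bilayer
from .monolayer import belt_director, monolayer_energy, solve_monolayer
from .parameters import EnvironmentParameters, LipidParameters

__all__ = [
    "PoreGeometry",
    "EnergyBreakdown",
    "junction_director_bounds",
    "total_energy",
    "optimize_junction",
]

#: stopping rule for the junction optimization, k_BT/nm
GRAD_TOL = 1e-7
#: central-difference step for junction gradients, nm
FD_STEP = 1e-5


@dataclass(frozen=True)
class PoreGeometry:
    """Generalized coordinates of one membrane configuration."""

    r: float  # pore waist radius at the neutral surface, nm
    L: float  # belt half-height, nm (0 for hydrophilic)
    R0: float  # junction circle radius, nm
    Z0: float  # junction circle height, nm

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("pore radius r must be positive")
        if self.L < 0:
            raise ValueError("belt half-height L must be non-negative")
        if self.R0 <= self.r:
            raise ValueError(f"junction radius R0={self.R0} must exceed r={self.r}")
        if self.Z0 <= self.L:
            raise ValueError(f"junction height Z0={self.Z0} must exceed L={self.L}")

    @property
    def mode(self) -> str:
        return "hydrophilic" if self.L == 0.0 else "hydrophobic"


@dataclass
class EnergyBreakdown:
    """Total pore-edge energy and its decomposition, k_BT."""

    W_total: float
    W_b: float  # horizontal bilayer region
    W_m: float  # vertical monolayer region
    W_h: float  # hydrophobic belt
    splay: float
    tilt: float
    stretch: float
    tension: float
    n_junction: float  # director rho-projection at the junction (bilayer side)
    converged: bool = True
    grad_norm: float = float("nan")
    geometry: PoreGeometry | None = None
    solutions: tuple = field(default=(), repr=False)


def junction_director_bounds(lipid: LipidParameters, L: float) -> tuple[float, float]:
    """Trust-region bounds [lo, hi] for the junction director theta = n(R0)."""
    v_rim = abs(belt_director(L, lipid.h))
    lo = 1.0 - max(0.5, v_rim)
    return lo, 0.5


def _elastic(lipid, env, geom: PoreGeometry, theta: float):
    bi = solve_bilayer(lipid, env, geom.R0, geom.Z0, theta)
    mo = solve_monolayer(
        lipid, env, geom.r, geom.L, geom.R0, geom.Z0, theta - 1.0, mode=geom.mode
    )
    return bi, mo


def _closed_theta(lipid, env, geom: PoreGeometry) -> float:
    """Junction director from the clipped quadratic vertex."""
    lo, hi = junction_director_bounds(lipid, geom.L)
    t0 = 0.5 * (lo + hi)
    dt = 0.2
    W = []
    for t in (t0 - dt, t0, t0 + dt):
        bi, mo = _elastic(lipid, env, geom, t)
        W.append(bilayer_energy(bi) + monolayer_energy(mo))
    curv = W[0] - 2.0 * W[1] + W[2]
    if curv <= 0:
        raise ArithmeticError(
            f"junction-director energy not convex at {geom} (curv={curv})"
        )
    vertex = t0 - dt * (W[2] - W[0]) / (2.0 * curv)
    return float(min(max(vertex, lo), hi))


def total_energy(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    geom: PoreGeometry,
    theta: float | None = None,
    keep_solutions: bool = False,
) -> EnergyBreakdown:
    """Total edge energy at a fixed geometry.

    The junction director theta = n(R0) is fixed by the clipped variational
    closure unless given explicitly.
    """
    if theta is None:
        theta = _closed_theta(lipid, env, geom)
    bi, mo = _elastic(lipid, env, geom, theta)
    Wb, cb = bilayer_energy(bi, components=True)
    Wm, cm = monolayer_energy(mo, components=True)
    Wh = belt_energy_rl(geom.r, geom.L, env)
    Wtot = Wb + Wm + Wh - 2.0 * np.pi * geom.r**2 * env.sigma0
    return EnergyBreakdown(
        W_total=float(Wtot),
        W_b=float(Wb),
        W_m=float(Wm),
        W_h=float(Wh),
        splay=float(cb["splay"] + cm["splay"]),
        tilt=float(cb["tilt"] + cm["tilt"]),
        stretch=float(cb["stretch"] + cm["stretch"]),
        tension=float(
            cb["tension"] + cm["tension"] - 2.0 * np.pi * geom.r**2 * env.sigma0
        ),
        n_junction=float(theta),
        geometry=geom,
        solutions=(bi, mo) if keep_solutions else (),
    )


def _objective(lipid, env, r, L):
    """W(R0, Z0) with the director closure applied at every point."""
    Wh = belt_energy_rl(r, L, env)
    area_term = -2.0 * np.pi * r**2 * env.sigma0

    def W(R0, Z0):
        if R0 <= r or Z0 <= L:
            return np.inf
        geom = PoreGeometry(r=r, L=L, R0=R0, Z0=Z0)
        try:
            theta = _closed_theta(lipid, env, geom)
            bi, mo = _elastic(lipid, env, geom, theta)
        except (ArithmeticError, ValueError):
            return np.inf
        return bilayer_energy(bi) + monolayer_energy(mo) + Wh + area_term

    return W


def _grad(W, R0, Z0, step=FD_STEP):
    return np.array(
        [
            (W(R0 + step, Z0) - W(R0 - step, Z0)) / (2 * step),
            (W(R0, Z0 + step) - W(R0, Z0 - step)) / (2 * step),
        ]
    )


def _hessian(W, R0, Z0, step=1e-4):
    f0 = W(R0, Z0)
    hxx = (W(R0 + step, Z0) - 2 * f0 + W(R0 - step, Z0)) / step**2
    hyy = (W(R0, Z0 + step) - 2 * f0 + W(R0, Z0 - step)) / step**2
    hxy = (
        W(R0 + step, Z0 + step)
        - W(R0 + step, Z0 - step)
        - W(R0 - step, Z0 + step)
        + W(R0 - step, Z0 - step)
    ) / (4 * step**2)
    return np.array([[hxx, hxy], [hxy, hyy]])


def _descend(W, r, L, R0, Z0, max_iter):
    """Gradient descent with backtracking + Newton polish."""
    lo_R, lo_Z = r + 1e-4, L + 1e-4
    f = W(R0, Z0)
    if not np.isfinite(f):
        return R0, Z0, np.inf, np.inf, False
    step = 0.1
    g = _grad(W, R0, Z0)
    for _ in range(max_iter):
        gn = float(np.hypot(*g))
        if gn < GRAD_TOL:
            return R0, Z0, f, gn, True
        moved = False
        if gn < 1.0:  # Newton once the quadratic model is trustworthy
            Hm = _hessian(W, R0, Z0)
            try:
                dn = np.linalg.solve(Hm, -g)
            except np.linalg.LinAlgError:
                dn = None
            if dn is not None and np.all(np.isfinite(dn)) and np.hypot(*dn) < 1.0:
                R1 = max(R0 + dn[0], lo_R)
                Z1 = max(Z0 + dn[1], lo_Z)
                f1 = W(R1, Z1)
                if f1 <= f + 1e-12:
                    R0, Z0, f, moved = R1, Z1, f1, True
        if not moved:
            d = -g / max(float(np.hypot(*g)), 1e-300)
            while step > 1e-13:
                R1 = max(R0 + step * d[0], lo_R)
                Z1 = max(Z0 + step * d[1], lo_Z)
                f1 = W(R1, Z1)
                if f1 < f:
                    R0, Z0, f = R1, Z1, f1
                    step *= 1.6
                    moved = True
                    break
                step *= 0.5
            if not moved:
                g = _grad(W, R0, Z0)
                gn = float(np.hypot(*g))
                return R0, Z0, f, gn, gn < GRAD_TOL
        g = _grad(W, R0, Z0)
    gn = float(np.hypot(*g))
    return R0, Z0, f, gn, gn < GRAD_TOL


def optimize_junction(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    r: float,
    L: float = 0.0,
    mode: str | None = None,
    init: tuple[float, float] | None = None,
    max_iter: int = 300,
) -> EnergyBreakdown:
    """Optimize the junction circle (R0, Z0) for fixed (r, L).

    Runs from two independent starting points (or the provided one) and
    keeps the lower optimum; stops when |grad W| < 1e-7 k_BT/nm.
    """
    if mode is not None:
        expected = "hydrophilic" if L == 0.0 else "hydrophobic"
        if mode != expected:
            raise ValueError(f"mode {mode!r} inconsistent with L={L}")
    h = lipid.h
    W = _objective(lipid, env, r, L)
    if init is not None:
        inits = [init]
    else:
        dz = max(h - L, 0.3 * h)
        inits = [(r + 0.35 * h, L + dz), (r + 0.6 * h, L + 0.6 * dz)]
    best = None
    for R0_0, Z0_0 in inits:
        res = _descend(W, r, L, R0_0, Z0_0, max_iter)
        if best is None or res[2] < best[2]:
            best = res
    R0, Z0, Wv, gnorm, ok = best
    if not ok:
        warnings.warn(
            f"junction optimization stalled at |grad|={gnorm:.3g} k_BT/nm "
            f"(r={r}, L={L})",
            RuntimeWarning,
            stacklevel=2,
        )
    bd = total_energy(lipid, env, PoreGeometry(r=r, L=L, R0=R0, Z0=Z0))
    bd.converged = bool(ok)
    bd.grad_norm = float(gnorm)
    return bd
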