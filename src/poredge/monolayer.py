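"""Deformation fields and elastic energy of the vertical (edge-lining)
monolayer region.

The pore-lining monolayer is described as a deviation from a reference
cylinder of neutral-surface radius R_v coaxial with the pore axis.  Fields,
all functions of the axial coordinate z:

* v(z)    -- axial director projection,
* m(z)    -- deviation of the tail-end surface radius, M(z) = M_v + m(z),
* beta(z) -- lateral stretch (identically zero at equilibrium, see below),
* u(z)    -- deviation of the neutral-surface radius, R(z) = R_v + u(z),
             slaved to the others by local volumetric incompressibility:

                 u = R_v^2/(2 R_v^2 + h^2) * (2 m + 2 h beta + h^2 v').

The elastic energy (second order in deviations, both mirror halves) is

    W_m = 2 Int_{z_lo}^{Z0} 2 pi R sqrt(1+R'^2)
            { (B/2) [(v' + 1/R + J0)^2 - J0^2] + (K_t/2) (v + u')^2
              + (K_A/2) beta^2 + sigma0 } dz  -  2 sigma0 pi (R0^2 - r^2)

with z_lo = 0 for a hydrophilic pore (mirror plane) and z_lo = L for a
hydrophobic defect (belt rim).  Because the energy depends on m and beta
only through the combination m + h*beta, the beta Euler-Lagrange equation
reduces to K_A beta = 0: the stretch vanishes exactly and is eliminated
analytically here (the discretized route keeps beta free and recovers this
numerically).

After elimination the quadratic Lagrangian density depends on
(v, v', v'', m, m').  Exponential modes e^{q z} satisfy a biquadratic
characteristic equation (the nominal degree-6 determinant degenerates:
v'' and m' enter only through u', which also makes the natural boundary
conditions identically satisfied).  Four modes and four boundary
conditions -- v and u prescribed at both ends -- determine the solution
uniquely; the junction director value itself is optimized at assembly
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import roots_legendre

from .parameters import EnvironmentParameters, LipidParameters

__all__ = [
    "equilibrium_cylinder",
    "belt_director",
    "MonolayerSolution",
    "solve_monolayer",
    "monolayer_energy",
]

# Y-vector component indices: v, v', v'', m, m'
_V, _VP, _VPP, _M, _MP = range(5)


def equilibrium_cylinder(lipid: LipidParameters, R_v: float) -> float:
    """Tail-end radius M_v of the volumetrically relaxed reference cylinder,

        M_v - R_v = h - h^2 / (2 R_v).

    Requires R_v > h/2 so that the tail-end surface lies outside the
    neutral surface.
    """
    if R_v <= lipid.h / 2.0:
        raise ValueError(
            f"R_v={R_v} <= h/2={lipid.h / 2}: reference cylinder has no "
            "geometrically sensible tail-end surface"
        )
    return R_v + lipid.h - lipid.h**2 / (2.0 * R_v)


def belt_director(L: float, h: float) -> float:
    """Director z-projection at the hydrophobic-belt rim,

        v(L) = -L / sqrt(L^2 + (h-L)^2),

    a direct consequence of constant hydrocarbon density in the belt.
    Continuously approaches the mirror-symmetry value v=0 as L -> 0.
    """
    if L == 0.0:
        return 0.0
    return -L / np.hypot(L, h - L)


# ---------------------------------------------------------------------------
# Quadratic-form assembly.
#
# Each energy-density term is gamma * (a.Y) * (b.Y); linear terms are
# coefficient vectors over Y, so a component of the density reads
#     e_c(z) = sum_t gamma_t (a_t.Y)(b_t.Y) + b_c.Y + c_c.
# ---------------------------------------------------------------------------


class _Component:
    """Quadratic + linear + constant part of one energy-density component."""

    __slots__ = ("Q", "lin", "const")

    def __init__(self):
        self.Q = np.zeros((5, 5))
        self.lin = np.zeros(5)
        self.const = 0.0

    def add_quad(self, gamma: float, a: np.ndarray, b: np.ndarray) -> None:
        # density gamma*(a.Y)(b.Y)  ->  (1/2) Y.Q.Y with Q symmetric
        self.Q += gamma * (np.outer(a, b) + np.outer(b, a))

    def value(self, Y: np.ndarray) -> np.ndarray:
        # Y shape (..., 5)
        quad = 0.5 * np.einsum("...i,ij,...j->...", Y, self.Q, Y)
        return quad + Y @ self.lin + self.const


@dataclass(frozen=True)
class _System:
    """Cached mode system for one (lipid, sigma0, R_v)."""

    R_v: float
    k: float
    comps: dict  # name -> _Component
    Q: np.ndarray
    lin: np.ndarray
    const: float
    qs: tuple  # representative mode exponents (complex)
    etas: tuple  # 5-vectors (complex) for each representative
    n_real: int  # real degrees of freedom
    v_p: float
    m_p: float


def _assemble(lipid: LipidParameters, sigma0: float, R_v: float) -> _System:
    h = lipid.h
    B = lipid.B
    K_t = lipid.K_t
    J0 = lipid.J0
    k = R_v * R_v / (2.0 * R_v * R_v + h * h)
    c0 = 1.0 / R_v + J0

    u = np.zeros(5)
    u[_M] = 2.0 * k
    u[_VP] = h * h * k
    up = np.zeros(5)
    up[_MP] = 2.0 * k
    up[_VPP] = h * h * k
    d1 = np.zeros(5)  # first-order part of (div + J0) - (1/R_v + J0)
    d1[_VP] = 1.0
    d1 -= u / (R_v * R_v)
    tl = np.zeros(5)  # tilt v + u'
    tl[_V] = 1.0
    tl += up

    f0s = 0.5 * B * (c0 * c0 - J0 * J0)  # splay density of the bare cylinder

    splay = _Component()
    splay.add_quad(B * c0 / (R_v * R_v), u, u)  # from expanding 1/R to 2nd order
    splay.add_quad(0.5 * R_v * B, d1, d1)
    splay.add_quad(B * c0, u, d1)  # measure x first-order density
    splay.add_quad(0.5 * f0s * R_v, up, up)  # area-element correction
    splay.lin += f0s * u + R_v * B * c0 * d1
    splay.const = R_v * f0s

    tilt = _Component()
    tilt.add_quad(0.5 * R_v * K_t, tl, tl)

    stretch = _Component()  # identically zero: beta == 0

    tension = _Component()
    if sigma0 != 0.0:
        tension.add_quad(0.5 * sigma0 * R_v, up, up)
        tension.lin += sigma0 * u
        tension.const = R_v * sigma0

    comps = {"splay": splay, "tilt": tilt, "stretch": stretch, "tension": tension}
    Q = sum(c.Q for c in comps.values())
    lin = sum(c.lin for c in comps.values())
    const = sum(c.const for c in comps.values())

    qs, etas, n_real = _modes(Q)
    # constant particular solution: S(0) x_p = -b0 on the plain (v, m) slots
    S0 = np.array([[Q[_V, _V], Q[_V, _M]], [Q[_M, _V], Q[_M, _M]]])
    b0 = np.array([lin[_V], lin[_M]])
    v_p, m_p = np.linalg.solve(S0, -b0)
    return _System(
        R_v=R_v, k=k, comps=comps, Q=Q, lin=lin, const=const,
        qs=tuple(qs), etas=tuple(etas), n_real=n_real, v_p=v_p, m_p=m_p,
    )


def _modes(Q: np.ndarray):
    """Exponential modes of the Euler-Lagrange system.

    Builds the 2x2 symbol S(q) = T(-q)^T Q T(q) as polynomials in q,
    extracts the roots of det S and the corresponding amplitude
    null-vectors, and returns conjugation representatives.
    """
    # T(q): columns (v-amplitude, m-amplitude), rows Y-components;
    # entries are polynomial coefficient arrays (ascending powers of q).
    def tpoly(sign):
        T = [[None, None] for _ in range(5)]
        z = np.zeros(1)
        T[_V] = [np.array([1.0]), z]
        T[_VP] = [np.array([0.0, sign * 1.0]), z]
        T[_VPP] = [np.array([0.0, 0.0, 1.0]), z]
        T[_M] = [z, np.array([1.0])]
        T[_MP] = [z, np.array([0.0, sign * 1.0])]
        return T

    Tm, Tp = tpoly(-1.0), tpoly(1.0)
    S = [[np.zeros(5) for _ in range(2)] for _ in range(2)]
    for i in range(2):
        for j in range(2):
            acc = np.zeros(5)
            for a in range(5):
                for b in range(5):
                    if Q[a, b] == 0.0:
                        continue
                    pa, pb = Tm[a][i], Tp[b][j]
                    if pa.size == 1 and pa[0] == 0.0:
                        continue
                    if pb.size == 1 and pb[0] == 0.0:
                        continue
                    prod = Q[a, b] * np.convolve(pa, pb)
                    acc[: prod.size] += prod
            S[i][j] = acc
    det = np.convolve(S[0][0], S[1][1]) - np.convolve(S[0][1], S[1][0])
    # trim numerically vanishing leading coefficients (the degree-6 terms
    # cancel structurally; see module docstring)
    tol = 1e-9 * np.max(np.abs(det))
    nz = np.nonzero(np.abs(det) > tol)[0]
    det = det[: nz[-1] + 1]
    roots = np.roots(det[::-1])
    if len(roots) != 4:
        raise ArithmeticError(
            f"unexpected characteristic structure: {len(roots)} modes"
        )

    def s_at(q):
        out = np.empty((2, 2), dtype=complex)
        for i in range(2):
            for j in range(2):
                out[i, j] = np.polyval(S[i][j][::-1], q)
        return out

    # conjugation representatives: keep Im q > tol, plus real roots
    rtol = 1e-9 * max(1.0, np.max(np.abs(roots)))
    reps = [q for q in roots if q.imag > rtol] + [
        complex(q.real, 0.0) for q in roots if abs(q.imag) <= rtol
    ]
    reps.sort(key=lambda q: (round(abs(q), 12), q.real))
    qs, etas = [], []
    n_real = 0
    for q in reps:
        _, _, vh = np.linalg.svd(s_at(q))
        V, M = vh[-1].conj()
        eta = np.array([V, q * V, q * q * V, M, q * M])
        qs.append(q)
        etas.append(eta)
        n_real += 1 if abs(q.imag) <= rtol else 2
    if n_real != 4:
        raise ArithmeticError(
            f"mode bookkeeping failure: {n_real} real degrees of freedom"
        )
    return qs, etas, n_real


_SYS_CACHE: dict = {}


def _system(lipid: LipidParameters, env: EnvironmentParameters, R_v: float) -> _System:
    key = (lipid.B, lipid.K_t, lipid.K_A, lipid.h, lipid.J0, env.sigma0, R_v)
    sys_ = _SYS_CACHE.get(key)
    if sys_ is None:
        if len(_SYS_CACHE) > 4096:
            _SYS_CACHE.clear()
        sys_ = _assemble(lipid, env.sigma0, R_v)
        _SYS_CACHE[key] = sys_
    return sys_


# ---------------------------------------------------------------------------


@dataclass
class MonolayerSolution:
    """Solved vertical-region boundary-value problem."""

    lipid: LipidParameters
    env: EnvironmentParameters
    mode: str  # "hydrophilic" | "hydrophobic"
    r: float
    L: float
    R0: float
    Z0: float
    v_junction: float
    R_v: float
    system: _System = field(repr=False)
    w: np.ndarray = field(repr=False)  # real basis weights
    basis: list = field(repr=False)  # (q, eta, anchor, part) per real function

    @property
    def z_lo(self) -> float:
        return 0.0 if self.mode == "hydrophilic" else self.L

    def _Y(self, z) -> np.ndarray:
        """Y = (v, v', v'', m, m') at the given z values, shape (..., 5)."""
        z = np.asarray(z, dtype=float)
        zf = np.atleast_1d(z).ravel()
        Y = np.zeros((zf.size, 5))
        for wk, (q, eta, anchor, part) in zip(self.w, self.basis):
            mode = eta[None, :] * np.exp(q * (zf[:, None] - anchor))
            Y += wk * (mode.real if part == "re" else mode.imag)
        Y[:, _V] += self.system.v_p
        Y[:, _M] += self.system.m_p
        return Y.reshape(z.shape + (5,))

    # -- physical fields ----------------------------------------------------
    def v(self, z):
        return self._Y(z)[..., _V]

    def m(self, z):
        return self._Y(z)[..., _M]

    def beta(self, z):
        z = np.asarray(z, dtype=float)
        return np.zeros(z.shape)

    def u(self, z):
        Y = self._Y(z)
        h, k = self.lipid.h, self.system.k
        return k * (2.0 * Y[..., _M] + h * h * Y[..., _VP])

    def R(self, z):
        return self.R_v + self.u(z)

    def M(self, z):
        """Tail-end surface radius (only meaningful for R_v > h/2)."""
        M_v = self.R_v + self.lipid.h - self.lipid.h**2 / (2.0 * self.R_v)
        return M_v + self.m(z)

    def u_residual(self, z):
        """Residual of the incompressibility relation tying u to (m, v')."""
        Y = self._Y(z)
        h, k = self.lipid.h, self.system.k
        return self.u(z) - k * (2.0 * Y[..., _M] + h * h * Y[..., _VP])


def solve_monolayer(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    r: float,
    L: float,
    R0: float,
    Z0: float,
    v_junction: float,
    mode: str = "hydrophilic",
) -> MonolayerSolution:
    """Solve the vertical region for one pore geometry.

    Boundary conditions: R = r and the symmetry/belt director value at the
    lower end (z = 0 for a hydrophilic pore, z = L at the belt rim), and
    R(Z0) = R0, v(Z0) = v_junction at the junction circle.  The reference
    cylinder radius is taken as R_v = r, so u vanishes at the lower end.
    """
    if mode not in ("hydrophilic", "hydrophobic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "hydrophilic" and L != 0.0:
        raise ValueError("hydrophilic mode requires L = 0")
    if not (0.0 <= L < lipid.h):
        raise ValueError(f"belt half-height L={L} outside [0, h)")
    if r <= 0.0:
        raise ValueError("pore radius must be positive")
    z_lo = 0.0 if mode == "hydrophilic" else L
    if Z0 <= z_lo:
        raise ValueError(f"junction height Z0={Z0} must exceed {z_lo}")

    sys_ = _system(lipid, env, r)
    h, k = lipid.h, sys_.k

    # real basis functions from the conjugation representatives
    basis = []
    for q, eta in zip(sys_.qs, sys_.etas):
        anchor = Z0 if q.real > 0 else z_lo
        basis.append((q, eta, anchor, "re"))
        if abs(q.imag) > 1e-9 * max(1.0, abs(q)):
            basis.append((q, eta, anchor, "im"))

    def row(z, kind):
        out = np.empty(len(basis))
        for j, (q, eta, anchor, part) in enumerate(basis):
            Y = eta * np.exp(q * (z - anchor))
            Y = Y.real if part == "re" else Y.imag
            if kind == "v":
                out[j] = Y[_V]
            else:  # u
                out[j] = k * (2.0 * Y[_M] + h * h * Y[_VP])
        return out

    v_lo = 0.0 if mode == "hydrophilic" else belt_director(L, h)
    u_p = k * 2.0 * sys_.m_p  # particular contributions (v_p' = 0)
    C = np.vstack(
        [row(z_lo, "v"), row(z_lo, "u"), row(Z0, "v"), row(Z0, "u")]
    )
    g = np.array(
        [
            v_lo - sys_.v_p,
            (r - r) - u_p,  # R(z_lo) = r with R_v = r
            v_junction - sys_.v_p,
            (R0 - r) - u_p,
        ]
    )
    # column equilibration: mode amplitudes span many orders of magnitude
    # on short domains, which is harmless after rescaling
    scale = np.max(np.abs(C), axis=0)
    scale[scale == 0.0] = 1.0
    Cs = C / scale
    cond = np.linalg.cond(Cs)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            f"ill-conditioned monolayer boundary system (cond={cond:.3g}, "
            f"r={r}, L={L}, Z0={Z0})",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        w = np.linalg.solve(Cs, g) / scale
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(
            f"inconsistent monolayer boundary system (r={r}, L={L}, "
            f"R0={R0}, Z0={Z0})"
        ) from exc
    return MonolayerSolution(
        lipid=lipid, env=env, mode=mode, r=r, L=L, R0=R0, Z0=Z0,
        v_junction=v_junction, R_v=r, system=sys_, w=w, basis=basis,
    )


_GL_NODES, _GL_WEIGHTS = roots_legendre(16)


def monolayer_energy(sol: MonolayerSolution, components: bool = False):
    """Vertical-region energy, k_BT (both mirror halves / both sections).

    With ``components=True`` returns ``(W, dict)`` with the
    splay/tilt/stretch/tension split.  The sigma0 area term
    -2 sigma0 pi (R0^2 - r^2) is booked under "tension".
    """
    z_lo, Z0 = sol.z_lo, sol.Z0
    qmax = max(abs(q) for q, *_ in sol.basis)
    n_panels = max(3, int(qmax * (Z0 - z_lo) / 2.0) + 1)
    edges = np.linspace(z_lo, Z0, n_panels + 1)
    mid = 0.5 * (edges[:-1, None] + edges[1:, None])
    half = 0.5 * (edges[1:, None] - edges[:-1, None])
    z = (mid + half * _GL_NODES[None, :]).ravel()
    wq = (half * _GL_WEIGHTS[None, :]).ravel()

    Y = sol._Y(z)
    out = {}
    for name, comp in sol.system.comps.items():
        out[name] = 4.0 * np.pi * float(np.sum(wq * comp.value(Y)))
    if sol.env.sigma0 != 0.0:
        out["tension"] -= (
            2.0 * sol.env.sigma0 * np.pi * (sol.R0**2 - sol.r**2)
        )
    W = float(sum(out.values()))
    if components:
        return W, out
    return W
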