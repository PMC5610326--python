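"""Direct finite-difference minimization of the region energy functionals.

This module is the slow, independent route to the same boundary-value
problems that :mod:`poredge.bilayer` and :mod:`poredge.monolayer` solve
analytically: each functional is discretized on a dense grid and minimized
as a sparse quadratic form under the same essential boundary conditions.
It is used to validate the analytic solutions (fields and energies agree to
well under 1% on admissible boundary data) and for debugging.

Discretization note: the functionals are stated in fields whose higher
derivatives enter only through the neutral-surface shape (H' in the
horizontal region, u' in the vertical one).  Discretizing in those
variables directly is degenerate and admits parasitic grid-scale modes, so
the oracle works in the equivalent first-order variables -- (n, H) for the
horizontal region with the stretch alpha slaved to them through local
incompressibility, and (v, u, beta) for the vertical region with the
tail-end deviation m slaved likewise.  Both maps are linear and exact, so
the minimized functional is identical.

For the vertical region the quadratic (second-order) truncation of the
energy density is generated symbolically with sympy from the *exact*
integrand -- measure and 1/R expansion included -- so the truncation is
derived independently of the hand-assembled quadratic form of
:mod:`poredge.monolayer`.  The lateral stretch beta is kept as a free
field; its vanishing at the minimum is a consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .parameters import EnvironmentParameters, LipidParameters

__all__ = ["minimize_bilayer_fd", "minimize_monolayer_fd"]


def _d1(x: np.ndarray):
    """Sparse first-derivative operator (2nd-order central / one-sided)."""
    n = x.size
    dx = x[1] - x[0]
    D1 = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        D1[i, i - 1], D1[i, i + 1] = -0.5 / dx, 0.5 / dx
    D1[0, 0], D1[0, 1], D1[0, 2] = -1.5 / dx, 2 / dx, -0.5 / dx
    D1[-1, -1], D1[-1, -2], D1[-1, -3] = 1.5 / dx, -2 / dx, 0.5 / dx
    return D1.tocsr()


def _trapz_weights(x: np.ndarray) -> np.ndarray:
    w = np.full(x.size, x[1] - x[0])
    w[0] = w[-1] = 0.5 * (x[1] - x[0])
    return w


def _kkt_solve(H, f, C, g):
    """Minimize (1/2) x.H.x + f.x subject to C x = g (sparse KKT)."""
    H = sp.csr_matrix(H)
    C = sp.csr_matrix(C)
    n = H.shape[0]
    K = sp.bmat([[H, C.T], [C, None]], format="csc")
    rhs = np.concatenate([-np.asarray(f).ravel(), np.asarray(g).ravel()])
    sol = spsolve(K, rhs)
    x = sol[:n]
    return x, float(0.5 * x @ (H @ x) + f @ x)


@dataclass
class BilayerFDResult:
    rho: np.ndarray
    n: np.ndarray
    alpha: np.ndarray
    H: np.ndarray
    energy: float


def minimize_bilayer_fd(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    R0: float,
    Z0: float,
    n0: float,
    span: float = 60.0,
    n_nodes: int = 6000,
) -> BilayerFDResult:
    """Discretized minimization of the horizontal-region functional.

    Fields: director projection n(rho) and neutral-surface height H(rho);
    the stretch is slaved, alpha = (h - H)/h - (h/2) div n.
    """
    rho = np.linspace(R0, R0 + span, n_nodes)
    D1 = _d1(rho)
    w = _trapz_weights(rho)
    h, l2, A, J0 = lipid.h, lipid.l2, lipid.A, lipid.J0
    sigma = env.sigma0 / lipid.K_t
    n = n_nodes
    I = sp.eye(n, format="csr")
    Z = sp.csr_matrix((n, n))
    Div = D1 + sp.diags(1.0 / rho)
    # operators on x = (n_i, H_i - h)  [work with H shifted by h so the
    # far-field state is x = 0 and the J0 coupling stays linear]
    OP_div = sp.bmat([[Div, Z]])
    OP_tilt = sp.bmat([[I, -D1]])
    OP_alpha = sp.bmat([[-(h / 2.0) * Div, -(1.0 / h) * I]])
    OP_Hp = sp.bmat([[Z, D1]])
    Wd = sp.diags(w * rho)
    pref = 2.0 * np.pi * lipid.K_t
    H_q = 2.0 * pref * (
        l2 * OP_div.T @ Wd @ OP_div
        + OP_tilt.T @ Wd @ OP_tilt
        + A * OP_alpha.T @ Wd @ OP_alpha
        + sigma * OP_Hp.T @ Wd @ OP_Hp
    )
    f = pref * 2.0 * l2 * J0 * (OP_div.T @ (w * rho))

    rows = []
    g = []
    for idx, val in ((0, n0), (n, Z0 - h), (n - 1, 0.0), (2 * n - 1, 0.0)):
        e = np.zeros(2 * n)
        e[idx] = 1.0
        rows.append(e)
        g.append(val)
    x, energy = _kkt_solve(H_q, f, np.array(rows), np.array(g))
    nf = x[:n]
    Hf = x[n:] + h
    alpha = (h - Hf) / h - (h / 2.0) * (Div @ nf)
    return BilayerFDResult(rho=rho, n=nf, alpha=alpha, H=Hf, energy=energy)


# ---------------------------------------------------------------------------


def _monolayer_density(lipid: LipidParameters, sigma0: float, R_v: float):
    """Second-order density of the vertical-region functional in the
    first-order variables (v, v', u, u', beta), derived symbolically from
    the exact integrand.  Returns (Hess 5x5, grad 5, const)."""
    import sympy as spy

    syms = spy.symbols("v vp u up be")
    v, vp, u, up, be = syms
    eps = spy.Symbol("epsilon")
    h, B, Kt, KA, J0 = lipid.h, lipid.B, lipid.K_t, lipid.K_A, lipid.J0
    R = R_v + u
    I_exact = R * spy.sqrt(1 + up**2) * (
        spy.Rational(1, 2) * B * (vp + 1 / R + J0) ** 2
        - spy.Rational(1, 2) * B * J0**2
        + spy.Rational(1, 2) * Kt * (v + up) ** 2
        + spy.Rational(1, 2) * KA * be**2
        + sigma0
    )
    Ie = I_exact.subs({s: eps * s for s in syms}, simultaneous=True)
    I2 = spy.expand(
        Ie.subs(eps, 0)
        + spy.diff(Ie, eps).subs(eps, 0)
        + spy.diff(Ie, eps, 2).subs(eps, 0) / 2
    )
    zero = {s: 0 for s in syms}
    const = float(I2.subs(zero))
    grad = np.array([float(spy.diff(I2, s).subs(zero)) for s in syms])
    hess = np.array([[float(spy.diff(I2, s1, s2)) for s2 in syms] for s1 in syms])
    return hess, grad, const


@dataclass
class MonolayerFDResult:
    z: np.ndarray
    v: np.ndarray
    u: np.ndarray
    beta: np.ndarray
    m: np.ndarray
    energy: float


def minimize_monolayer_fd(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    r: float,
    L: float,
    R0: float,
    Z0: float,
    v_junction: float,
    mode: str = "hydrophilic",
    n_nodes: int = 2000,
) -> MonolayerFDResult:
    """Discretized minimization of the vertical-region functional.

    Fields: (v, u, beta) with the tail-end deviation m slaved through the
    (linear, exact) incompressibility relation.  The returned energy covers
    both mirror halves (factor 2) but not the sigma0 junction area term,
    which the caller adds when sigma0 != 0.
    """
    z_lo = 0.0 if mode == "hydrophilic" else L
    z = np.linspace(z_lo, Z0, n_nodes)
    D1 = _d1(z)
    w = _trapz_weights(z)
    hess, grad, const = _monolayer_density(lipid, env.sigma0, r)
    h = lipid.h
    k = r**2 / (2 * r**2 + h**2)

    n = n_nodes
    I = sp.eye(n, format="csr")
    Z_ = sp.csr_matrix((n, n))
    ops = [
        sp.bmat([[I, Z_, Z_]]),  # v
        sp.bmat([[D1, Z_, Z_]]),  # v'
        sp.bmat([[Z_, I, Z_]]),  # u
        sp.bmat([[Z_, D1, Z_]]),  # u'
        sp.bmat([[Z_, Z_, I]]),  # beta
    ]
    Wd = sp.diags(w)
    H_q = sp.csr_matrix((3 * n, 3 * n))
    for a in range(5):
        for b in range(5):
            if hess[a, b] != 0.0:
                H_q = H_q + hess[a, b] * (ops[a].T @ Wd @ ops[b])
    H_q = 4.0 * np.pi * H_q
    f = 4.0 * np.pi * sum(
        grad[a] * (ops[a].T @ w) for a in range(5) if grad[a] != 0.0
    )

    from .monolayer import belt_director

    v_lo = 0.0 if mode == "hydrophilic" else belt_director(L, h)
    rows, g = [], []
    for idx, val in (
        (0, v_lo),
        (n, 0.0),  # u(z_lo) = 0: R = r at the lower end with R_v = r
        (n - 1, v_junction),
        (2 * n - 1, R0 - r),
    ):
        e = np.zeros(3 * n)
        e[idx] = 1.0
        rows.append(e)
        g.append(val)
    x, energy = _kkt_solve(H_q, np.asarray(f), np.array(rows), np.array(g))
    energy += 4.0 * np.pi * const * (Z0 - z_lo)
    v = x[:n]
    u = x[n : 2 * n]
    be = x[2 * n :]
    # m back out of the incompressibility relation
    m = u * (2 * r**2 + h**2) / (2 * r**2) - h * be - (h**2 / 2.0) * (D1 @ v)
    return MonolayerFDResult(z=z, v=v, u=u, beta=be, m=m, energy=energy)
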