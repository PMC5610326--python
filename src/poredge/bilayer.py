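"""Deformation fields and elastic energy of the horizontal (quasi-flat)
bilayer region surrounding the pore.

The region is described in cylindrical coordinates by the radial director
projection n(rho) and the relative area stretch alpha(rho) of the upper
monolayer (the lower one mirrors it).  Local volumetric incompressibility
ties the neutral-surface height to the fields,

    H(rho) = h - (h^2/2) (n' + n/rho) - h alpha,

and the elastic energy (both monolayers, relative to the flat state) is

    W_b = 2 pi K_t Int_{R0}^{inf} rho { l^2 [(div n + J0)^2 - J0^2] + t^2
          + A alpha^2 + sigma (H')^2 } drho

with div n = n' + n/rho, tilt t = n - H', l^2 = B/K_t, A = K_A/K_t and
sigma = sigma0/K_t.  The Euler-Lagrange equations are solved by cylinder
harmonics Z_1(p rho) for n and Z_0(p rho) for alpha, where the complex
wavenumbers p satisfy the characteristic quartic

    (1+sigma) h^2 (A h^2 + 4 l^2) p^4 - 4 (A (h^2-l^2) - sigma h^2) p^2 + 4 A = 0.

For physical lipid parameters the two p^2 roots form a complex-conjugate
pair; the decaying fundamental system consists of outgoing Hankel functions
H^(1)_nu(p rho) with Im p > 0 together with their complex conjugates, so the
general real decaying solution has exactly two real degrees of freedom.
These are fixed by the junction data n(R0) = n0 and H(R0) = Z0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.special import roots_legendre

from .parameters import EnvironmentParameters, LipidParameters

__all__ = ["characteristic_roots", "BilayerSolution", "solve_bilayer", "bilayer_energy"]


def characteristic_roots(lipid: LipidParameters, sigma: float = 0.0):
    """Both characteristic wavenumbers (p1, p2) of the horizontal region.

    Parameters
    ----------
    sigma : float
        Dimensionless lateral tension sigma0/K_t (>= 0).

    Returns
    -------
    (p1, p2) : complex
        Principal square roots of the two roots of the characteristic
        quartic in p^2; the '+' discriminant branch is p1.  For physical
        parameters p2 = -conj(p1) up to root ordering, i.e. the pair allows
        a real field reconstruction.
    """
    h2 = lipid.h**2
    l2 = lipid.l2
    A = lipid.A
    s = 1.0 + sigma
    a4 = s * h2 * (A * h2 + 4.0 * l2)
    if a4 == 0.0:
        raise ValueError("degenerate lipid parameters: h^2*A + 4*l^2 = 0")
    half_b = A * (h2 - l2) - sigma * h2  # quartic is a4 p^4 - 4*half_b p^2 + 4A
    disc = complex(half_b * half_b - s * A * h2 * (A * h2 + 4.0 * l2))
    sq = np.sqrt(disc)
    p1 = np.sqrt(2.0 * (half_b + sq) / a4)
    p2 = np.sqrt(2.0 * (half_b - sq) / a4)
    return p1, p2


def _alpha_amplitude(p: complex, lipid: LipidParameters, sigma: float) -> complex:
    """Amplitude ratio a(p): for an n-mode Z1(p rho) the stretch field is
    alpha = a(p) Z0(p rho) (from the alpha Euler-Lagrange equation)."""
    h = lipid.h
    A = lipid.A
    s = 1.0 + sigma
    hp2 = h * h * p * p
    return h * p * (2.0 - hp2 * s) / (2.0 * (A + hp2 * s))


@dataclass
class BilayerSolution:
    """Decaying solution of the horizontal-region boundary-value problem.

    The fields are reconstructed from one complex coefficient ``c`` for the
    Im p > 0 Hankel mode; the conjugate mode carries conj(c), which keeps
    every physical field real.
    """

    lipid: LipidParameters
    env: EnvironmentParameters
    R0_applied: float
    Z0_applied: float
    n0_applied: float
    p1: complex
    p2: complex
    c: complex
    a1: complex  # alpha amplitude for the p1 mode

    # -- field evaluation ---------------------------------------------------
    def _z(self, order: int, rho):
        rho = np.asarray(rho, dtype=float)
        return special.hankel1(order, self.p1 * rho)

    def n(self, rho):
        """Radial director projection."""
        return 2.0 * np.real(self.c * self._z(1, rho))

    def div(self, rho):
        """Director divergence n' + n/rho."""
        return 2.0 * np.real(self.c * self.p1 * self._z(0, rho))

    def alpha(self, rho):
        """Relative area stretch."""
        return 2.0 * np.real(self.c * self.a1 * self._z(0, rho))

    def n_prime(self, rho):
        rho = np.asarray(rho, dtype=float)
        return self.div(rho) - self.n(rho) / rho

    def tilt(self, rho):
        """Tilt projection t = n - H'."""
        h = self.lipid.h
        tau = 1.0 - h * h * self.p1 * self.p1 / 2.0 - h * self.a1 * self.p1
        return 2.0 * np.real(self.c * tau * self._z(1, rho))

    def H_prime(self, rho):
        h = self.lipid.h
        amp = (h * h / 2.0) * self.p1 * self.p1 + h * self.a1 * self.p1
        return 2.0 * np.real(self.c * amp * self._z(1, rho))

    def H(self, rho):
        """Neutral-surface height above the midplane, nm."""
        h = self.lipid.h
        amp = (h * h / 2.0) * self.p1 + h * self.a1
        return h - 2.0 * np.real(self.c * amp * self._z(0, rho))

    @property
    def decay_rate(self) -> float:
        """Asymptotic exponential decay rate of the fields, 1/nm."""
        return float(np.imag(self.p1))


def solve_bilayer(
    lipid: LipidParameters,
    env: EnvironmentParameters,
    R0: float,
    Z0: float,
    n0: float,
) -> BilayerSolution:
    """Solve the horizontal region for junction data (R0, Z0, n0).

    Selects the two real degrees of freedom of the decaying fundamental
    system and fixes them by n(R0) = n0 and H(R0) = Z0.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    if abs(n0) >= 1.0:
        raise ValueError("|n0| must be < 1 (small-deformation regime)")
    sigma = env.sigma0 / lipid.K_t
    p1, p2 = characteristic_roots(lipid, sigma)
    # orient both modes into the upper half plane; the conjugate partners
    # (carrying conj coefficients) then decay as well.
    if p1.imag < 0:
        p1 = np.conj(p1)
    if p1.imag <= 0:
        raise ValueError(
            "characteristic roots are purely real: no decaying solution "
            f"(p1={p1}, p2={p2})"
        )
    a1 = _alpha_amplitude(p1, lipid, sigma)
    h = lipid.h
    # n(R0):  2 Re[c * H1(p1 R0)] = n0
    # H(R0):  h - 2 Re[c * ((h^2/2) p1 + h a1) H0(p1 R0)] = Z0
    A1 = special.hankel1(1, p1 * R0)
    B1 = ((h * h / 2.0) * p1 + h * a1) * special.hankel1(0, p1 * R0)
    M = np.array(
        [[A1.real, -A1.imag], [B1.real, -B1.imag]], dtype=float
    )
    rhs = np.array([n0 / 2.0, (h - Z0) / 2.0])
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        import warnings

        warnings.warn(
            f"ill-conditioned bilayer boundary system (cond={cond:.3g}, "
            f"R0={R0}, p1={p1})",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        x = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ArithmeticError(
            f"singular bilayer boundary system at R0={R0}, roots ({p1}, {p2})"
        ) from exc
    c = complex(x[0], x[1])
    return BilayerSolution(
        lipid=lipid,
        env=env,
        R0_applied=R0,
        Z0_applied=Z0,
        n0_applied=n0,
        p1=p1,
        p2=p2,
        c=c,
        a1=a1,
    )


# fixed Gauss-Legendre rule reused across panels
_GL_NODES, _GL_WEIGHTS = roots_legendre(24)


def _quad_nodes(a: float, b: float, n_panels: int):
    """Composite Gauss-Legendre nodes/weights on [a, b]."""
    edges = np.linspace(a, b, n_panels + 1)
    mid = 0.5 * (edges[:-1, None] + edges[1:, None])
    half = 0.5 * (edges[1:, None] - edges[:-1, None])
    x = (mid + half * _GL_NODES[None, :]).ravel()
    w = (half * _GL_WEIGHTS[None, :]).ravel()
    return x, w


def bilayer_energy(sol: BilayerSolution, components: bool = False):
    """Elastic energy of the horizontal region, k_BT.

    Integrates the energy density over rho in [R0, rho_max] with a composite
    Gauss-Legendre rule; rho_max is chosen from the asymptotic decay rate so
    that the neglected tail is below ~1e-8 k_BT.

    With ``components=True`` returns ``(W, dict)`` with the splay/tilt/
    stretch/tension split.
    """
    lipid, env = sol.lipid, sol.env
    R0 = sol.R0_applied
    if sol.c == 0:
        zero = {"splay": 0.0, "tilt": 0.0, "stretch": 0.0, "tension": 0.0}
        return (0.0, zero) if components else 0.0
    b = max(sol.decay_rate, 1e-3)
    span = max(30.0, 12.0 / b)
    n_panels = int(max(8, min(40, span * max(abs(sol.p1.real), 0.2) / 2.0)))
    rho, w = _quad_nodes(R0, R0 + span, n_panels)

    l2 = lipid.l2
    A = lipid.A
    J0 = lipid.J0
    sigma = env.sigma0 / lipid.K_t
    dv = sol.div(rho)
    t = sol.tilt(rho)
    al = sol.alpha(rho)
    pref = 2.0 * np.pi * lipid.K_t
    splay = pref * np.sum(w * rho * l2 * ((dv + J0) ** 2 - J0 * J0))
    tiltE = pref * np.sum(w * rho * t * t)
    stretch = pref * np.sum(w * rho * A * al * al)
    if sigma != 0.0:
        Hp = sol.H_prime(rho)
        tensionE = pref * np.sum(w * rho * sigma * Hp * Hp)
    else:
        tensionE = 0.0
    W = float(splay + tiltE + stretch + tensionE)
    if components:
        return W, {
            "splay": float(splay),
            "tilt": float(tiltE),
            "stretch": float(stretch),
            "tension": float(tensionE),
        }
    return W
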