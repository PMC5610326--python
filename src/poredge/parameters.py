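"""Unit system, physical constants, and the lipid/environment parameter registry.

Internal unit system: energy in units of k_BT, length in nm.  All surface
moduli and tensions are therefore carried in k_BT/nm^2, line tensions in
k_BT/nm, curvatures in 1/nm.  The conversion constant is fixed at
k_BT = 4.14e-21 J (T ~ 300 K), the value against which all registry numbers
are stated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "KBT_JOULES",
    "tension_to_internal",
    "tension_to_mN_per_m",
    "line_tension_to_pN",
    "pN_to_line_tension",
    "LipidParameters",
    "EnvironmentParameters",
    "get_lipid",
    "available_lipids",
    "make_lipid",
    "default_environment",
    "dopc_uncertainty_sets",
]

#: thermal energy quantum, joules
KBT_JOULES = 4.14e-21


def tension_to_internal(value_mN_per_m: float) -> float:
    """Convert a surface tension from mN/m to k_BT/nm^2.

    1 mN/m = 1e-3 J/m^2 = 1e-21 J/nm^2.
    """
    return value_mN_per_m * 1e-21 / KBT_JOULES


def tension_to_mN_per_m(value_kBT_nm2: float) -> float:
    """Inverse of :func:`tension_to_internal`."""
    return value_kBT_nm2 * KBT_JOULES / 1e-21


def line_tension_to_pN(value_kBT_nm: float) -> float:
    """Convert a line tension from k_BT/nm to pN (1 pN = 1e-21 J/nm)."""
    return value_kBT_nm * KBT_JOULES / 1e-21


def pN_to_line_tension(value_pN: float) -> float:
    """Convert a line tension from pN to k_BT/nm."""
    return value_pN * 1e-21 / KBT_JOULES


@dataclass(frozen=True)
class LipidParameters:
    """Elastic constants of one monolayer species, in internal units.

    Attributes
    ----------
    name : str
        Registry label.
    B : float
        Splay (bending) modulus per monolayer, k_BT.
    K_t : float
        Tilt modulus per monolayer, k_BT/nm^2.
    K_A : float
        Lateral stretch/compression modulus per monolayer, k_BT/nm^2.
    h : float
        Monolayer hydrophobic thickness, nm.
    J0 : float
        Monolayer spontaneous curvature, 1/nm (lysolipid-positive convention).
    """

    name: str
    B: float
    K_t: float
    K_A: float
    h: float
    J0: float

    def __post_init__(self) -> None:
        for attr in ("B", "K_t", "K_A", "h"):
            v = getattr(self, attr)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.name}: {attr} must be positive and finite, got {v}")
        if not math.isfinite(self.J0):
            raise ValueError(f"{self.name}: J0 must be finite")

    @property
    def l2(self) -> float:
        """Squared splay/tilt decay length l^2 = B/K_t, nm^2 (always recomputed)."""
        return self.B / self.K_t

    @property
    def A(self) -> float:
        """Dimensionless stretch/tilt modulus ratio A = K_A/K_t (always recomputed)."""
        return self.K_A / self.K_t

    def with_(self, **kwargs) -> "LipidParameters":
        """Return a copy with the given fields replaced (internal units)."""
        return replace(self, **kwargs)


def make_lipid(
    name: str,
    B_kBT: float,
    KA_mN_per_m: float,
    h_nm: float,
    J0_per_nm: float = 0.0,
    Kt_mN_per_m: float = 40.0,
) -> LipidParameters:
    """Build a :class:`LipidParameters` from the units used in the literature.

    The splay modulus is quoted directly in k_BT; area moduli in mN/m.
    """
    return LipidParameters(
        name=name,
        B=B_kBT,
        K_t=tension_to_internal(Kt_mN_per_m),
        K_A=tension_to_internal(KA_mN_per_m),
        h=h_nm,
        J0=J0_per_nm,
    )


# ---------------------------------------------------------------------------
# Registry.  A generic reference model lipid, single-parameter variants of it,
# and three experimentally characterised phosphatidylcholines.  The tilt
# modulus is 40 mN/m per monolayer for every species.
# ---------------------------------------------------------------------------
_REGISTRY: dict[str, LipidParameters] = {}


def _register(name, B_kBT, KA_mN_per_m, h_nm, J0_per_nm=0.0):
    _REGISTRY[name] = make_lipid(name, B_kBT, KA_mN_per_m, h_nm, J0_per_nm)


_register("reference", 8.0, 100.0, 2.0, 0.0)
# spontaneous-curvature variants of the reference lipid
_register("reference_J0+0.1", 8.0, 100.0, 2.0, +0.1)
_register("reference_J0-0.1", 8.0, 100.0, 2.0, -0.1)
# splay-modulus variants (x1.5 down/up)
_register("reference_B5.3", 5.3, 100.0, 2.0, 0.0)
_register("reference_B12", 12.0, 100.0, 2.0, 0.0)
# stretch-modulus variants
_register("reference_KA67", 8.0, 67.0, 2.0, 0.0)
_register("reference_KA150", 8.0, 150.0, 2.0, 0.0)
# thickness variants
_register("reference_h1.3", 8.0, 100.0, 1.3, 0.0)
_register("reference_h3", 8.0, 100.0, 3.0, 0.0)
# constant-B/h pair used for the line-tension scaling analysis
_register("reference_B5.3_h1.3", 5.3, 100.0, 1.3, 0.0)
_register("reference_B12_h3", 12.0, 100.0, 3.0, 0.0)
# experimentally characterised lipids.  DOPC spontaneous curvature: two
# published values exist (-0.091 and -0.11 nm^-1); -0.091 is the default and
# can be overridden via ``with_`` or a custom config.
_register("DOPC", 10.3, 133.0, 1.45, -0.091)
_register("POPC", 11.0, 117.0, 1.46, -0.022)
_register("DMPC", 6.8, 117.0, 1.37, +0.075)


def available_lipids() -> list[str]:
    return sorted(_REGISTRY)


def get_lipid(name: str) -> LipidParameters:
    """Look up a registered lipid parameter set by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown lipid {name!r}; available: {', '.join(available_lipids())}"
        ) from None


@dataclass(frozen=True)
class EnvironmentParameters:
    """Membrane environment: lateral tension and hydrophobic-belt parameters.

    Attributes
    ----------
    sigma0 : float
        Lateral tension applied to the membrane, k_BT/nm^2 (default 0).
    sigma_h : float
        Macroscopic interfacial tension between lipid tails and water,
        k_BT/nm^2 (default from 36 mN/m).
    xi_h : float
        Characteristic decay length of hydrophobic interactions, nm.
    """

    sigma0: float = 0.0
    sigma_h: float = field(default_factory=lambda: tension_to_internal(36.0))
    xi_h: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_h <= 0:
            raise ValueError("sigma_h must be positive")
        if self.xi_h <= 0:
            raise ValueError("xi_h must be positive")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")


def default_environment(
    sigma0_mN_per_m: float = 0.0,
    sigma_h_mN_per_m: float = 36.0,
    xi_h_nm: float = 1.0,
) -> EnvironmentParameters:
    """Environment in literature units (tensions in mN/m)."""
    return EnvironmentParameters(
        sigma0=tension_to_internal(sigma0_mN_per_m),
        sigma_h=tension_to_internal(sigma_h_mN_per_m),
        xi_h=xi_h_nm,
    )


# experimental confidence-interval half-widths for DOPC
_DOPC_UNCERTAINTY = {"B": 1.2, "KA": 9.0, "h": 0.02, "J0": 0.008}


def dopc_uncertainty_sets(include_center: bool = True) -> list[LipidParameters]:
    """All corner combinations of the DOPC experimental confidence intervals.

    The published DOPC elastic parameters carry confidence intervals
    (B = 10.3 +/- 1.2 k_BT, K_A = 133 +/- 9 mN/m, h = 1.45 +/- 0.02 nm,
    J0 = -0.091 +/- 0.008 nm^-1).  Which endpoint combinations bound the
    energy/line-tension envelope is not obvious a priori, so this returns the
    full 2^4 corner sweep (optionally plus the central set) for the caller to
    scan.
    """
    base = dict(B_kBT=10.3, KA_mN_per_m=133.0, h_nm=1.45, J0_per_nm=-0.091)
    out = [get_lipid("DOPC")] if include_center else []
    for sB, sKA, sh, sJ in itertools.product((-1, 1), repeat=4):
        out.append(
            make_lipid(
                f"DOPC[{sB:+d}B,{sKA:+d}KA,{sh:+d}h,{sJ:+d}J0]",
                base["B_kBT"] + sB * _DOPC_UNCERTAINTY["B"],
                base["KA_mN_per_m"] + sKA * _DOPC_UNCERTAINTY["KA"],
                base["h_nm"] + sh * _DOPC_UNCERTAINTY["h"],
                base["J0_per_nm"] + sJ * _DOPC_UNCERTAINTY["J0"],
            )
        )
    return out
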