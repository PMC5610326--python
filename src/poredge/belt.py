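"""Energy of the water-filled cylindrical hydrophobic belt.

The pre-pore ("hydrophobic defect") intermediate carries a cylindrical belt
of exposed lipid tails of radius r and height 2L.  Its cost follows from the
mean-field (Marcelja) description of water ordering next to a hydrophobic
surface, integrated over the cylinder interior:

    W_h = 4 pi r L sigma_h I1(r/xi_h) / I0(r/xi_h)

with I0, I1 modified Bessel functions of the first kind, sigma_h the
tail/water interfacial tension and xi_h the decay length of hydrophobic
interactions.  The Bessel ratio suppresses the cost of narrow channels,
whose lumen water cannot develop bulk-like ordering; for r >> xi_h the
energy approaches the macroscopic wetting cost 4 pi r L sigma_h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .parameters import EnvironmentParameters

__all__ = ["BeltSpec", "belt_energy", "bessel_ratio"]


@dataclass(frozen=True)
class BeltSpec:
    """Geometry and material constants of one hydrophobic belt."""

    r: float  # belt radius, nm
    L: float  # belt half-height, nm
    sigma_h: float  # tail/water interfacial tension, k_BT/nm^2
    xi_h: float  # hydrophobic decay length, nm

    def __post_init__(self) -> None:
        if self.r < 0 or self.L < 0:
            raise ValueError("belt radius and half-height must be non-negative")
        if self.sigma_h <= 0 or self.xi_h <= 0:
            raise ValueError("sigma_h and xi_h must be positive")


def bessel_ratio(x):
    """I1(x)/I0(x), evaluated with scaled Bessel functions (overflow-safe)."""
    x = np.asarray(x, dtype=float)
    return special.i1e(x) / special.i0e(x)


def belt_energy(spec: BeltSpec) -> float:
    """Belt energy W_h in k_BT; zero for a vanishing belt (r=0 or L=0)."""
    if spec.r == 0.0 or spec.L == 0.0:
        return 0.0
    return float(
        4.0 * np.pi * spec.r * spec.L * spec.sigma_h * bessel_ratio(spec.r / spec.xi_h)
    )


def belt_energy_rl(r: float, L: float, env: EnvironmentParameters) -> float:
    """Convenience wrapper taking radius/half-height and an environment."""
    if L == 0.0 or r == 0.0:
        return 0.0
    return belt_energy(BeltSpec(r=r, L=L, sigma_h=env.sigma_h, xi_h=env.xi_h))
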