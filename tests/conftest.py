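"""Shared fixtures.

The trajectory-level fixtures are session-scoped because each one runs
many junction optimizations; they are shared between the trajectory tests
and the acceptance tests.
"""

import warnings

import numpy as np
import pytest

from poredge import (
    default_environment,
    equal_energy_radius,
    get_lipid,
    optimal_trajectory,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def env():
    return default_environment()


@pytest.fixture(scope="session")
def reference():
    return get_lipid("reference")


@pytest.fixture(scope="session")
def reference_landscape(env):
    """Reference-lipid optimal trajectory through transition + metastable
    region (belt height optimized at small radii)."""
    r_grid = np.concatenate([np.arange(0.05, 1.201, 0.05), np.arange(1.3, 4.01, 0.1)])
    return optimal_trajectory(get_lipid("reference"), env, r_grid, belt_scan_rmax=1.0)


@pytest.fixture(scope="session")
def lipid_trajectories(env):
    """Hydrophilic-branch trajectories for the three real lipids."""
    r_grid = np.concatenate(
        [np.arange(1.2, 6.01, 0.2), np.array([7, 8, 10, 12, 15, 20, 30, 40, 50])]
    )
    return {
        name: optimal_trajectory(get_lipid(name), env, r_grid)
        for name in ("DOPC", "POPC", "DMPC")
    }


@pytest.fixture(scope="session")
def degeneracy_scan(env):
    """Radius where hydrophilic pore and hydrophobic defect are degenerate,
    with the belt-height scan there."""
    return equal_energy_radius(get_lipid("reference"), env)


@pytest.fixture(scope="session")
def j0_forward_barriers(env):
    """Forward barriers for the spontaneous-curvature variants (coarse grids)."""
    r_grid = np.concatenate([np.arange(0.1, 1.21, 0.1), np.arange(1.4, 2.61, 0.2)])
    out = {}
    for name in ("reference_J0-0.1", "reference", "reference_J0+0.1"):
        traj = optimal_trajectory(
            get_lipid(name), env, r_grid, belt_scan_rmax=1.0, L_step=0.15
        )
        out[name] = traj.features.barrier_forward
    return out
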