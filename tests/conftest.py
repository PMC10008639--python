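"""Shared fixtures: small synthetic systems generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from aquaswing import synthetic as syn


@pytest.fixture(scope="session")
def ice_box():
    """Pristine 3×3×3 cubic-ice box: every molecule (2,2)-coordinated."""
    traj, truth = syn.synthetic_water_box(syn.LatticePlan(n_cells=(3, 3, 3)))
    return traj, truth


@pytest.fixture(scope="session")
def defect_box():
    """Ice box with ~10% planted coordination defects."""
    traj, truth = syn.synthetic_water_box(
        syn.LatticePlan(n_cells=(3, 3, 3), defect_fraction=0.10, seed=7)
    )
    return traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
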