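"""Shared fixtures: phantoms, recovery networks, traced results.

Expensive artifacts (Laplace solves, skeletonizations over 10 seeded
networks) are session-scoped so module tests and the acceptance suite
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from vasculomap.flatmap import build_projection, solve_laplace
from vasculomap.synthetic import (
    generate_cortex_phantom,
    generate_recovery_network,
    rasterize_tubes,
)
from vasculomap.trace import trace_vessels
from vasculomap.volume import VoxelVolume

RECOVERY_SEEDS = tuple(range(10))
RECOVERY_EXTENT = 200.0


@pytest.fixture(scope="session")
def slab_phantom():
    return generate_cortex_phantom(
        "slab", [0.1, 0.2, 0.3, 0.3, 0.1], (400, 500, 200), 10.0
    )


@pytest.fixture(scope="session")
def slab_field(slab_phantom):
    return solve_laplace(slab_phantom)


@pytest.fixture(scope="session")
def slab_projection(slab_field, slab_phantom):
    return build_projection(slab_field, slab_phantom)


@pytest.fixture(scope="session")
def cylinder_phantom():
    return generate_cortex_phantom(
        "half_cylinder", [0.1, 0.2, 0.3, 0.3, 0.1], (1000, 600, 200), 10.0
    )


@pytest.fixture(scope="session")
def cylinder_field(cylinder_phantom):
    return solve_laplace(cylinder_phantom)


@pytest.fixture(scope="session")
def cylinder_projection(cylinder_field, cylinder_phantom):
    return build_projection(cylinder_field, cylinder_phantom)


def run_recovery(seed: int):
    """Ground-truth network → rasterize → trace; returns (truth, traced)."""
    truth = generate_recovery_network(extent=RECOVERY_EXTENT, rng=seed)
    shape = (int(RECOVERY_EXTENT),) * 3
    mask = VoxelVolume(
        rasterize_tubes(truth.graph, shape, (1.0, 1.0, 1.0)), (1.0, 1.0, 1.0)
    )
    traced = trace_vessels(mask.like(mask.data.astype(bool)))
    return truth, traced


@pytest.fixture(scope="session")
def recovery_results():
    return [run_recovery(seed) for seed in RECOVERY_SEEDS]
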