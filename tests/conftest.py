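"""Shared fixtures.

Session-scoped fixtures cache the (deterministic) default mesh and its
reduced beam geometry, which several simulation-based tests reuse.  The
``small_config`` fixture is a coarse, fast variant for structural tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tendonwave.constitutive import MaterialParams
from tendonwave.geometry import MeshConfig, build_mesh, generate_butterfly_mesh
from tendonwave.loading import (
    LoadCase,
    distal_subtendon_areas,
    partition_cohort_forces,
)
from tendonwave.wave_sim import beam_geometry_from_mesh


@pytest.fixture(scope="session")
def params() -> MaterialParams:
    return MaterialParams.default()


@pytest.fixture(scope="session")
def default_mesh():
    """Untwisted default-resolution mesh (reference element counts)."""
    return generate_butterfly_mesh(MeshConfig())


@pytest.fixture(scope="session")
def default_geometry(default_mesh):
    """Reduced beam geometry of the fibre-assigned untwisted default mesh."""
    from tendonwave.geometry import assign_fiber_directions

    mesh = assign_fiber_directions(
        generate_butterfly_mesh(MeshConfig())
    )
    return beam_geometry_from_mesh(mesh)


@pytest.fixture
def small_config() -> MeshConfig:
    """Coarse mesh configuration for fast structural tests."""
    return MeshConfig(
        n_slices=6,
        sector_divisions={"LG": (3, 3), "MG": (3, 2), "S": (2, 3)},
    )


@pytest.fixture
def small_mesh(small_config):
    return build_mesh(small_config)


@pytest.fixture
def untapered_config() -> MeshConfig:
    """Prismatic (no taper) coarse configuration; fibre/centroid geometry
    has exact closed forms without the taper."""
    return MeshConfig(
        distal_width=20.0,
        distal_thickness=8.0,
        proximal_width=20.0,
        proximal_thickness=8.0,
        n_slices=8,
        sector_divisions={"LG": (3, 3), "MG": (3, 2), "S": (2, 3)},
    )


def make_case(
    total_force: float,
    ratio: float = 1.0,
    cohort: str = "test",
    twist_deg: float = 0.0,
    areas=None,
) -> LoadCase:
    """Build a load case from a total force (helper, not a fixture)."""
    if areas is None:
        areas = distal_subtendon_areas()
    stresses, forces = partition_cohort_forces(total_force, areas, ratio)
    return LoadCase(
        cohort=cohort,
        twist_deg=twist_deg,
        increment=0,
        ratio=ratio,
        total_force=total_force,
        areas_mm2=areas,
        stresses=stresses,
        forces=forces,
    )


@pytest.fixture
def case_factory():
    return make_case
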