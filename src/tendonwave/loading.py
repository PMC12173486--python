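"""Gait-cycle load cases for the three differential-loading cohorts.

Three cohorts are simulated: uniform loading (soleus-to-gastrocnemius
stress ratio 1), soleus doubled (ratio 2) and soleus halved (ratio 0.5).
The two gastrocnemius subtendons are always loaded identically, and the
total tendon force at each gait increment is conserved across cohorts.
Axial stresses are determined a priori from the undeformed cross-sectional
areas at the distal end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tendonwave.geometry import SUBTENDONS, MeshConfig

__all__ = [
    "COHORT_RATIOS",
    "GaitProfile",
    "LoadCase",
    "distal_subtendon_areas",
    "partition_cohort_forces",
    "build_batch",
    "batch_manifest",
]

#: soleus-to-gastrocnemius axial stress ratio per cohort
COHORT_RATIOS = {"uniform": 1.0, "soleus_double": 2.0, "soleus_half": 0.5}

DEFAULT_TWIST_GRID = tuple(range(0, 181, 10))  # 19 conditions


@dataclass(frozen=True)
class GaitProfile:
    """Total triceps-surae force (N) at successive gait-cycle increments."""

    forces: np.ndarray

    def __post_init__(self) -> None:
        forces = np.asarray(self.forces, dtype=float)
        if forces.ndim != 1 or forces.size < 1:
            raise ValueError("forces must be a non-empty 1-D array")
        if np.any(forces < 0):
            raise ValueError("forces must be non-negative")
        object.__setattr__(self, "forces", forces)

    @property
    def n_increments(self) -> int:
        return int(self.forces.size)


@dataclass(frozen=True)
class LoadCase:
    """Per-subtendon loading at one gait increment for one cohort/twist."""

    cohort: str
    twist_deg: float
    increment: int
    ratio: float
    total_force: float  # N
    areas_mm2: dict  # per subtendon, undeformed distal cross-section
    stresses: dict  # per subtendon, Pa
    forces: dict  # per subtendon, N


def distal_subtendon_areas(config: MeshConfig | None = None) -> dict:
    """Undeformed distal cross-sectional area (mm^2) of each subtendon."""
    if config is None:
        config = MeshConfig()
    a, b = config.semi_axes(0.0)
    total = np.pi * float(a) * float(b)
    return {lab: total * config.csa_fractions[lab] for lab in SUBTENDONS}


def partition_cohort_forces(
    total_force: float,
    areas_mm2: dict,
    ratio: float,
) -> tuple[dict, dict]:
    """Split a total tendon force into per-subtendon stresses and forces.

    The soleus-to-gastrocnemius stress ratio is prescribed while the total
    force is conserved:

        sigma_G = F_total / (A_LG + A_MG + ratio * A_S)
        sigma_S = ratio * sigma_G

    with the lateral and medial gastrocnemius loaded identically.  Areas in
    mm^2; returns ``(stresses_pa, forces_n)`` dictionaries.
    """
    if total_force < 0:
        raise ValueError("total force must be non-negative")
    if ratio <= 0:
        raise ValueError("stress ratio must be positive")
    if set(areas_mm2) != set(SUBTENDONS):
        raise ValueError(f"areas must be keyed by {SUBTENDONS}")
    if any(a <= 0 for a in areas_mm2.values()):
        raise ValueError("all areas must be positive")
    denom_m2 = (
        areas_mm2["LG"] + areas_mm2["MG"] + ratio * areas_mm2["S"]
    ) * 1e-6
    sigma_g = total_force / denom_m2
    stresses = {"LG": sigma_g, "MG": sigma_g, "S": ratio * sigma_g}
    forces = {lab: stresses[lab] * areas_mm2[lab] * 1e-6 for lab in SUBTENDONS}
    return stresses, forces


def build_batch(
    cohorts=tuple(COHORT_RATIOS),
    twist_grid=DEFAULT_TWIST_GRID,
    profile: GaitProfile | None = None,
    areas_mm2: dict | None = None,
) -> list[LoadCase]:
    """One load case per (cohort, twist, gait increment), deterministic order.

    The default twist grid (0..180 degrees in 10-degree steps) crossed with
    a 100-increment profile yields 1900 cases per cohort.
    """
    if profile is None:
        from tendonwave.synthetic_data import synth_gait_profile

        profile = synth_gait_profile()
    if areas_mm2 is None:
        areas_mm2 = distal_subtendon_areas()
    twist_grid = list(twist_grid)
    if len(twist_grid) == 0:
        raise ValueError("twist grid must not be empty")
    cases = []
    for cohort in cohorts:
        ratio = COHORT_RATIOS[cohort] if isinstance(cohort, str) else float(cohort)
        name = cohort if isinstance(cohort, str) else f"ratio_{ratio:g}"
        for twist in twist_grid:
            for inc, force in enumerate(profile.forces):
                stresses, forces = partition_cohort_forces(float(force), areas_mm2, ratio)
                cases.append(
                    LoadCase(
                        cohort=name,
                        twist_deg=float(twist),
                        increment=inc,
                        ratio=ratio,
                        total_force=float(force),
                        areas_mm2=dict(areas_mm2),
                        stresses=stresses,
                        forces=forces,
                    )
                )
    return cases


def batch_manifest(cases: list[LoadCase]) -> pd.DataFrame:
    """Tidy manifest: one row per model spec with per-subtendon sigma and F."""
    rows = []
    for case in cases:
        row = {
            "cohort": case.cohort,
            "twist_deg": case.twist_deg,
            "increment": case.increment,
            "ratio": case.ratio,
            "total_force_n": case.total_force,
        }
        for lab in SUBTENDONS:
            row[f"sigma_{lab}_pa"] = case.stresses[lab]
            row[f"force_{lab}_n"] = case.forces[lab]
            row[f"area_{lab}_mm2"] = case.areas_mm2[lab]
        rows.append(row)
    return pd.DataFrame(rows)
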