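"""End-to-end orchestration: generate -> load -> simulate -> estimate -> regress."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tendonwave.constitutive import MaterialParams
from tendonwave.geometry import SUBTENDONS, MeshConfig, build_mesh
from tendonwave.loading import (
    COHORT_RATIOS,
    GaitProfile,
    LoadCase,
    batch_manifest,
    build_batch,
    distal_subtendon_areas,
)
from tendonwave.regression import fit_wave_speed_stress, results_table
from tendonwave.synthetic_data import synth_gait_profile
from tendonwave.wave_sim import (
    DEFAULT_COUPLING_COEFF,
    ExcitationSpec,
    beam_geometry_from_mesh,
    make_assembly,
    simulate_coupled_beams,
)
from tendonwave.wavespeed import estimate_speed_robust

__all__ = ["RunConfig", "SweepResult", "run_sweep"]

log = logging.getLogger("tendonwave")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one end-to-end sweep."""

    cohorts: tuple = tuple(COHORT_RATIOS)
    twist_grid: tuple = (0.0, 60.0, 120.0, 180.0)
    n_increments: int = 20
    peak_force: float = 3300.0
    peak_location: float = 0.45
    coupling_coeff: float = DEFAULT_COUPLING_COEFF
    kprime: float = 1.0
    min_stress_pa: float = 0.0
    n_beam_points: int | None = None
    duration: float = 1.0e-3
    dt_out: float = 1.0e-5
    use_filter: bool = True
    seed: int = 0
    mesh: dict = field(default_factory=dict)  # MeshConfig overrides
    material: dict | None = None  # MPa-convention document, None = defaults
    out_dir: str | None = None

    def mesh_config(self, twist_deg: float = 0.0) -> MeshConfig:
        return MeshConfig(**{**self.mesh, "twist_deg": twist_deg})

    def material_params(self) -> MaterialParams:
        if self.material is None:
            return MaterialParams.default()
        return MaterialParams.from_json(json.dumps(self.material))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=list)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else str(source))
        for key in ("cohorts", "twist_grid"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class SweepResult:
    """Per-increment speeds and per-condition regressions of one sweep."""

    speeds: pd.DataFrame
    regressions: pd.DataFrame
    manifest: pd.DataFrame
    errors: list

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.speeds.to_csv(out_dir / "speeds.csv", index=False)
        self.regressions.to_csv(out_dir / "regressions.csv", index=False)
        self.manifest.to_csv(out_dir / "manifest.csv", index=False)


def run_sweep(config: RunConfig) -> SweepResult:
    """Run the full chain for every (cohort, twist, increment).

    Produces the wave-speed-versus-gait series and the squared-speed/stress
    regression table per (cohort, twist, subtendon).  Deterministic given
    the configuration.  Per-case estimation failures are collected in
    ``errors`` and the run continues.
    """
    params = config.material_params()
    profile: GaitProfile = synth_gait_profile(
        n=config.n_increments,
        peak_force=config.peak_force,
        peak_location=config.peak_location,
        seed=config.seed,
    )
    areas = distal_subtendon_areas(config.mesh_config(0.0))
    excitation = ExcitationSpec()
    cases = build_batch(
        cohorts=config.cohorts,
        twist_grid=config.twist_grid,
        profile=profile,
        areas_mm2=areas,
    )
    manifest = batch_manifest(cases)

    geom_cache: dict = {}
    speed_rows = []
    errors: list = []
    for case in cases:
        if case.twist_deg not in geom_cache:
            log.info("meshing twist %g deg", case.twist_deg)
            mesh = build_mesh(config.mesh_config(case.twist_deg))
            geom_cache[case.twist_deg] = beam_geometry_from_mesh(
                mesh, n_points=config.n_beam_points
            )
        geom = geom_cache[case.twist_deg]
        try:
            assembly = make_assembly(
                geom, case, params,
                kprime=config.kprime, coupling_coeff=config.coupling_coeff,
            )
            result = simulate_coupled_beams(
                assembly, excitation,
                duration=config.duration, dt_out=config.dt_out,
            )
            for lab in SUBTENDONS:
                est = estimate_speed_robust(result[lab], use_filter=config.use_filter)
                speed_rows.append(
                    {
                        "cohort": case.cohort,
                        "twist_deg": case.twist_deg,
                        "increment": case.increment,
                        "subtendon": lab,
                        "sigma_pa": case.stresses[lab],
                        "speed_m_s": est.speed,
                        "peak_angle_deg": est.peak_angle_deg,
                        "flags": ";".join(est.flags),
                    }
                )
        except Exception as exc:  # keep sweeping on per-case failure
            errors.append(
                {
                    "cohort": case.cohort,
                    "twist_deg": case.twist_deg,
                    "increment": case.increment,
                    "error": str(exc),
                }
            )
    speeds = pd.DataFrame(speed_rows)

    reg_results = []
    if not speeds.empty:
        grouped = speeds[speeds["flags"] == ""].groupby(
            ["cohort", "twist_deg", "subtendon"], sort=True
        )
        for (cohort, twist, lab), g in grouped:
            g = g[g["sigma_pa"] >= config.min_stress_pa]
            if len(g) < 3:
                continue
            try:
                reg_results.append(
                    fit_wave_speed_stress(
                        g["speed_m_s"].to_numpy(),
                        g["sigma_pa"].to_numpy(),
                        subtendon=lab,
                        cohort=cohort,
                        twist_deg=twist,
                    )
                )
            except ValueError as exc:
                errors.append(
                    {"cohort": cohort, "twist_deg": twist, "error": str(exc)}
                )
    result = SweepResult(
        speeds=speeds,
        regressions=results_table(reg_results),
        manifest=manifest,
        errors=errors,
    )
    if config.out_dir:
        result.write(config.out_dir)
        Path(config.out_dir, "config.json").write_text(config.to_json() + "\n")
    return result
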