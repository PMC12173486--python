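# tendonwave

Shear-wave tensiometry simulation and analysis for a three-subtendon
Achilles tendon model.

The package builds a tapered, elliptical free-tendon geometry partitioned
into the lateral gastrocnemius (LG), medial gastrocnemius (MG) and soleus
(S) subtendons, applies helical twist, constructs gait-cycle load cases
for three differential-loading cohorts, propagates transverse waves
through a reduced-order model of three coupled tensioned beams, measures
wave speeds from spatiotemporal displacement maps (directional filtering +
Radon transform + Gaussian peak fit), and fits the tensioned-beam
relationship `sigma = rho_eff * c^2 - k'*mu` to recover effective density
and the shear-correction intercept.  A FEBio 4.x writer exports any model
specification for full-fidelity 3-D dynamic finite-element solves on an
external solver; plain-text nodal displacement logs can be read back into
the same estimation pipeline.

## Modules

| module | purpose |
| --- | --- |
| `tendonwave.constitutive` | fibre-reinforced material law, derived constants, closed-form tensioned-beam wave speed |
| `tendonwave.geometry` | butterfly hex meshes with exact per-subtendon element counts (22140/13500/16200), helical twist, fibre directions, centroid lines, contact adjacency |
| `tendonwave.loading` | cohort stress partitioning and 3 x 1900 batch building |
| `tendonwave.wave_sim` | explicit central-difference integration of three coupled tensioned beams |
| `tendonwave.wavespeed` | directional filter, Radon wave-speed estimator, map assembly |
| `tendonwave.regression` | stress-on-squared-speed OLS, effective-density table, +/-10 % deviation flag |
| `tendonwave.febio_io` | deterministic FEBio .feb writer, plain-text node-log reader |
| `tendonwave.synthetic_data` | gait force profiles and ground-truth plane-wave maps |
| `tendonwave.pipeline` / `tendonwave.cli` | end-to-end sweeps and the `tendonwave` command |

## CLI

```bash
tendonwave mesh --twist 90 --out mesh.vtk          # export geometry (legacy VTK)
tendonwave batch --out manifest.csv                # 5700-row model-spec manifest
tendonwave simulate --cohort soleus_double --twist 60 --out-dir maps
tendonwave estimate maps/map_soleus_double_twist60_LG.csv [--no-filter]
tendonwave regress speeds.csv --out regressions.csv
tendonwave sweep --config run.json --out-dir sweep_out
tendonwave export-feb --cohort uniform --twist 0 --increments 3
```

All configurations are JSON; tabular outputs are CSV.  Spatiotemporal
maps are stored as commented CSV or HDF5.

## Conventions

- SI units internally (Pa, m, s, kg/m^3); mesh coordinates in mm; FEBio
  files in the mm/N/MPa/tonne/s convention.
- x = medial-lateral (width), y = anterior-posterior (thickness),
  z = tendon axis with the distal end at z = 0; twist rotates the distal
  cross-section while the proximal end stays fixed.
- The reduced contact model couples beams through a distributed stiffness
  `kappa(z) = coeff * mu * boundary_length(z) / thickness(z)`; `coeff = 0`
  is free sliding, large values approach the bonded composite.
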