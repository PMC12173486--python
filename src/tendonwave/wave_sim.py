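"""Reduced-order wave propagation: three coupled tensioned shear beams.

Each subtendon is collapsed onto its centroid line and treated as a
tensioned beam carrying transverse displacement u(x, t):

    rho*A * u_tt = d/dx[ (sigma + k'*mu)*A * u_x ] - sum_j kappa_ij (u_i - u_j)

The effective tension combines the axial stress contribution sigma*A with
the shear restoring term k'*mu*A of the tensioned-beam model, so the
uncoupled wave speed is exactly the closed-form sqrt((sigma + k'*mu)/rho).
Frictionless inter-subtendon contact is reduced to a distributed
displacement coupling kappa(z) proportional to the shared sector boundary
length; kappa = 0 recovers freely sliding subtendons and large kappa the
bonded (composite) limit.

Integration is explicit central-difference with the distal node
displacement-driven (half-sine) and the proximal node free (reflective by
design, so the directional filter downstream has reflections to remove).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from tendonwave.constitutive import MaterialParams, matrix_shear_modulus
from tendonwave.geometry import (
    SUBTENDONS,
    Mesh,
    centroid_line,
    contact_adjacency,
)
from tendonwave.loading import LoadCase
from tendonwave.maps import SpatioTemporalMap

__all__ = [
    "ExcitationSpec",
    "half_sine_excitation",
    "BeamGeometry",
    "BeamAssembly",
    "beam_geometry_from_mesh",
    "make_assembly",
    "simulate_coupled_beams",
    "SimulationResult",
]

# Dimensionless closure of the reduced contact model: kappa(z) =
# coeff * mu * shared_boundary_length(z) / section_thickness(z).
# 0 recovers free sliding; values >> 1 approach the bonded composite.
# 1.0 is the smallest order-of-magnitude at which adjacent-subtendon drag
# (slower neighbour slows a faster subtendon) dominates the elastic-
# foundation stiffening that any finite coupling also introduces.
DEFAULT_COUPLING_COEFF = 1.0


@dataclass(frozen=True)
class ExcitationSpec:
    """Impulsive distal excitation: half-sine displacement pulse."""

    amplitude: float = 20.0e-6  # m
    half_period: float = 250.0e-6  # s
    direction: str = "y"

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.half_period <= 0:
            raise ValueError("amplitude must be non-negative and half_period positive")


def half_sine_excitation(t, spec: ExcitationSpec | None = None):
    """Prescribed distal displacement ``A*sin(pi*t/T)`` for ``0 <= t <= T``."""
    if spec is None:
        spec = ExcitationSpec()
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("time must be non-negative")
    inside = tt <= spec.half_period
    out = np.where(
        inside,
        spec.amplitude * np.sin(np.pi * np.minimum(tt, spec.half_period) / spec.half_period),
        0.0,
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class BeamGeometry:
    """Load-independent reduced geometry extracted from a mesh.

    Arrays are sampled at ``n_points`` uniform stations along each
    subtendon centroid path (SI units).  ``coupling_shape`` holds the
    dimensionless per-pair profile (shared boundary length / section
    thickness scale); multiplying by ``coeff * mu`` yields the distributed
    coupling stiffness in N/m^2.
    """

    labels: tuple
    n_points: int
    path_length: dict  # label -> m
    area: dict  # label -> (n_points,) m^2
    coupling_shape: dict  # (lab_a, lab_b) -> (n_points,) dimensionless
    twist_deg: float = 0.0


def beam_geometry_from_mesh(mesh: Mesh, n_points: int | None = None) -> BeamGeometry:
    """Sample centroid-path lengths, areas and contact weights from a mesh.

    ``n_points`` defaults to ``4 * n_slices + 1`` (the centroid path is
    refined for estimator resolution while inheriting the mesh topology).
    """
    cfg = mesh.config
    if n_points is None:
        n_points = 4 * cfg.n_slices + 1
    if n_points < 8:
        raise ValueError("need at least 8 stations along the beam")
    z = mesh.slice_z()
    a_mm, b_mm = cfg.semi_axes(z)
    adjacency = contact_adjacency(mesh)  # mm per slice
    s_uniform = np.linspace(0.0, 1.0, n_points)

    path_length: dict = {}
    area: dict = {}
    slice_frac = {}
    for lab in SUBTENDONS:
        path = centroid_line(mesh, lab)
        arc = path.arc_positions()  # mm
        path_length[lab] = float(arc[-1]) * 1e-3
        frac = arc / arc[-1]
        slice_frac[lab] = frac
        area_slices = cfg.csa_fractions[lab] * np.pi * a_mm * b_mm * 1e-6  # m^2
        area[lab] = np.interp(s_uniform, frac, area_slices)

    coupling_shape: dict = {}
    thickness_scale = b_mm  # transverse gap scale of the section, mm
    for pair, lengths in adjacency.items():
        shape_slices = np.asarray(lengths, dtype=float) / thickness_scale
        # sample on the mean normalized coordinate of the two members
        frac = 0.5 * (slice_frac[pair[0]] + slice_frac[pair[1]])
        coupling_shape[pair] = np.interp(s_uniform, frac, shape_slices)

    return BeamGeometry(
        labels=SUBTENDONS,
        n_points=n_points,
        path_length=path_length,
        area=area,
        coupling_shape=coupling_shape,
        twist_deg=mesh.twist_applied_deg,
    )


@dataclass
class BeamAssembly:
    """Three coupled tensioned beams ready for explicit integration.

    Per subtendon: station positions along the centroid path, linear mass
    density ``rho*A`` (kg/m) and tension ``(sigma + k'*mu)*A`` (N).
    ``kappa`` is the symmetric non-negative pairwise coupling stiffness per
    unit length (N/m^2).
    """

    labels: tuple
    x: dict  # label -> (n,) m
    mass: dict  # label -> (n,) kg/m
    tension: dict  # label -> (n,) N
    kappa: dict  # (lab_a, lab_b) -> (n,) N/m^2
    stresses: dict  # label -> Pa (nominal, for metadata)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab in self.labels:
            if np.any(self.tension[lab] < 0):
                raise ValueError("tension must be non-negative")
        for pair, k in self.kappa.items():
            if np.any(np.asarray(k) < 0):
                raise ValueError(f"coupling stiffness for {pair} must be non-negative")

    @property
    def n_points(self) -> int:
        return next(iter(self.x.values())).size

    def dx(self, label: str) -> float:
        x = self.x[label]
        return float(x[1] - x[0])

    def max_wave_speed(self) -> float:
        return max(
            float(np.sqrt(np.max(self.tension[lab] / self.mass[lab])))
            for lab in self.labels
        )

    def stable_dt(self) -> float:
        """Explicit central-difference stability bound."""
        dt_adv = min(
            self.dx(lab) / np.sqrt(np.max(self.tension[lab] / self.mass[lab]))
            for lab in self.labels
        )
        # stiffness of the coupling springs
        omega2 = 0.0
        for lab in self.labels:
            k_tot = np.zeros(self.n_points)
            for pair, k in self.kappa.items():
                if lab in pair:
                    k_tot = k_tot + np.asarray(k)
            with np.errstate(divide="ignore", invalid="ignore"):
                w2 = np.max(2.0 * k_tot / self.mass[lab])
            omega2 = max(omega2, float(w2))
        dt_cpl = 2.0 / np.sqrt(omega2) if omega2 > 0 else np.inf
        return min(dt_adv, dt_cpl)


def make_assembly(
    geometry: BeamGeometry,
    case: LoadCase,
    params: MaterialParams | None = None,
    kprime: float = 1.0,
    coupling_coeff: float = DEFAULT_COUPLING_COEFF,
) -> BeamAssembly:
    """Combine reduced geometry with a load case into a beam assembly.

    The nominal axial stress of each subtendon is applied uniformly along
    its beam, so the uncoupled propagation speed equals the closed-form
    tensioned-beam speed for that stress.
    """
    if params is None:
        params = MaterialParams.default()
    if coupling_coeff < 0:
        raise ValueError("coupling coefficient must be non-negative")
    mu = matrix_shear_modulus(params)
    n = geometry.n_points
    x, mass, tension = {}, {}, {}
    for lab in geometry.labels:
        x[lab] = np.linspace(0.0, geometry.path_length[lab], n)
        mass[lab] = params.rho * geometry.area[lab]
        tension[lab] = (case.stresses[lab] + kprime * mu) * geometry.area[lab]
    kappa = {
        pair: coupling_coeff * mu * shape
        for pair, shape in geometry.coupling_shape.items()
    }
    return BeamAssembly(
        labels=geometry.labels,
        x=x,
        mass=mass,
        tension=tension,
        kappa=kappa,
        stresses=dict(case.stresses),
        meta={
            "cohort": case.cohort,
            "twist_deg": geometry.twist_deg,
            "increment": case.increment,
            "kprime": kprime,
            "coupling_coeff": coupling_coeff,
            "mu_pa": mu,
            "rho": params.rho,
        },
    )


def assembly_from_mesh(
    mesh: Mesh,
    case: LoadCase,
    params: MaterialParams | None = None,
    kprime: float = 1.0,
    coupling_coeff: float = DEFAULT_COUPLING_COEFF,
    n_points: int | None = None,
) -> BeamAssembly:
    """Convenience: :func:`beam_geometry_from_mesh` + :func:`make_assembly`."""
    geom = beam_geometry_from_mesh(mesh, n_points=n_points)
    return make_assembly(geom, case, params, kprime, coupling_coeff)


@dataclass
class SimulationResult:
    """Output bundle of one dynamic solve."""

    maps: dict  # label -> SpatioTemporalMap
    dt_internal: float
    times: np.ndarray  # output sample times, s
    energy: np.ndarray | None = None  # total discrete energy per output frame

    def __getitem__(self, label: str) -> SpatioTemporalMap:
        return self.maps[label]


def simulate_coupled_beams(
    assembly: BeamAssembly,
    excitation: ExcitationSpec | None = None,
    duration: float = 1.0e-3,
    dt_out: float = 1.0e-5,
    dt_internal: float | None = None,
    record_energy: bool = False,
) -> SimulationResult:
    """Explicit central-difference integration of the coupled beam system.

    The distal station of every beam is displacement-driven by the
    excitation (plane excitation across the whole distal cross-section);
    the proximal station is free.  Output is sampled every ``dt_out``
    (default 10 us) over ``duration`` (default 1 ms).  The internal step is
    half the explicit stability bound unless overridden; an override above
    the bound is rejected.
    """
    if excitation is None:
        excitation = ExcitationSpec()
    bound = assembly.stable_dt()
    if dt_internal is not None:
        if dt_internal > bound:
            raise ValueError(
                f"dt_internal={dt_internal:g} s violates the explicit stability "
                f"bound {bound:g} s"
            )
        dt_target = dt_internal
    else:
        dt_target = 0.5 * bound
    substeps = max(1, int(np.ceil(dt_out / dt_target)))
    dt = dt_out / substeps
    n_out = int(round(duration / dt_out)) + 1
    n_steps = (n_out - 1) * substeps

    labels = list(assembly.labels)
    n = assembly.n_points
    nb = len(labels)
    mass = np.stack([assembly.mass[lab] for lab in labels])  # (nb, n)
    tension = np.stack([assembly.tension[lab] for lab in labels])
    dxs = np.array([assembly.dx(lab) for lab in labels])[:, None]
    t_half = 0.5 * (tension[:, 1:] + tension[:, :-1])  # (nb, n-1)
    pair_idx = []
    pair_kappa = []
    for (la, lb), k in assembly.kappa.items():
        if la in labels and lb in labels:
            pair_idx.append((labels.index(la), labels.index(lb)))
            pair_kappa.append(np.asarray(k))

    u_prev = np.zeros((nb, n))
    u = np.zeros((nb, n))
    out = np.zeros((nb, n, n_out))
    energy = np.zeros(n_out) if record_energy else None

    def accel(u_arr):
        flux = t_half * (u_arr[:, 1:] - u_arr[:, :-1]) / dxs  # (nb, n-1)
        acc = np.zeros_like(u_arr)
        acc[:, 1:-1] = (flux[:, 1:] - flux[:, :-1]) / dxs
        acc[:, -1] = -flux[:, -1] / dxs[:, 0]  # free end
        for (ia, ib), k in zip(pair_idx, pair_kappa):
            f = k * (u_arr[ia] - u_arr[ib])
            acc[ia] -= f
            acc[ib] += f
        return acc / mass

    def total_energy(u_now, v_now):
        e = 0.0
        for i in range(nb):
            dx = dxs[i, 0]
            e += 0.5 * np.sum(mass[i] * v_now[i] ** 2) * dx
            grad = (u_now[i, 1:] - u_now[i, :-1]) / dx
            e += 0.5 * np.sum(t_half[i] * grad**2) * dx
        for (ia, ib), k in zip(pair_idx, pair_kappa):
            e += 0.5 * np.sum(k * (u_now[ia] - u_now[ib]) ** 2) * dxs[ia, 0]
        return e

    out[:, :, 0] = u
    frame = 1
    for step in range(1, n_steps + 1):
        t_new = step * dt
        acc = accel(u)
        u_next = 2.0 * u - u_prev + dt * dt * acc
        u_next[:, 0] = half_sine_excitation(t_new, excitation)
        if step % substeps == 0:
            out[:, :, frame] = u_next
            if record_energy:
                v_now = (u_next - u_prev) / (2.0 * dt)
                energy[frame] = total_energy(u, v_now)
            frame += 1
        u_prev, u = u, u_next

    times = np.arange(n_out) * dt_out
    maps = {}
    for i, lab in enumerate(labels):
        meta = dict(assembly.meta)
        meta.update(
            {
                "subtendon": lab,
                "sigma_pa": assembly.stresses[lab],
                "path_length_m": float(assembly.x[lab][-1]),
            }
        )
        maps[lab] = SpatioTemporalMap(
            u=out[i], dx=float(dxs[i, 0]), dt=dt_out, meta=meta
        )
    return SimulationResult(maps=maps, dt_internal=dt, times=times, energy=energy)
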