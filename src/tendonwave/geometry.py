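"""Tapered elliptical three-subtendon tendon meshes with helical twist.

The free-tendon cross-section is an ellipse, linearly tapered from the
distal end (z = 0) to the proximal end (z = length).  The cross-section is
partitioned into three angular sectors -- one per subtendon (lateral
gastrocnemius ``LG``, medial gastrocnemius ``MG``, soleus ``S``) -- whose
areas match configurable fractions exactly (angular extent is measured in
the elliptical parametric angle, for which sector area is proportional to
parametric span).

Each sector is meshed independently as a separate body (the subtendons
interact through sliding contact, not shared nodes) using a butterfly
pattern: the wedge apex region is covered by a three-quad midpoint
subdivision core, surrounded by a structured annulus block.  Wide sectors
are split into conforming sub-wedges so that no patch becomes re-entrant.
The default in-plane densities are chosen so that the per-subtendon
hexahedral element counts are exactly 22140 (LG) / 13500 (MG) / 16200 (S).

Coordinates: x = width (medial-lateral), y = thickness
(anterior-posterior), z = tendon axis with the distal end at z = 0.
Node coordinates are stored in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SUBTENDONS",
    "MeshConfig",
    "Mesh",
    "generate_butterfly_mesh",
    "apply_helical_twist",
    "assign_fiber_directions",
    "fibre_prestretch",
    "centroid_line",
    "CentroidPath",
    "contact_adjacency",
    "build_mesh",
    "export_vtk",
]

SUBTENDONS = ("LG", "MG", "S")

#: per-sector (core_division k, annulus radial layers) reproducing the
#: reference per-subtendon element counts with 27 axial slices.
_DEFAULT_DIVISIONS = {"LG": (10, 26), "MG": (10, 10), "S": (6, 16)}

#: sub-wedges wider than this parametric span (radians) are split in two.
_MAX_WEDGE_SPAN = 2.5

_MERGE_DECIMALS = 9


@dataclass(frozen=True)
class MeshConfig:
    """Geometry configuration of the composite tendon.

    Lengths in mm, angles in degrees.  ``csa_fractions`` are the
    per-subtendon cross-sectional area fractions (summing to 1); the
    in-plane mesh density is controlled independently through
    ``sector_divisions`` (per-subtendon ``(core_division, radial_layers)``)
    scaled by the global ``butterfly_density`` factor, because the
    reference element counts are not proportional to the area fractions.
    """

    distal_width: float = 22.04
    distal_thickness: float = 6.42
    proximal_width: float = 17.83
    proximal_thickness: float = 5.76
    length: float = 60.0
    twist_deg: float = 0.0
    n_slices: int = 27
    butterfly_density: float = 1.0
    csa_fractions: dict = field(
        default_factory=lambda: {"LG": 0.22, "MG": 0.26, "S": 0.52}
    )
    sector_divisions: dict | None = None
    core_radius_fraction: float = 0.4
    start_angle: float = 0.0
    twist_sense: int = 1

    def __post_init__(self) -> None:
        dims = (
            self.distal_width,
            self.distal_thickness,
            self.proximal_width,
            self.proximal_thickness,
            self.length,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all geometric dimensions must be positive")
        if not (0.0 <= self.twist_deg < 360.0):
            # anatomical range is 0-180 degrees; larger values are allowed
            # so that an applied twist can always be recorded in the config
            raise ValueError(f"twist must lie in [0, 360) degrees, got {self.twist_deg}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be at least 1")
        if set(self.csa_fractions) != set(SUBTENDONS):
            raise ValueError(f"csa_fractions must be keyed by {SUBTENDONS}")
        total = sum(self.csa_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"csa_fractions must sum to 1, got {total}")
        if any(f <= 0 for f in self.csa_fractions.values()):
            raise ValueError("all csa_fractions must be positive")
        if not (0 < self.core_radius_fraction < 1):
            raise ValueError("core_radius_fraction must lie in (0, 1)")
        if self.twist_sense not in (-1, 1):
            raise ValueError("twist_sense must be +1 or -1")

    def divisions(self) -> dict:
        """Resolved per-sector (core_division, radial_layers) after scaling."""
        base = self.sector_divisions or _DEFAULT_DIVISIONS
        out = {}
        for lab in SUBTENDONS:
            k, nr = base[lab]
            k = max(1, round(k * self.butterfly_density))
            nr = max(1, round(nr * self.butterfly_density))
            out[lab] = (int(k), int(nr))
        return out

    def semi_axes(self, z) -> tuple:
        """Linearly tapered ellipse semi-axes (a, b) in mm at axial position z."""
        f = np.asarray(z, dtype=float) / self.length
        a = 0.5 * (self.distal_width + (self.proximal_width - self.distal_width) * f)
        b = 0.5 * (
            self.distal_thickness
            + (self.proximal_thickness - self.distal_thickness) * f
        )
        return a, b

    def sector_bounds(self) -> dict:
        """Parametric angular span [t0, t1] (radians) of each sector."""
        bounds = {}
        t = self.start_angle
        for lab in SUBTENDONS:
            span = 2.0 * np.pi * self.csa_fractions[lab]
            bounds[lab] = (t, t + span)
            t += span
        return bounds


@dataclass
class Mesh:
    """Hexahedral three-subtendon mesh.

    ``nodes`` are (N, 3) coordinates in mm; ``hexes`` is (E, 8) 0-based
    connectivity with the first four nodes forming the lower-z quad face
    (counter-clockwise in the xy-plane) and the last four the matching
    upper face.  Subtendon bodies do not share nodes.
    """

    nodes: np.ndarray
    hexes: np.ndarray
    subtendon_label: np.ndarray  # (E,) unicode labels
    node_label: np.ndarray  # (N,) unicode labels
    slice_index: np.ndarray  # (N,) int
    config: MeshConfig
    fibre_dir: np.ndarray | None = None
    twist_applied_deg: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hexes.shape[0]

    def element_counts(self) -> dict:
        return {
            lab: int(np.sum(self.subtendon_label == lab)) for lab in SUBTENDONS
        }

    def slice_z(self) -> np.ndarray:
        """Axial coordinates of the mesh slices (distal first)."""
        return np.linspace(0.0, self.config.length, self.config.n_slices + 1)

    # -- geometric measures -------------------------------------------------

    def slice_areas(self, label: str | None = None) -> np.ndarray:
        """Cross-sectional polygon area (mm^2) at every slice.

        Computed from the node coordinates via the shoelace formula on the
        in-plane quad faces, so it is exactly invariant under the in-plane
        rotations used to impose helical twist.
        """
        if label is None:
            total = np.zeros(self.config.n_slices + 1)
            for lab in SUBTENDONS:
                total += self.slice_areas(lab)
            return total
        hexes = self.hexes[self.subtendon_label == label]
        per_slice = self.config.n_slices
        n_quads = hexes.shape[0] // per_slice
        areas = np.empty(per_slice + 1)
        for s in range(per_slice):
            quad = hexes[s * n_quads : (s + 1) * n_quads, :4]
            areas[s] = _shoelace_area(self.nodes[quad][:, :, :2])
        quad_top = hexes[(per_slice - 1) * n_quads :, 4:]
        areas[per_slice] = _shoelace_area(self.nodes[quad_top][:, :, :2])
        return areas

    def volume(self) -> float:
        """Total volume (mm^3) as the axial trapezoidal integral of the
        per-slice cross-sectional polygon area (Cavalieri)."""
        dz = self.config.length / self.config.n_slices
        areas = self.slice_areas()
        return float(np.trapezoid(areas, dx=dz))

    def corner_jacobians(self) -> np.ndarray:
        """Signed corner Jacobians (8 per hex); positive means non-inverted."""
        n = self.nodes[self.hexes]  # (E, 8, 3)
        # local edge triads at each corner of the trilinear hexahedron
        corner_edges = {
            0: (1, 3, 4),
            1: (2, 0, 5),
            2: (3, 1, 6),
            3: (0, 2, 7),
            4: (7, 5, 0),
            5: (4, 6, 1),
            6: (5, 7, 2),
            7: (6, 4, 3),
        }
        jac = np.empty((self.n_elements, 8))
        for c, (i, j, k) in corner_edges.items():
            e1 = n[:, i] - n[:, c]
            e2 = n[:, j] - n[:, c]
            e3 = n[:, k] - n[:, c]
            jac[:, c] = np.einsum("ij,ij->i", np.cross(e1, e2), e3)
        return jac


# ---------------------------------------------------------------------------
# 2-D butterfly templates (unit circle)
# ---------------------------------------------------------------------------


def _unit_point(t):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return np.stack([np.cos(t), np.sin(t)], axis=-1)


def _coons_patch(c00, c10, c11, c01, nu, nv, bottom=None, top=None, left=None, right=None):
    """Transfinite (Coons) patch on a quad with optionally curved edges.

    Edge callables take an array of parameters in [0, 1] and return (n, 2)
    points; straight edges are used when a callable is omitted.  Returns a
    grid of shape (nu+1, nv+1, 2).
    """
    c00, c10, c11, c01 = (np.asarray(c, dtype=float) for c in (c00, c10, c11, c01))
    u = np.linspace(0.0, 1.0, nu + 1)
    v = np.linspace(0.0, 1.0, nv + 1)

    def line(p, q):
        return lambda s: p[None, :] * (1.0 - s[:, None]) + q[None, :] * s[:, None]

    eb = (bottom or line(c00, c10))(u)  # (nu+1, 2)
    et = (top or line(c01, c11))(u)
    el = (left or line(c00, c01))(v)  # (nv+1, 2)
    er = (right or line(c10, c11))(v)

    U = u[:, None, None]
    V = v[None, :, None]
    surf = (
        (1.0 - V) * eb[:, None, :]
        + V * et[:, None, :]
        + (1.0 - U) * el[None, :, :]
        + U * er[None, :, :]
        - (
            (1.0 - U) * (1.0 - V) * c00
            + U * (1.0 - V) * c10
            + U * V * c11
            + (1.0 - U) * V * c01
        )
    )
    return surf


def _grid_quads(grid_ids):
    """Quad connectivity for a (nu+1, nv+1) array of node ids."""
    a = grid_ids[:-1, :-1].ravel()
    b = grid_ids[1:, :-1].ravel()
    c = grid_ids[1:, 1:].ravel()
    d = grid_ids[:-1, 1:].ravel()
    return np.stack([a, b, c, d], axis=1)


def _subwedge_template(ta: float, tb: float, k: int, n_r: int, alpha: float):
    """Butterfly mesh of one wedge of the unit disc between parametric
    angles ``ta < tb`` (span < pi): three-quad midpoint core + annulus.

    Returns (points, quads) with duplicated seam nodes (merged later).
    """
    tm = 0.5 * (ta + tb)
    A = np.zeros(2)
    D = alpha * _unit_point(ta)[0]
    E = alpha * _unit_point(tb)[0]
    Marc = alpha * _unit_point(tm)[0]
    M_AD = 0.5 * D
    M_AE = 0.5 * E
    G = 0.25 * (A + D + E + Marc)

    def arc(t_from, t_to, radius):
        return lambda s: radius * _unit_point(t_from + s * (t_to - t_from))

    patches = [
        _coons_patch(A, M_AD, G, M_AE, k, k),
        _coons_patch(M_AD, D, Marc, G, k, k, right=arc(ta, tm, alpha)),
        _coons_patch(G, Marc, E, M_AE, k, k, right=arc(tm, tb, alpha)),
    ]
    pts_list = []
    quads_list = []
    offset = 0
    for grid in patches:
        nu, nv = grid.shape[0] - 1, grid.shape[1] - 1
        ids = np.arange((nu + 1) * (nv + 1)).reshape(nu + 1, nv + 1) + offset
        pts_list.append(grid.reshape(-1, 2))
        quads_list.append(_grid_quads(ids))
        offset += (nu + 1) * (nv + 1)

    if n_r > 0:
        t = np.linspace(ta, tb, 2 * k + 1)
        r = alpha + (1.0 - alpha) * np.linspace(0.0, 1.0, n_r + 1)
        ring = r[None, :, None] * _unit_point(t)[:, None, :]  # (2k+1, nr+1, 2)
        ids = np.arange((2 * k + 1) * (n_r + 1)).reshape(2 * k + 1, n_r + 1) + offset
        pts_list.append(ring.reshape(-1, 2))
        quads_list.append(_grid_quads(ids))

    points = np.concatenate(pts_list, axis=0)
    quads = np.concatenate(quads_list, axis=0)
    return points, quads


def _merge_points(points, quads, decimals=_MERGE_DECIMALS):
    key = np.round(points, decimals)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    merged = points[first[order]]
    return merged, rank[inverse][quads]


def _orient_quads(points, quads):
    """Flip any clockwise quads so all have positive shoelace area."""
    p = points[quads]
    x, y = p[..., 0], p[..., 1]
    area2 = (
        x[:, 0] * (y[:, 1] - y[:, 3])
        + x[:, 1] * (y[:, 2] - y[:, 0])
        + x[:, 2] * (y[:, 3] - y[:, 1])
        + x[:, 3] * (y[:, 0] - y[:, 2])
    )
    flip = area2 < 0
    quads = quads.copy()
    quads[flip] = quads[flip][:, ::-1]
    return quads


def _sector_template(t0: float, t1: float, k: int, n_r: int, alpha: float):
    """Conforming butterfly template of a full sector (possibly split into
    sub-wedges).  Returns (points, quads) on the unit disc."""
    span = t1 - t0
    n_w = max(1, int(np.ceil(span / _MAX_WEDGE_SPAN)))
    edges = np.linspace(t0, t1, n_w + 1)
    pts_list, quads_list = [], []
    offset = 0
    for ta, tb in zip(edges[:-1], edges[1:]):
        p, q = _subwedge_template(float(ta), float(tb), k, n_r, alpha)
        pts_list.append(p)
        quads_list.append(q + offset)
        offset += p.shape[0]
    points = np.concatenate(pts_list, axis=0)
    quads = np.concatenate(quads_list, axis=0)
    points, quads = _merge_points(points, quads)
    quads = _orient_quads(points, quads)
    return points, quads


def _shoelace_area(quad_pts: np.ndarray) -> float:
    """Total area of a set of quads given as (Q, 4, 2) vertex coordinates."""
    x, y = quad_pts[..., 0], quad_pts[..., 1]
    area2 = (
        x[:, 0] * (y[:, 1] - y[:, 3])
        + x[:, 1] * (y[:, 2] - y[:, 0])
        + x[:, 2] * (y[:, 3] - y[:, 1])
        + x[:, 3] * (y[:, 0] - y[:, 2])
    )
    return float(0.5 * np.sum(area2))


def _quad_centroid_area(points, quads):
    """Area-weighted centroid and total area of a quad patch."""
    p = points[quads]  # (Q, 4, 2)
    cen = np.zeros(2)
    total = 0.0
    for i in range(4):
        a = p[:, i]
        b = p[:, (i + 1) % 4]
        cross = a[:, 0] * b[:, 1] - b[:, 0] * a[:, 1]
        total += np.sum(cross)
        cen += np.sum((a + b) * cross[:, None], axis=0)
    total *= 0.5
    cen /= 6.0 * total
    return cen, total


# ---------------------------------------------------------------------------
# mesh generation operations
# ---------------------------------------------------------------------------


def generate_butterfly_mesh(config: MeshConfig | None = None) -> Mesh:
    """Generate the untwisted tapered three-subtendon butterfly hex mesh.

    The elliptical cross-sections taper linearly from distal to proximal;
    each subtendon occupies an angular sector whose area matches its
    ``csa_fractions`` entry exactly.  The default configuration reproduces
    per-subtendon element counts of 22140 / 13500 / 16200.
    """
    if config is None:
        config = MeshConfig()
    bounds = config.sector_bounds()
    divisions = config.divisions()

    all_nodes, all_hexes = [], []
    elem_labels, node_labels, slice_idx = [], [], []
    node_offset = 0
    z = np.linspace(0.0, config.length, config.n_slices + 1)
    a, b = config.semi_axes(z)

    for lab in SUBTENDONS:
        t0, t1 = bounds[lab]
        k, n_r = divisions[lab]
        pts2d, quads = _sector_template(t0, t1, k, n_r, config.core_radius_fraction)
        m = pts2d.shape[0]
        # extrude: node (slice s, template node j) -> index s*m + j
        xs = a[:, None] * pts2d[None, :, 0]
        ys = b[:, None] * pts2d[None, :, 1]
        zs = np.broadcast_to(z[:, None], xs.shape)
        nodes = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3)

        q = quads[None, :, :] + (np.arange(config.n_slices) * m)[:, None, None]
        hexes = np.concatenate([q, q + m], axis=2).reshape(-1, 8)

        all_nodes.append(nodes)
        all_hexes.append(hexes + node_offset)
        elem_labels.append(np.full(hexes.shape[0], lab, dtype="U2"))
        node_labels.append(np.full(nodes.shape[0], lab, dtype="U2"))
        slice_idx.append(np.repeat(np.arange(config.n_slices + 1), m))
        node_offset += nodes.shape[0]

    return Mesh(
        nodes=np.concatenate(all_nodes, axis=0),
        hexes=np.concatenate(all_hexes, axis=0),
        subtendon_label=np.concatenate(elem_labels),
        node_label=np.concatenate(node_labels),
        slice_index=np.concatenate(slice_idx),
        config=config,
    )


def _twist_angles(mesh: Mesh, twist_deg: float) -> np.ndarray:
    """Per-node rotation angle (radians): proximal slice fixed, distal slice
    rotated by the full twist; linear in axial fraction."""
    frac = 1.0 - mesh.nodes[:, 2] / mesh.config.length
    return np.deg2rad(mesh.config.twist_sense * twist_deg) * frac


def apply_helical_twist(mesh: Mesh, twist_deg: float) -> Mesh:
    """Rotate mesh nodes in-plane about the cross-section centre axis.

    A node at axial fraction ``f`` (0 proximal, 1 distal) is rotated by
    ``f * twist_deg`` about the z-axis.  In-plane radii and per-slice
    cross-sectional areas are preserved (the rotation is an isometry).
    """
    if not (0.0 <= twist_deg < 360.0):
        raise ValueError(f"twist must lie in [0, 360) degrees, got {twist_deg}")
    if mesh.twist_applied_deg != 0.0:
        raise ValueError("mesh is already twisted; generate a fresh mesh first")
    phi = _twist_angles(mesh, twist_deg)
    c, s = np.cos(phi), np.sin(phi)
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    nodes = np.stack([c * x - s * y, s * x + c * y, mesh.nodes[:, 2]], axis=1)
    return Mesh(
        nodes=nodes,
        hexes=mesh.hexes,
        subtendon_label=mesh.subtendon_label,
        node_label=mesh.node_label,
        slice_index=mesh.slice_index,
        config=replace(mesh.config, twist_deg=twist_deg),
        fibre_dir=None,
        twist_applied_deg=twist_deg,
    )


def assign_fiber_directions(mesh: Mesh) -> Mesh:
    """Per-element unit fibre vector along the rotated axial element edge.

    The fibre direction of each hex is the direction of the edge joining
    its first lower-face node to the matching upper-face node, so fibres
    follow the helical material lines imposed by the twist.
    """
    edge = mesh.nodes[mesh.hexes[:, 4]] - mesh.nodes[mesh.hexes[:, 0]]
    norm = np.linalg.norm(edge, axis=1, keepdims=True)
    mesh.fibre_dir = edge / norm
    return mesh


def fibre_prestretch(r: float, twist_rad: float, length: float):
    """Arc-length ratio of a helical material line at radius ``r`` to the axis.

    ``sqrt(1 + (r * twist_rad / length)^2)``; quantifies the twist-induced
    stretch non-uniformity across the cross-section.  ``r`` and ``length``
    share units.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    out = np.sqrt(1.0 + (r * twist_rad / length) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass
class CentroidPath:
    """Ordered (distal -> proximal) node path tracking a subtendon centroid."""

    label: str
    node_ids: np.ndarray  # (n_slices+1,)
    points: np.ndarray  # (n_slices+1, 3) mm

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length along the path (mm), starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_positions()[-1])


def centroid_line(mesh: Mesh, label: str) -> CentroidPath:
    """Per-slice node nearest the subtendon's in-plane area centroid.

    Ties in the nearest-node selection are broken by lowest node index.
    Under twist the returned path follows the helix of the sector centroid.
    """
    if label not in SUBTENDONS:
        raise ValueError(f"unknown subtendon label {label!r}")
    cfg = mesh.config
    t0, t1 = cfg.sector_bounds()[label]
    k, n_r = cfg.divisions()[label]
    pts2d, quads = _sector_template(t0, t1, k, n_r, cfg.core_radius_fraction)
    cen2d, _ = _quad_centroid_area(pts2d, quads)

    z = mesh.slice_z()
    a, b = cfg.semi_axes(z)
    cx = a * cen2d[0]
    cy = b * cen2d[1]
    phi = np.deg2rad(cfg.twist_sense * mesh.twist_applied_deg) * (1.0 - z / cfg.length)
    targets = np.stack(
        [np.cos(phi) * cx - np.sin(phi) * cy, np.sin(phi) * cx + np.cos(phi) * cy], axis=1
    )

    in_label = mesh.node_label == label
    node_ids = np.empty(cfg.n_slices + 1, dtype=int)
    points = np.empty((cfg.n_slices + 1, 3))
    for s in range(cfg.n_slices + 1):
        cand = np.nonzero(in_label & (mesh.slice_index == s))[0]
        if cand.size == 0:
            raise ValueError(f"no nodes labelled {label!r} in slice {s}")
        d2 = np.sum((mesh.nodes[cand, :2] - targets[s]) ** 2, axis=1)
        best = cand[d2 <= d2.min() + 1e-12]
        node_ids[s] = best.min()
        points[s] = mesh.nodes[node_ids[s]]
    return CentroidPath(label=label, node_ids=node_ids, points=points)


def contact_adjacency(mesh: Mesh) -> dict:
    """Shared internal boundary length (mm) between subtendon sector pairs.

    Returns ``{(label_a, label_b): lengths}`` with sorted label tuples and
    one length per slice.  Each adjacent sector pair shares one straight
    radial boundary from the centre to the ellipse surface; the length is
    rotation-invariant, so twist enters only through the taper.
    """
    cfg = mesh.config
    bounds = cfg.sector_bounds()
    z = mesh.slice_z()
    a, b = cfg.semi_axes(z)
    boundaries = {}
    order = list(SUBTENDONS)
    for i, lab in enumerate(order):
        nxt = order[(i + 1) % len(order)]
        t_b = bounds[lab][1]  # == bounds[nxt][0] (mod 2*pi)
        length = np.hypot(a * np.cos(t_b), b * np.sin(t_b))
        key = tuple(sorted((lab, nxt)))
        boundaries[key] = boundaries.get(key, 0.0) + length
    # non-adjacent pairs (cannot occur with three sectors, kept for contract)
    for i, lab in enumerate(order):
        for other in order[i + 1 :]:
            key = tuple(sorted((lab, other)))
            boundaries.setdefault(key, np.zeros_like(z))
    return boundaries


def build_mesh(config: MeshConfig | None = None) -> Mesh:
    """Generate, twist (per ``config.twist_deg``) and assign fibres."""
    if config is None:
        config = MeshConfig()
    mesh = generate_butterfly_mesh(config)
    if config.twist_deg != 0.0:
        mesh = apply_helical_twist(mesh, config.twist_deg)
    return assign_fiber_directions(mesh)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_vtk(mesh: Mesh, path: str | Path) -> Path:
    """Write the mesh as legacy ASCII VTK (hexahedra with cell data).

    Cell data: integer subtendon id (0=LG, 1=MG, 2=S) and, when assigned,
    the per-element fibre vector.
    """
    path = Path(path)
    lab_to_id = {lab: i for i, lab in enumerate(SUBTENDONS)}
    lines = [
        "# vtk DataFile Version 3.0",
        "tendonwave mesh (mm)",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines.extend(" ".join(f"{v:.9g}" for v in row) for row in mesh.nodes)
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}")
    lines.extend("8 " + " ".join(str(i) for i in hx) for hx in mesh.hexes)
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend("12" for _ in range(mesh.n_elements))
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("SCALARS subtendon int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(lab_to_id[lab]) for lab in mesh.subtendon_label)
    if mesh.fibre_dir is not None:
        lines.append("VECTORS fibre double")
        lines.extend(" ".join(f"{v:.9g}" for v in row) for row in mesh.fibre_dir)
    path.write_text("\n".join(lines) + "\n")
    return path
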