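"""FEBio model-file writer and solver-output reader (full-fidelity path).

The reduced-order solver in :mod:`tendonwave.wave_sim` is a desk-scale
stand-in; for full 3-D dynamic solves each model specification can be
exported as a self-contained FEBio 4.x XML document (uncoupled
transversely isotropic Mooney-Rivlin material, per-element fibre vectors,
frictionless sliding-elastic penalty contact between subtendon bodies,
static preload step followed by a 1 ms dynamic step at 10 us output).

Files use the mm / N / MPa / tonne / s unit convention (stated in a header
comment).  Writing is deterministic: identical specifications produce
byte-identical files.  Only plain-text nodal displacement logs are read
back; binary plot files are out of scope.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from tendonwave.constitutive import MaterialParams, MPA
from tendonwave.geometry import SUBTENDONS, Mesh, centroid_line
from tendonwave.loading import LoadCase
from tendonwave.wave_sim import ExcitationSpec

__all__ = [
    "FEB_VERSION",
    "DEFAULT_CONTACT_PENALTY",
    "write_feb",
    "read_feb",
    "write_node_log",
    "read_node_displacements",
    "export_batch",
]

FEB_VERSION = "4.0"
DEFAULT_CONTACT_PENALTY = 100.0
_FMT = "{:.9g}"


def _fmt(value: float) -> str:
    return _FMT.format(float(value))


def _vec(values) -> str:
    return ",".join(_fmt(v) for v in values)


@dataclass(frozen=True)
class FebDoc:
    """Parsed subset of a .feb file used for round-trip verification."""

    nodes: np.ndarray  # (N, 3) mm
    elements: dict  # label -> (E, 8) 0-based connectivity
    fibres: dict  # label -> (E, 3) unit vectors
    materials: dict  # label -> {param: value}


def write_feb(
    mesh: Mesh,
    params: MaterialParams,
    case: LoadCase,
    excitation: ExcitationSpec | None = None,
    path: str | Path = "model.feb",
    contact_penalty: float = DEFAULT_CONTACT_PENALTY,
    static_time: float = 0.1,
    dynamic_duration: float = 1.0e-3,
    dynamic_dt: float = 1.0e-5,
) -> Path:
    """Write one model specification as a self-contained FEBio 4.x file.

    The mesh must carry fibre directions.  Units inside the file are
    mm / N / MPa with density in tonne/mm^3 and time in seconds.
    """
    if mesh.fibre_dir is None:
        raise ValueError("mesh has no fibre directions; run assign_fiber_directions")
    if excitation is None:
        excitation = ExcitationSpec()
    path = Path(path)

    root = ET.Element("febio_spec", version=FEB_VERSION)
    root.append(
        ET.Comment(
            " units: mm / N / MPa, density tonne/mm^3, time s "
            f"| cohort={case.cohort} twist={mesh.twist_applied_deg:g}deg "
            f"increment={case.increment} "
        )
    )
    ET.SubElement(root, "Module", type="solid")

    # --- materials (identical constants per subtendon, separate bodies) ---
    material = ET.SubElement(root, "Material")
    for i, lab in enumerate(SUBTENDONS, start=1):
        mat = ET.SubElement(
            material, "material", id=str(i), name=f"subtendon_{lab}",
            type="trans iso Mooney-Rivlin",
        )
        ET.SubElement(mat, "density").text = _fmt(params.rho * 1e-12)  # tonne/mm^3
        ET.SubElement(mat, "c1").text = _fmt(params.c1 / MPA)
        ET.SubElement(mat, "c2").text = _fmt(params.c2 / MPA)
        ET.SubElement(mat, "c3").text = _fmt(params.c3 / MPA)
        ET.SubElement(mat, "c4").text = _fmt(params.c4)
        ET.SubElement(mat, "c5").text = _fmt(params.c5 / MPA)
        ET.SubElement(mat, "lam_max").text = _fmt(params.lambda_star)
        ET.SubElement(mat, "k").text = _fmt(params.bulk / MPA)
        ET.SubElement(mat, "fiber", type="user")

    # --- mesh ------------------------------------------------------------
    mesh_el = ET.SubElement(root, "Mesh")
    nodes_el = ET.SubElement(mesh_el, "Nodes", name="tendon")
    for i, row in enumerate(mesh.nodes, start=1):
        ET.SubElement(nodes_el, "node", id=str(i)).text = _vec(row)
    for lab in SUBTENDONS:
        idx = np.nonzero(mesh.subtendon_label == lab)[0]
        elems_el = ET.SubElement(mesh_el, "Elements", type="hex8", name=f"sub_{lab}")
        for eid, e in enumerate(idx, start=1):
            ET.SubElement(elems_el, "elem", id=str(eid)).text = _vec(
                mesh.hexes[e] + 1
            )

    # node sets: distal face, proximal face, centroid lines
    distal = np.nonzero(mesh.slice_index == 0)[0] + 1
    proximal = np.nonzero(mesh.slice_index == mesh.config.n_slices)[0] + 1
    ET.SubElement(mesh_el, "NodeSet", name="distal_face").text = _vec(distal)
    ET.SubElement(mesh_el, "NodeSet", name="proximal_face").text = _vec(proximal)
    for lab in SUBTENDONS:
        cpath = centroid_line(mesh, lab)
        ET.SubElement(mesh_el, "NodeSet", name=f"centroid_{lab}").text = _vec(
            cpath.node_ids + 1
        )
    pairs = [("LG", "MG"), ("MG", "S"), ("LG", "S")]
    for a, b in pairs:
        ET.SubElement(
            mesh_el, "SurfacePair", name=f"contact_{a}_{b}",
            primary=f"sub_{a}", secondary=f"sub_{b}",
        )

    # --- domains and fibre data ------------------------------------------
    domains = ET.SubElement(root, "MeshDomains")
    for i, lab in enumerate(SUBTENDONS, start=1):
        ET.SubElement(
            domains, "SolidDomain", name=f"sub_{lab}", mat=f"subtendon_{lab}"
        )
    meshdata = ET.SubElement(root, "MeshData")
    for lab in SUBTENDONS:
        idx = np.nonzero(mesh.subtendon_label == lab)[0]
        ed = ET.SubElement(
            meshdata, "ElementData", elem_set=f"sub_{lab}", var="fiber"
        )
        for eid, e in enumerate(idx, start=1):
            ET.SubElement(ed, "e", lid=str(eid)).text = _vec(mesh.fibre_dir[e])

    # --- contact ----------------------------------------------------------
    contact = ET.SubElement(root, "Contact")
    for a, b in pairs:
        c = ET.SubElement(
            contact, "contact", type="sliding-elastic",
            surface_pair=f"contact_{a}_{b}", name=f"contact_{a}_{b}",
        )
        ET.SubElement(c, "penalty").text = _fmt(contact_penalty)
        ET.SubElement(c, "auto_penalty").text = "1"
        ET.SubElement(c, "fric_coeff").text = "0"
        ET.SubElement(c, "two_pass").text = "1"

    # --- boundary: distal end fixed during preload ------------------------
    boundary = ET.SubElement(root, "Boundary")
    fix = ET.SubElement(
        boundary, "bc", name="fix_distal", type="zero displacement",
        node_set="distal_face",
    )
    for dof in ("x_dof", "y_dof", "z_dof"):
        ET.SubElement(fix, dof).text = "1"

    # --- load controllers -------------------------------------------------
    loaddata = ET.SubElement(root, "LoadData")
    ramp = ET.SubElement(loaddata, "load_controller", id="1", type="loadcurve")
    ET.SubElement(ramp, "interpolate").text = "SMOOTH"
    rp = ET.SubElement(ramp, "points")
    ET.SubElement(rp, "pt").text = _vec((0.0, 0.0))
    ET.SubElement(rp, "pt").text = _vec((static_time, 1.0))
    ET.SubElement(rp, "pt").text = _vec((static_time + dynamic_duration, 1.0))
    pulse = ET.SubElement(loaddata, "load_controller", id="2", type="loadcurve")
    ET.SubElement(pulse, "interpolate").text = "LINEAR"
    pp = ET.SubElement(pulse, "points")
    t_pulse = np.linspace(0.0, excitation.half_period, 51)
    for tp in t_pulse:
        val = np.sin(np.pi * tp / excitation.half_period)
        ET.SubElement(pp, "pt").text = _vec((static_time + tp, val))
    ET.SubElement(pp, "pt").text = _vec((static_time + dynamic_duration, 0.0))

    # --- steps ------------------------------------------------------------
    steps = ET.SubElement(root, "Step")
    step1 = ET.SubElement(steps, "step", id="1", name="static_preload")
    ctrl1 = ET.SubElement(step1, "Control")
    ET.SubElement(ctrl1, "analysis").text = "STATIC"
    ET.SubElement(ctrl1, "time_steps").text = "10"
    ET.SubElement(ctrl1, "step_size").text = _fmt(static_time / 10.0)
    loads1 = ET.SubElement(step1, "Loads")
    a_prox, b_prox = mesh.config.semi_axes(mesh.config.length)
    area_scale = (float(a_prox) * float(b_prox)) / (
        0.5 * mesh.config.distal_width * 0.5 * mesh.config.distal_thickness
    )
    for lab in SUBTENDONS:
        # uniform axial traction on the proximal end face of each subtendon;
        # nominal stress is defined on the distal section, rescale by taper
        traction_mpa = case.stresses[lab] / MPA / area_scale
        load = ET.SubElement(
            loads1, "surface_load", name=f"traction_{lab}",
            type="traction", surface=f"proximal_{lab}",
        )
        ET.SubElement(load, "scale", lc="1").text = _fmt(traction_mpa)
        ET.SubElement(load, "traction").text = _vec((0.0, 0.0, 1.0))

    step2 = ET.SubElement(steps, "step", id="2", name="dynamic_wave")
    ctrl2 = ET.SubElement(step2, "Control")
    ET.SubElement(ctrl2, "analysis").text = "DYNAMIC"
    n_dyn = int(round(dynamic_duration / dynamic_dt))
    ET.SubElement(ctrl2, "time_steps").text = str(n_dyn)
    ET.SubElement(ctrl2, "step_size").text = _fmt(dynamic_dt)
    bc2 = ET.SubElement(step2, "Boundary")
    drive = ET.SubElement(
        bc2, "bc", name="distal_pulse", type="prescribed displacement",
        node_set="distal_face",
    )
    ET.SubElement(drive, "dof").text = excitation.direction
    ET.SubElement(drive, "value", lc="2").text = _fmt(excitation.amplitude * 1e3)  # mm
    ET.SubElement(drive, "relative").text = "1"

    # --- output -----------------------------------------------------------
    output = ET.SubElement(root, "Output")
    log_name = (
        f"{case.cohort}_twist{mesh.twist_applied_deg:g}_inc{case.increment:03d}_log.txt"
    )
    logfile = ET.SubElement(output, "logfile", file=log_name)
    for lab in SUBTENDONS:
        ET.SubElement(
            logfile, "node_data", data="uy", name=f"centroid_{lab}",
            node_set=f"centroid_{lab}", delim=" ",
        )

    ET.indent(root, space="  ")
    xml_bytes = ET.tostring(root, encoding="ISO-8859-1", xml_declaration=True)
    path.write_bytes(xml_bytes + b"\n")
    return path


def read_feb(path: str | Path) -> FebDoc:
    """Parse the mesh/material subset of a .feb file written by write_feb."""
    tree = ET.parse(path)
    root = tree.getroot()
    mesh_el = root.find("Mesh")
    nodes = np.array(
        [[float(v) for v in n.text.split(",")] for n in mesh_el.find("Nodes")]
    )
    elements: dict = {}
    for elems in mesh_el.findall("Elements"):
        lab = elems.get("name").removeprefix("sub_")
        conn = np.array(
            [[int(v) - 1 for v in e.text.split(",")] for e in elems]
        )
        elements[lab] = conn
    fibres: dict = {}
    meshdata = root.find("MeshData")
    if meshdata is not None:
        for ed in meshdata.findall("ElementData"):
            lab = ed.get("elem_set").removeprefix("sub_")
            fibres[lab] = np.array(
                [[float(v) for v in e.text.split(",")] for e in ed]
            )
    materials: dict = {}
    for mat in root.find("Material"):
        lab = mat.get("name").removeprefix("subtendon_")
        materials[lab] = {
            child.tag: float(child.text)
            for child in mat
            if child.text and child.tag != "fiber"
        }
    return FebDoc(nodes=nodes, elements=elements, fibres=fibres, materials=materials)


# ---------------------------------------------------------------------------
# plain-text nodal displacement logs
# ---------------------------------------------------------------------------


def write_node_log(
    path: str | Path,
    node_ids,
    times,
    displacements: np.ndarray,
    data_name: str = "uy",
) -> Path:
    """Write a FEBio-style plain-text node data log.

    ``displacements`` is (n_nodes, n_times) in the file's length unit.
    One ``*Time`` block per output step with ``node_id value`` records.
    """
    path = Path(path)
    node_ids = np.asarray(node_ids, dtype=int)
    times = np.asarray(times, dtype=float)
    disp = np.asarray(displacements, dtype=float)
    if disp.shape != (node_ids.size, times.size):
        raise ValueError("displacements must be (n_nodes, n_times)")
    lines = [f"*Title = tendonwave node log", f"*Data = {data_name}"]
    for j, t in enumerate(times):
        lines.append(f"*Step = {j + 1}")
        lines.append(f"*Time = {float(t)!r}")
        for i, nid in enumerate(node_ids):
            lines.append(f"{int(nid)} {float(disp[i, j])!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_node_displacements(
    path: str | Path,
    node_ids=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse a plain-text node data log into per-node time series.

    Returns ``(node_ids, times, displacements)`` with ``displacements`` of
    shape (n_nodes, n_times).  Missing nodes or ragged blocks are rejected
    with the offending step named.
    """
    path = Path(path)
    times: list = []
    blocks: list = []
    current: dict | None = None
    step_label = step_label_prev = "?"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("*Title") or line.startswith("*Data"):
            continue
        if line.startswith("*Step"):
            step_label = line.split("=")[1].strip()
            continue
        if line.startswith("*Time"):
            if current is not None:
                blocks.append((step_label_prev, current))
            current = {}
            step_label_prev = step_label
            times.append(float(line.split("=")[1]))
            continue
        if current is None:
            raise ValueError(f"{path}: data record before any *Time header: {line!r}")
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed record in step {step_label}: {line!r}")
        current[int(parts[0])] = float(parts[1])
    if current is not None:
        blocks.append((step_label_prev, current))
    if not blocks:
        raise ValueError(f"{path}: no data blocks found")

    first_ids = sorted(blocks[0][1])
    wanted = list(first_ids) if node_ids is None else [int(n) for n in node_ids]
    disp = np.empty((len(wanted), len(blocks)))
    for j, (step, block) in enumerate(blocks):
        if sorted(block) != first_ids:
            raise ValueError(
                f"{path}: ragged series at step {step}: expected {len(first_ids)} "
                f"records, found {len(block)}"
            )
        for i, nid in enumerate(wanted):
            if nid not in block:
                raise ValueError(f"{path}: node {nid} missing in step {step}")
            disp[i, j] = block[nid]
    t = np.asarray(times)
    if t.size > 1:
        dt = np.diff(t)
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1e-30):
            raise ValueError(f"{path}: non-uniform output cadence")
    return np.asarray(wanted), t, disp


def export_batch(
    cases,
    mesh_factory,
    params: MaterialParams,
    out_dir: str | Path,
    excitation: ExcitationSpec | None = None,
    **write_kwargs,
) -> list[Path]:
    """Write one .feb file per load case.

    ``mesh_factory(twist_deg)`` must return a fibre-assigned mesh for the
    requested twist (meshes are cached per twist angle).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache: dict = {}
    paths = []
    for case in cases:
        if case.twist_deg not in cache:
            cache[case.twist_deg] = mesh_factory(case.twist_deg)
        name = f"{case.cohort}_twist{case.twist_deg:g}_inc{case.increment:03d}.feb"
        paths.append(
            write_feb(
                cache[case.twist_deg], params, case,
                excitation=excitation, path=out_dir / name, **write_kwargs,
            )
        )
    return paths
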