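import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tendonwave.geometry import (
    SUBTENDONS,
    MeshConfig,
    apply_helical_twist,
    assign_fiber_directions,
    build_mesh,
    centroid_line,
    contact_adjacency,
    export_vtk,
    fibre_prestretch,
    generate_butterfly_mesh,
)

REFERENCE_COUNTS = {"LG": 22140, "MG": 13500, "S": 16200}


class TestMeshConfig:
    def test_default_dimensions(self):
        cfg = MeshConfig()
        assert cfg.distal_width == 22.04
        assert cfg.distal_thickness == 6.42
        assert cfg.proximal_width == 17.83
        assert cfg.proximal_thickness == 5.76

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"distal_width": 0.0},
            {"length": -1.0},
            {"twist_deg": 400.0},
            {"csa_fractions": {"LG": 0.5, "MG": 0.5, "S": 0.2}},
            {"csa_fractions": {"LG": 0.5, "MG": 0.5}},
            {"n_slices": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MeshConfig(**kwargs)


class TestGenerateButterflyMesh:
    def test_reference_element_counts(self, default_mesh):
        assert default_mesh.element_counts() == REFERENCE_COUNTS

    def test_distal_width(self, default_mesh):
        distal = default_mesh.nodes[default_mesh.slice_index == 0]
        width = distal[:, 0].max() - distal[:, 0].min()
        assert width == pytest.approx(22.04, abs=5e-3)
        thickness = distal[:, 1].max() - distal[:, 1].min()
        assert thickness == pytest.approx(6.42, abs=8e-3)

    def test_proximal_extent(self, default_mesh):
        prox = default_mesh.nodes[
            default_mesh.slice_index == default_mesh.config.n_slices
        ]
        assert prox[:, 0].max() - prox[:, 0].min() == pytest.approx(17.83, abs=5e-3)

    def test_positive_jacobians(self, default_mesh):
        assert default_mesh.corner_jacobians().min() > 0

    def test_area_fractions_every_slice(self, default_mesh):
        total = default_mesh.slice_areas()
        for lab in SUBTENDONS:
            frac = default_mesh.slice_areas(lab) / total
            expected = default_mesh.config.csa_fractions[lab]
            assert np.all(np.abs(frac - expected) / expected < 0.02)

    def test_circular_equal_fractions_symmetry(self):
        cfg = MeshConfig(
            distal_width=10.0,
            distal_thickness=10.0,
            proximal_width=10.0,
            proximal_thickness=10.0,
            n_slices=4,
            csa_fractions={"LG": 1 / 3, "MG": 1 / 3, "S": 1 / 3},
            sector_divisions={"LG": (3, 3), "MG": (3, 3), "S": (3, 3)},
        )
        mesh = generate_butterfly_mesh(cfg)
        areas = np.array([mesh.slice_areas(lab)[0] for lab in SUBTENDONS])
        assert np.ptp(areas) / areas.mean() < 0.01

    def test_labels_and_slices_consistent(self, small_mesh):
        cfg = small_mesh.config
        assert small_mesh.slice_index.max() == cfg.n_slices
        # every element's nodes all carry the element's label
        lab_of_nodes = small_mesh.node_label[small_mesh.hexes]
        assert np.all(lab_of_nodes == small_mesh.subtendon_label[:, None])


class TestApplyHelicalTwist:
    def test_zero_twist_identity(self, small_config):
        mesh = generate_butterfly_mesh(small_config)
        twisted = apply_helical_twist(mesh, 0.0)
        np.testing.assert_allclose(twisted.nodes, mesh.nodes)

    def test_half_rotation_distal_node(self, untapered_config):
        mesh = generate_butterfly_mesh(untapered_config)
        distal = np.nonzero(mesh.slice_index == 0)[0]
        # node closest to (+r, 0) on the distal slice
        r = mesh.nodes[distal, 0]
        idx = distal[np.argmax(r - 1e3 * np.abs(mesh.nodes[distal, 1]))]
        x0, y0 = mesh.nodes[idx, :2]
        twisted = apply_helical_twist(mesh, 180.0)
        assert twisted.nodes[idx, 0] == pytest.approx(-x0, abs=1e-9)
        assert twisted.nodes[idx, 1] == pytest.approx(-y0, abs=1e-9)

    def test_volume_invariant_180(self, default_mesh):
        twisted = apply_helical_twist(default_mesh, 180.0)
        v0, v1 = default_mesh.volume(), twisted.volume()
        assert abs(v1 - v0) / v0 < 1e-9

    @given(st.floats(0.0, 359.0))
    @settings(max_examples=15, deadline=None)
    def test_volume_invariant_any_twist(self, twist):
        cfg = MeshConfig(
            n_slices=4, sector_divisions={"LG": (2, 2), "MG": (2, 2), "S": (2, 2)}
        )
        mesh = generate_butterfly_mesh(cfg)
        twisted = apply_helical_twist(mesh, twist)
        assert abs(twisted.volume() - mesh.volume()) / mesh.volume() < 1e-9

    def test_radii_preserved(self, small_mesh):
        twisted = apply_helical_twist(small_mesh, 90.0)
        r0 = np.hypot(small_mesh.nodes[:, 0], small_mesh.nodes[:, 1])
        r1 = np.hypot(twisted.nodes[:, 0], twisted.nodes[:, 1])
        np.testing.assert_allclose(r0, r1, atol=1e-10)

    def test_no_inverted_hexes_at_180(self, default_mesh):
        twisted = apply_helical_twist(default_mesh, 180.0)
        assert twisted.corner_jacobians().min() > 0

    def test_out_of_range_rejected(self, small_mesh):
        with pytest.raises(ValueError):
            apply_helical_twist(small_mesh, 360.0)
        with pytest.raises(ValueError):
            apply_helical_twist(small_mesh, -5.0)

    def test_double_twist_rejected(self, small_config):
        mesh = apply_helical_twist(generate_butterfly_mesh(small_config), 30.0)
        with pytest.raises(ValueError):
            apply_helical_twist(mesh, 30.0)


class TestFiberDirections:
    def test_untwisted_prismatic_axial(self, untapered_config):
        mesh = assign_fiber_directions(generate_butterfly_mesh(untapered_config))
        np.testing.assert_allclose(
            mesh.fibre_dir, np.tile([0.0, 0.0, 1.0], (mesh.n_elements, 1)), atol=1e-12
        )

    def test_unit_norm(self, small_mesh):
        mesh = assign_fiber_directions(small_mesh)
        np.testing.assert_allclose(
            np.linalg.norm(mesh.fibre_dir, axis=1), 1.0, atol=1e-12
        )

    def test_helix_angle_oracle(self, untapered_config):
        # helix geometry: a material line at radius r under total twist theta
        # over length L makes angle atan(r*theta/L) with the tendon axis
        twist = 120.0
        mesh = assign_fiber_directions(
            apply_helical_twist(generate_butterfly_mesh(untapered_config), twist)
        )
        lower = mesh.nodes[mesh.hexes[:, 0]]
        upper = mesh.nodes[mesh.hexes[:, 4]]
        r_mid = np.hypot(*(0.5 * (lower + upper))[:, :2].T)
        expected = np.arctan(r_mid * np.deg2rad(twist) / mesh.config.length)
        actual = np.arccos(np.clip(mesh.fibre_dir[:, 2], -1, 1))
        # discretization: each slice rotates by a finite increment (chord
        # vs arc), so allow a fraction of the per-slice rotation angle
        tol = 0.25 * np.deg2rad(twist) / mesh.config.n_slices
        assert np.max(np.abs(actual - expected)) < tol


class TestFibrePrestretch:
    def test_axis_unstretched(self):
        assert fibre_prestretch(0.0, np.pi, 60.0) == 1.0

    def test_reference_value(self):
        # sqrt(1 + (5*pi/60)^2)
        assert fibre_prestretch(5.0, np.pi, 60.0) == pytest.approx(1.0337, abs=1e-4)

    def test_monotone_in_radius_and_twist(self):
        r = np.linspace(0, 10, 50)
        vals = fibre_prestretch(r, np.pi, 60.0)
        assert np.all(np.diff(vals) > 0)
        twists = np.linspace(0.1, 2 * np.pi, 50)
        vals_t = np.array([fibre_prestretch(5.0, t, 60.0) for t in twists])
        assert np.all(np.diff(vals_t) > 0)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            fibre_prestretch(1.0, 0.5, 0.0)


class TestCentroidLine:
    def test_node_count(self, small_mesh):
        path = centroid_line(small_mesh, "S")
        assert path.node_ids.size == small_mesh.config.n_slices + 1

    def test_untwisted_prismatic_straight(self, untapered_config):
        mesh = generate_butterfly_mesh(untapered_config)
        path = centroid_line(mesh, "MG")
        assert np.ptp(path.points[:, 0]) < 1e-9
        assert np.ptp(path.points[:, 1]) < 1e-9
        assert path.length == pytest.approx(mesh.config.length)

    def test_twisted_path_longer(self, untapered_config):
        mesh0 = generate_butterfly_mesh(untapered_config)
        mesh1 = apply_helical_twist(generate_butterfly_mesh(untapered_config), 180.0)
        for lab in SUBTENDONS:
            l0 = centroid_line(mesh0, lab).length
            l1 = centroid_line(mesh1, lab).length
            assert l1 > l0
            assert l0 >= mesh0.config.length - 1e-9

    def test_distal_to_proximal_order(self, small_mesh):
        path = centroid_line(small_mesh, "LG")
        assert np.all(np.diff(path.points[:, 2]) > 0)
        assert path.points[0, 2] == 0.0

    def test_unknown_label_rejected(self, small_mesh):
        with pytest.raises(ValueError):
            centroid_line(small_mesh, "XX")


class TestContactAdjacency:
    def test_symmetry_and_nonnegativity(self, small_mesh):
        adj = contact_adjacency(small_mesh)
        for (a, b), w in adj.items():
            assert (a, b) == tuple(sorted((a, b)))
            assert np.all(np.asarray(w) >= 0)

    def test_prismatic_constant_along_z(self, untapered_config):
        mesh = generate_butterfly_mesh(untapered_config)
        for w in contact_adjacency(mesh).values():
            assert np.ptp(np.asarray(w)) < 1e-9

    def test_total_interface_against_polygon_oracle(self, small_mesh):
        """Independent oracle: total internal interface length from the
        boundary edges of each sector's quad template (edges used by one
        quad only, excluding those on the outer ellipse)."""
        mesh = small_mesh
        adj = contact_adjacency(mesh)
        z0 = 0.0
        a, b = mesh.config.semi_axes(z0)
        total_from_adjacency = sum(np.asarray(w)[0] for w in adj.values())

        from tendonwave.geometry import _sector_template

        total_internal = 0.0
        bounds = mesh.config.sector_bounds()
        divisions = mesh.config.divisions()
        for lab in SUBTENDONS:
            t0, t1 = bounds[lab]
            k, nr = divisions[lab]
            pts, quads = _sector_template(
                t0, t1, k, nr, mesh.config.core_radius_fraction
            )
            edges = {}
            for quad in quads:
                for i in range(4):
                    e = tuple(sorted((quad[i], quad[(i + 1) % 4])))
                    edges[e] = edges.get(e, 0) + 1
            scaled = pts * np.array([a, b])
            for (i, j), count in edges.items():
                if count != 1:
                    continue
                ri = np.hypot(*pts[i])
                rj = np.hypot(*pts[j])
                if ri > 1 - 1e-6 and rj > 1 - 1e-6:
                    continue  # outer ellipse arc, not internal
                total_internal += np.linalg.norm(scaled[i] - scaled[j])
        # every internal interface is shared by two sectors
        assert total_internal / 2.0 == pytest.approx(
            total_from_adjacency, rel=1e-6
        )

    def test_taper_scaling(self, default_mesh):
        adj = contact_adjacency(default_mesh)
        for w in adj.values():
            w = np.asarray(w)
            # tapered section: interface shrinks monotonically to proximal
            assert w[-1] < w[0]


class TestExport:
    def test_vtk_round_numbers(self, small_mesh, tmp_path):
        mesh = assign_fiber_directions(small_mesh)
        path = export_vtk(mesh, tmp_path / "mesh.vtk")
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert f"POINTS {mesh.n_nodes} double" in text
        assert f"CELL_TYPES {mesh.n_elements}" in text
        assert "VECTORS fibre double" in text


class TestBuildMesh:
    def test_build_applies_twist_and_fibres(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, twist_deg=90.0)
        mesh = build_mesh(cfg)
        assert mesh.twist_applied_deg == 90.0
        assert mesh.fibre_dir is not None
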