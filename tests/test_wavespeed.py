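import numpy as np
import pytest

from tendonwave.geometry import apply_helical_twist, centroid_line, generate_butterfly_mesh
from tendonwave.maps import SpatioTemporalMap
from tendonwave.synthetic_data import SynthMapSpec, synth_plane_wave_map
from tendonwave.wavespeed import (
    assemble_map,
    directional_filter,
    estimate_speed,
    radon_speed,
)


def forward_map(c=60.0, **kwargs):
    smap, _ = synth_plane_wave_map(SynthMapSpec(true_speed=c, **kwargs))
    return smap


def backward_map(c=60.0):
    fwd = forward_map(c)
    return SpatioTemporalMap(u=fwd.u[::-1].copy(), dx=fwd.dx, dt=fwd.dt)


def periodic_plane_wave(p=6, q=10, n_x=64, n_t=100, backward=False):
    """Spectrally pure plane wave: integer cycle counts in both dimensions,
    so its DFT occupies exactly one conjugate bin pair and the quadrant
    mask acts without truncation leakage."""
    i = np.arange(n_x)[:, None]
    j = np.arange(n_t)[None, :]
    sign = 1 if backward else -1
    u = 1e-5 * np.sin(2 * np.pi * (p * i / n_x + sign * q * j / n_t))
    return SpatioTemporalMap(u=u, dx=1e-3, dt=1e-5)


class TestAssembleMap:
    def test_uniform_input_identity(self):
        rng = np.random.default_rng(1)
        disp = rng.normal(size=(20, 30))
        pos = np.arange(20) * 1e-3
        out = assemble_map(disp, pos, dt=1e-5)
        np.testing.assert_array_equal(out.u, disp)
        assert out.dx == pytest.approx(1e-3)

    def test_nan_row_infilled_and_flagged(self):
        disp = np.ones((10, 5))
        disp[4, :] = np.nan
        pos = np.arange(10) * 1e-3
        out = assemble_map(disp, pos, dt=1e-5)
        assert np.all(np.isfinite(out.u))
        assert out.meta["interpolated_rows"] == 1
        np.testing.assert_allclose(out.u[4], 1.0)

    def test_non_monotone_rejected(self):
        disp = np.zeros((3, 4))
        with pytest.raises(ValueError):
            assemble_map(disp, np.array([0.0, 2.0, 1.0]), dt=1e-5)

    def test_twisted_path_arc_length_extent(self, untapered_config):
        """Helix oracle: under twist the map must span the centroid-path arc
        length, which exceeds the axial length for an off-axis centroid."""
        mesh = apply_helical_twist(generate_butterfly_mesh(untapered_config), 180.0)
        path = centroid_line(mesh, "LG")
        pos = path.arc_positions() * 1e-3  # m
        disp = np.zeros((pos.size, 12))
        out = assemble_map(disp, pos, dt=1e-5)
        extent = (out.n_positions - 1) * out.dx
        assert extent == pytest.approx(path.length * 1e-3, rel=0.02)
        # independent helix length check: L * mean stretch factor >= L
        assert path.length * 1e-3 > mesh.config.length * 1e-3


class TestDirectionalFilter:
    def test_forward_passband_identity(self):
        smap = periodic_plane_wave()
        out = directional_filter(smap)
        err = np.sqrt(np.mean((out.u - smap.u) ** 2)) / np.sqrt(np.mean(smap.u**2))
        assert err < 0.02

    def test_backward_stopband(self):
        smap = periodic_plane_wave(backward=True)
        out = directional_filter(smap)
        assert np.sqrt(np.mean(out.u**2)) < 0.05 * np.sqrt(np.mean(smap.u**2))

    def test_two_wave_superposition_recovery(self):
        fwd = forward_map(50.0)
        bwd = backward_map(50.0)
        mixed = SpatioTemporalMap(u=fwd.u + bwd.u, dx=fwd.dx, dt=fwd.dt)
        est = radon_speed(directional_filter(mixed))
        assert abs(est.speed - 50.0) / 50.0 < 0.02

    def test_small_map_rejected(self):
        smap = SpatioTemporalMap(u=np.zeros((4, 4)), dx=1e-3, dt=1e-5)
        with pytest.raises(ValueError):
            directional_filter(smap)


class TestRadonSpeed:
    def test_reference_line_image(self):
        # displacement band advancing 0.5 mm per 10 us sample = 50 m/s
        est = radon_speed(forward_map(50.0))
        assert est.speed == pytest.approx(50.0, abs=0.5)
        assert est.ok

    def test_amplitude_scale_invariance(self):
        smap = forward_map(70.0)
        scaled = SpatioTemporalMap(u=10.0 * smap.u, dx=smap.dx, dt=smap.dt)
        a = radon_speed(smap)
        b = radon_speed(scaled)
        assert a.peak_angle_deg == pytest.approx(b.peak_angle_deg, abs=1e-9)

    def test_consistency_over_speed_range(self):
        """Relative error < 1 % noiseless for speeds log-spaced in the
        physiological-to-ultrasound range."""
        for c in np.geomspace(20.0, 160.0, 7):
            est = radon_speed(forward_map(float(c)))
            assert abs(est.speed - c) / c < 0.01, f"speed {c}"

    def test_angle_grid_refinement_stability(self):
        smap = forward_map(40.0)
        a = radon_speed(smap, angle_step=0.25)
        b = radon_speed(smap, angle_step=0.125)
        assert abs(a.speed - b.speed) / a.speed < 0.002

    def test_noise_robustness_seeded(self):
        for seed in range(15):
            smap, truth = synth_plane_wave_map(
                SynthMapSpec(true_speed=60.0, snr_db=20.0, seed=seed)
            )
            est = estimate_speed(smap, use_filter=False)
            assert abs(est.speed - truth["speed"]) / truth["speed"] < 0.05

    def test_zero_map_flagged_low_signal(self):
        smap = SpatioTemporalMap(u=np.zeros((32, 32)), dx=1e-3, dt=1e-5)
        est = radon_speed(smap)
        assert "low-signal" in est.flags
        assert not est.ok

    def test_out_of_range_speed_flagged_at_boundary(self):
        # 2000 m/s at dx/dt = 100 m/s -> band angle ~2.9 deg, below the
        # scanned range, so the peak must sit at the grid boundary
        est = radon_speed(forward_map(2000.0))
        assert "angle-at-boundary" in est.flags

    def test_small_map_rejected(self):
        with pytest.raises(ValueError):
            radon_speed(SpatioTemporalMap(u=np.zeros((5, 5)), dx=1e-3, dt=1e-5))

    def test_explicit_angle_grid(self):
        smap = forward_map(50.0)
        est = radon_speed(smap, angle_grid=np.arange(55.0, 72.0, 0.25))
        assert est.speed == pytest.approx(50.0, abs=0.5)


class TestReflectiveVsAbsorbing:
    def test_filtered_reflective_matches_absorbing(self):
        """Filter + estimator on a reflective-boundary field must agree with
        the estimator on the absorbing (forward-only) field within 3 %."""
        for c in (60.0, 80.0, 120.0, 150.0):
            # window long enough for the reflection to cross the whole map
            absorbing, _ = synth_plane_wave_map(
                SynthMapSpec(true_speed=c, n_times=200)
            )
            reflective, _ = synth_plane_wave_map(
                SynthMapSpec(true_speed=c, n_times=200, reflection=1.0)
            )
            a = estimate_speed(absorbing, use_filter=False)
            b = estimate_speed(reflective, use_filter=True, differentiate=True)
            assert abs(a.speed - b.speed) / a.speed < 0.03


class TestEstimateSpeed:
    def test_differentiate_preserves_speed(self):
        smap = forward_map(80.0)
        a = estimate_speed(smap, use_filter=False)
        b = estimate_speed(smap, use_filter=False, differentiate=True)
        assert abs(a.speed - b.speed) / a.speed < 0.01
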