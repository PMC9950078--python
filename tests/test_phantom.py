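import dataclasses

import numpy as np
import pytest

from drujkin.phantom import (
    GHOST_SWEEP_THRESHOLD_DEG,
    AcquisitionProtocol,
    SceneConfig,
    SceneValidationError,
    add_quantum_mottle,
    build_default_scene,
    fit_grid,
    rasterize,
    simulate_experiment,
    simulate_motion_frame,
)
from drujkin.transforms import RigidTransform, random_rigid_transform


class TestScene:
    def test_rotation_axis_passes_through_ulna_shaft(self, scene):
        a = np.asarray(scene.ulna.shaft_start)
        b = np.asarray(scene.ulna.shaft_end)
        p = np.asarray(scene.axis_point)
        d = np.asarray(scene.axis_direction)
        # axis point on the ulna shaft segment, axis parallel to it
        t = (p - a) @ (b - a) / ((b - a) @ (b - a))
        assert np.linalg.norm(a + t * (b - a) - p) < 1e-9
        assert np.linalg.norm(np.cross(d, (b - a) / np.linalg.norm(b - a))) < 1e-9

    def test_zero_gap_is_rejected(self):
        with pytest.raises(SceneValidationError):
            build_default_scene(SceneConfig(gap=0.0))

    def test_nonpositive_radius_is_rejected(self):
        with pytest.raises(SceneValidationError):
            build_default_scene(SceneConfig(ulna_shaft_semiaxes=(0.0, 4.5)))

    def test_min_surface_distance_equals_configured_gap(self, scene):
        # dense parametric sampling of both analytic surfaces; the nearest
        # pair must sit at the configured inter-bone gap
        assert scene.min_surface_distance(step_mm=0.25) == pytest.approx(
            scene.gap, rel=0.01
        )

    def test_intensity_ordering_is_enforced(self):
        with pytest.raises(SceneValidationError):
            build_default_scene(SceneConfig(medullary_value=2000.0))


class TestRasterize:
    def test_deep_cortical_and_background_voxels_exact(self, scene, grid):
        vol = rasterize(scene, None, grid)  # smoothstep over one voxel
        w = np.mean(grid.spacing)
        centers = grid.voxel_centers()
        d_r = scene.radius.sdf(centers)
        d_u = scene.ulna.sdf(centers)
        deep_cortex = (d_r < -w) & (d_r > -scene.radius.cortical_thickness + w)
        far_outside = (d_r > w) & (d_u > w)
        vals = vol.data.ravel()
        assert deep_cortex.any() and far_outside.any()
        assert np.all(vals[deep_cortex] == scene.cortical_value)
        assert np.all(vals[far_outside] == scene.background_value)

    def test_equivariance_under_rigid_pose(self, scene, grid):
        # rasterizing a posed scene equals sampling the scene intensity at
        # inverse-transformed voxel centers (computed independently here)
        rng = np.random.default_rng(7)
        T = random_rigid_transform(rng, 3.0, 5.0, center=(30.0, 9.0, 0.0))
        vol = rasterize(scene, T, grid, profile="gauss")
        centers = T.inverse().apply(grid.voxel_centers())
        w = 2.0 * float(np.mean(grid.spacing))
        expected = scene.intensity(centers, smooth_width=w, profile="gauss")
        contrast = scene.cortical_value - scene.background_value
        assert np.max(np.abs(vol.data.ravel() - expected)) < 0.01 * contrast

    def test_composition_of_poses(self, scene, grid):
        rng = np.random.default_rng(8)
        T = random_rigid_transform(rng, 2.0, 3.0)
        S = random_rigid_transform(rng, 2.0, 3.0)
        a = rasterize(scene, T @ S, grid, profile="gauss")
        centers = (T @ S).inverse().apply(grid.voxel_centers())
        b = scene.intensity(centers, smooth_width=2.4, profile="gauss")
        contrast = scene.cortical_value - scene.background_value
        assert np.max(np.abs(a.data.ravel() - b)) < 0.01 * contrast


class TestQuantumMottle:
    def test_sigma_at_reference_exposure(self, protocol):
        from drujkin.volume import Volume

        vol = Volume(np.zeros((64, 64, 64)), spacing=(1.0, 1.0, 1.0))
        noisy = add_quantum_mottle(vol, protocol.mas_ref, protocol, seed=3)
        resid = noisy.data - vol.data
        assert resid.size > 2e5
        assert np.std(resid) == pytest.approx(protocol.sigma_ref, rel=0.02)

    def test_sigma_scales_inverse_sqrt_mas(self, protocol):
        from drujkin.volume import Volume

        vol = Volume(np.zeros((64, 64, 64)), spacing=(1.0, 1.0, 1.0))
        r30 = add_quantum_mottle(vol, 30, protocol, seed=4).data - vol.data
        r120 = add_quantum_mottle(vol, 120, protocol, seed=5).data - vol.data
        assert np.std(r30) / np.std(r120) == pytest.approx(2.0, rel=0.03)

    def test_same_seed_is_bit_identical(self, scene, grid, protocol):
        vol = rasterize(scene, None, grid)
        a = add_quantum_mottle(vol, 75, protocol, seed=6)
        b = add_quantum_mottle(vol, 75, protocol, seed=6)
        assert np.array_equal(a.data, b.data)

    def test_nonpositive_mas_rejected(self, scene, grid, protocol):
        vol = rasterize(scene, None, grid)
        with pytest.raises(ValueError):
            add_quantum_mottle(vol, 0.0, protocol, seed=0)


class TestMotion:
    def test_zero_velocity_equals_static_rasterization(self, scene, grid, protocol):
        frame, gt = simulate_motion_frame(scene, 0.0, 1.0, protocol, grid)
        static = rasterize(scene, gt, grid, profile="gauss")
        assert np.array_equal(frame.data, static.data)
        assert gt.isclose(RigidTransform.identity(center=scene.axis_point))

    def test_blur_grows_with_velocity(self, scene, grid, protocol):
        static = rasterize(scene, scene.pose_at(0.0), grid, profile="gauss")
        dev = {}
        for omega in (1.0, 30.0):
            frame, _ = simulate_motion_frame(scene, omega, 0.0, protocol, grid)
            dev[omega] = np.max(np.abs(frame.data - static.data))
        assert dev[1.0] < dev[30.0]

    def test_ghost_mode_is_endpoint_average(self, scene, grid, protocol):
        omega, t_mid = 30.0, 0.5
        assert omega * protocol.exposure_window > GHOST_SWEEP_THRESHOLD_DEG
        frame, _ = simulate_motion_frame(scene, omega, t_mid, protocol, grid)
        w = protocol.exposure_window
        lo = rasterize(scene, scene.pose_at(omega * (t_mid - w / 2)), grid, profile="gauss")
        hi = rasterize(scene, scene.pose_at(omega * (t_mid + w / 2)), grid, profile="gauss")
        oracle = 0.5 * lo.data + 0.5 * hi.data
        assert np.allclose(frame.data, oracle, atol=1e-9)

    def test_ground_truth_is_mid_exposure_pose(self, scene, grid, protocol):
        _, gt = simulate_motion_frame(scene, 10.0, 0.75, protocol, grid)
        assert gt.isclose(scene.pose_at(7.5), atol=1e-12)

    def test_negative_velocity_rejected(self, scene, grid, protocol):
        with pytest.raises(ValueError):
            simulate_motion_frame(scene, -1.0, 0.0, protocol, grid)


class TestSimulateExperiment:
    def test_snr_design_has_33_target_frames(self, scene, grid):
        protocol = AcquisitionProtocol.for_experiment("snr", mas=75.0)
        assert protocol.frames == 33
        sim = simulate_experiment(scene, protocol, "snr", grid)
        assert len(sim.targets) == 33

    def test_zcoverage_design_has_9_targets(self, scene, grid):
        protocol = AcquisitionProtocol.for_experiment("zcoverage")
        assert protocol.frames == 9 and protocol.mas == 120.0
        sim = simulate_experiment(scene, protocol, "zcoverage", grid)
        assert len(sim.targets) == 9

    def test_unknown_experiment_rejected(self, scene, grid, protocol):
        with pytest.raises(ValueError):
            simulate_experiment(scene, protocol, "nonsense", grid)

    @pytest.mark.parametrize("experiment", ["snr", "motion"])
    def test_radius_fixed_relative_to_ulna_in_ground_truth(
        self, scene, grid, experiment
    ):
        protocol = AcquisitionProtocol.for_experiment(
            experiment, frames=5, omega_deg_s=10.0
        )
        sim = simulate_experiment(scene, protocol, experiment, grid)
        # both bones share each frame's scene pose, so the radius pose
        # relative to the ulna is the identity in every frame
        for pose in sim.targets.poses:
            rel = np.linalg.inv(pose.matrix) @ pose.matrix
            assert np.allclose(rel, np.eye(4), atol=1e-12)
        assert np.all(np.diff(sim.targets.times) > 0)

    def test_identical_seed_reproduces_bit_identical_frames(self, scene, grid):
        protocol = AcquisitionProtocol.for_experiment("snr", mas=30.0, frames=3, seed=11)
        a = simulate_experiment(scene, protocol, "snr", grid)
        b = simulate_experiment(scene, protocol, "snr", grid)
        assert np.array_equal(a.source.data, b.source.data)
        for va, vb in zip(a.targets.volumes, b.targets.volumes):
            assert np.array_equal(va.data, vb.data)
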