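"""Biplane 3D reconstruction: line fits, orthonormals, pose recovery."""

import numpy as np
import pytest

from cryoloc import annotate as ann
from cryoloc import geometry as geo
from cryoloc import phantom as ph
from cryoloc import recon3d
from cryoloc.postprocess import SeedPoint


def _obs_from_truth(scene, views, noise_px=0.0, rng=None):
    """Build a BiplaneObservation from the scene's exact projections."""
    view_obs = {}
    for g in views:
        seed_uv = np.asarray(scene.per_view[g.label]["true_seed_px"], dtype=float)
        pts = np.asarray(scene.per_view[g.label]["true_centerline_px"], dtype=float).copy()
        if noise_px > 0:
            seed_uv = seed_uv + rng.normal(0, noise_px, 2)
            pts += rng.normal(0, noise_px, pts.shape)
        cl = ann.fit_centerline_spline(pts, smoothing_sigma_px=max(noise_px, 0.1))
        view_obs[g.label] = recon3d.ViewObservation(
            g, SeedPoint(uv=tuple(seed_uv), source="annotated", contour_area_px=9), cl)
    return recon3d.BiplaneObservation(frontal=view_obs["frontal"],
                                      lateral=view_obs["lateral"])


@pytest.fixture(scope="module")
def biplane_views():
    return ph.default_views((512, 512))


class TestFitLine2D:
    def test_collinear_points_along_diagonal(self):
        t = np.arange(20, dtype=float)
        pts = np.stack([t, t], axis=1)
        line = recon3d.fit_line_2d(pts)
        assert np.allclose(np.abs(line.direction), [1, 1] / np.sqrt(2), atol=1e-12)
        assert line.rms_px == pytest.approx(0.0, abs=1e-9)

    def test_direction_points_away_from_first_point(self):
        pts = np.stack([np.arange(20, 0, -1.0), np.zeros(20)], axis=1)  # u decreasing
        line = recon3d.fit_line_2d(pts)
        assert line.direction[0] < 0

    def test_isotropic_cloud_warns_ill_conditioned(self):
        pts = np.array([[0, 1.0], [0, -1], [1, 0], [-1, 0], [0.5, 0.5],
                        [-0.5, 0.5], [0.5, -0.5], [-0.5, -0.5]])
        with pytest.warns(UserWarning, match="ill-conditioned"):
            recon3d.fit_line_2d(pts)

    def test_coincident_points_rejected(self):
        with pytest.raises(recon3d.ReconstructionError):
            recon3d.fit_line_2d(np.ones((5, 2)))

    def test_noisy_line_matches_angle_scan_oracle(self, rng):
        angle_true = np.deg2rad(37.0)
        t = np.linspace(0, 50, 50)
        pts = np.stack([t * np.cos(angle_true), t * np.sin(angle_true)], axis=1)
        pts += rng.normal(0, 0.5, pts.shape)
        line = recon3d.fit_line_2d(pts)
        got_angle = np.arctan2(line.direction[1], line.direction[0])
        assert abs(np.rad2deg(got_angle) - 37.0) < 2.0
        # oracle: scan directions on a 0.1 degree grid, measure rms residual
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        best_rms = np.inf
        for a in np.arange(0.0, 180.0, 0.1):
            d = np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))])
            perp = centered - np.outer(centered @ d, d)
            best_rms = min(best_rms, np.sqrt(np.mean(np.sum(perp**2, axis=1))))
        assert line.rms_px == pytest.approx(best_rms, rel=0.1)


class TestViewOrthonormal:
    def test_identity_view_u_line_through_center_gives_v_axis_normal(self):
        g = geo.build_view("ap", 0.0)
        line = recon3d.FittedLine2D(point=g.detector_center_px,
                                    direction=np.array([1.0, 0.0]), rms_px=0)
        n = recon3d.view_orthonormal(line, g)
        assert np.allclose(np.abs(n), np.abs(g.v_axis), atol=1e-12)

    def test_orthogonal_to_line_and_source_ray(self):
        g = geo.build_view("x", -30.0, 10.0)
        d = np.array([0.6, 0.8])
        line = recon3d.FittedLine2D(point=(10, 20), direction=d, rms_px=0)
        n = recon3d.view_orthonormal(line, g)
        e = recon3d.embed_line_direction(line, g)
        ray = geo.backproject_pixel(g, line.point)
        assert abs(np.dot(n, ray.direction)) < 1e-9
        assert abs(np.dot(n, e)) < 1e-9
        assert abs(np.linalg.norm(n) - 1) < 1e-9
        # through the detector center the source ray is the projection vector
        center_line = recon3d.FittedLine2D(point=g.detector_center_px, direction=d, rms_px=0)
        nc = recon3d.view_orthonormal(center_line, g)
        assert abs(np.dot(nc, g.projection_vector)) < 1e-9

    def test_projected_3d_line_lies_in_plane(self, rng):
        g = geo.build_view("x", 40.0)
        p0 = rng.uniform(-30, 30, 3)
        d3 = rng.normal(size=3)
        d3 /= np.linalg.norm(d3)
        pts3 = p0[None, :] + np.linspace(0, 30, 20)[:, None] * d3[None, :]
        uv = geo.project_points(g, pts3)
        line = recon3d.fit_line_2d(uv)
        n = recon3d.view_orthonormal(line, g)
        assert abs(np.dot(n, d3)) < 1e-6


class TestReconstructPose:
    def test_noiseless_phantom_recovered_exactly(self, biplane_views):
        cfg = ph.PhantomConfig(image_size_px=(512, 512))
        scene = ph.sample_scene(cfg, ph.BalloonModel(), biplane_views, rng_seed=21)
        pose = recon3d.reconstruct_pose(_obs_from_truth(scene, biplane_views))
        assert np.linalg.norm(pose.marker_position_mm - scene.marker_position_mm) < 1e-6
        dot = np.clip(np.dot(pose.shaft_direction, scene.shaft_direction), -1, 1)
        assert np.arccos(abs(dot)) < 1e-6
        assert dot > 0  # sign convention: along the visible shaft
        assert pose.triangulation_residual_mm < 1e-6

    def test_one_pixel_seed_error_bounded(self, biplane_views):
        cfg = ph.PhantomConfig(image_size_px=(512, 512))
        scene = ph.sample_scene(cfg, ph.BalloonModel(), biplane_views, rng_seed=22)
        obs = _obs_from_truth(scene, biplane_views)
        shifted = recon3d.BiplaneObservation(
            frontal=recon3d.ViewObservation(
                obs.frontal.geometry,
                SeedPoint(uv=(obs.frontal.seed.uv[0] + 1.0, obs.frontal.seed.uv[1]),
                          source="annotated", contour_area_px=9),
                obs.frontal.centerline),
            lateral=recon3d.ViewObservation(
                obs.lateral.geometry,
                SeedPoint(uv=(obs.lateral.seed.uv[0], obs.lateral.seed.uv[1] - 1.0),
                          source="annotated", contour_area_px=9),
                obs.lateral.centerline))
        pose = recon3d.reconstruct_pose(shifted)
        err = np.linalg.norm(pose.marker_position_mm - scene.marker_position_mm)
        assert err < 2.0  # ~2 x spacing x depth amplification for the default geometry

    def test_identical_views_degenerate(self, biplane_views):
        cfg = ph.PhantomConfig(image_size_px=(512, 512))
        scene = ph.sample_scene(cfg, ph.BalloonModel(), biplane_views, rng_seed=23)
        obs = _obs_from_truth(scene, biplane_views)
        twice = recon3d.BiplaneObservation(frontal=obs.frontal, lateral=obs.frontal)
        with pytest.raises(geo.DegenerateTriangulationError):
            recon3d.reconstruct_pose(twice)

    def test_missing_detection_raises(self, biplane_views):
        cfg = ph.PhantomConfig(image_size_px=(512, 512))
        scene = ph.sample_scene(cfg, ph.BalloonModel(), biplane_views, rng_seed=24)
        obs = _obs_from_truth(scene, biplane_views)
        broken = recon3d.BiplaneObservation(
            frontal=recon3d.ViewObservation(obs.frontal.geometry, None,
                                            obs.frontal.centerline),
            lateral=obs.lateral)
        with pytest.raises(recon3d.MissingDetectionError):
            recon3d.reconstruct_pose(broken)


class TestAlignBalloon:
    def test_placement_definitions(self):
        pose = geo.Pose3D(marker_position_mm=np.array([5.0, -2, 7]),
                          shaft_direction=np.array([0.0, 0, 1.0]),
                          triangulation_residual_mm=0.1)
        model = ph.BalloonModel()
        placed = recon3d.align_balloon(pose, model)
        assert np.array_equal(placed.marker_center_mm, pose.marker_position_mm)
        assert np.dot(placed.axis, pose.shaft_direction) == pytest.approx(1.0, abs=1e-9)
        expected_center = pose.marker_position_mm + model.marker_offset_mm * pose.shaft_direction
        assert np.allclose(placed.balloon_center_mm, expected_center)

    def test_frame_is_orthonormal(self):
        pose = geo.Pose3D(marker_position_mm=np.zeros(3),
                          shaft_direction=np.array([1.0, 0, 0]),
                          triangulation_residual_mm=0.0)
        a, e1, e2 = recon3d.align_balloon(pose, ph.BalloonModel()).frame()
        for x, y in [(a, e1), (a, e2), (e1, e2)]:
            assert abs(np.dot(x, y)) < 1e-12
        assert all(abs(np.linalg.norm(v) - 1) < 1e-12 for v in (a, e1, e2))


class TestBackprojection:
    def test_noiseless_reconstruction_backprojects_to_zero(self, biplane_views):
        cfg = ph.PhantomConfig(image_size_px=(512, 512))
        scene = ph.sample_scene(cfg, ph.BalloonModel(), biplane_views, rng_seed=25)
        obs = _obs_from_truth(scene, biplane_views)
        pose = recon3d.reconstruct_pose(obs)
        err = recon3d.backprojection_error(pose, obs)
        for label in ("frontal", "lateral"):
            assert err[label]["px"] == pytest.approx(0.0, abs=1e-6)
            assert err[label]["in_view"]

    def test_displacement_along_projection_vector_is_depth_insensitive(self, biplane_views):
        cfg = ph.PhantomConfig(image_size_px=(512, 512))
        scene = ph.sample_scene(cfg, ph.BalloonModel(), biplane_views, rng_seed=26)
        obs = _obs_from_truth(scene, biplane_views)
        pose = recon3d.reconstruct_pose(obs)
        g = obs.frontal.geometry
        depth_dir = pose.marker_position_mm - g.source_position_mm
        depth_dir /= np.linalg.norm(depth_dir)
        moved = geo.Pose3D(
            marker_position_mm=pose.marker_position_mm + 1.0 * depth_dir,
            shaft_direction=pose.shaft_direction,
            triangulation_residual_mm=pose.triangulation_residual_mm)
        err = recon3d.backprojection_error(moved, obs)
        assert err["frontal"]["px"] < 0.05
        assert err["lateral"]["px"] > 0.5

    def test_symmetric_under_view_swap(self, biplane_views):
        cfg = ph.PhantomConfig(image_size_px=(512, 512))
        scene = ph.sample_scene(cfg, ph.BalloonModel(), biplane_views, rng_seed=27)
        obs = _obs_from_truth(scene, biplane_views)
        pose = recon3d.reconstruct_pose(obs)
        swapped = recon3d.BiplaneObservation(frontal=obs.lateral, lateral=obs.frontal)
        a = recon3d.backprojection_error(pose, obs)
        b = recon3d.backprojection_error(pose, swapped)
        assert a["frontal"]["px"] == b["frontal"]["px"]
        assert a["lateral"]["px"] == b["lateral"]["px"]


class TestDiagnostics:
    def _placed(self):
        pose = geo.Pose3D(marker_position_mm=np.array([0.0, 0, 0]),
                          shaft_direction=np.array([0.0, 0, 1.0]),
                          triangulation_residual_mm=0.0)
        return recon3d.align_balloon(pose, ph.BalloonModel())

    def test_overlay_draws_marker_at_projection(self):
        g = geo.build_view("ap", 0.0, size_px=(256, 256))
        img = np.zeros((256, 256), dtype=np.uint8)
        out = recon3d.render_overlay(self._placed(), g, img)
        u, v = geo.project_point(g, [0, 0, 0])
        assert out[int(round(v)), int(round(u))] == 255

    def test_overlay_leaves_background_untouched_and_deterministic(self):
        g = geo.build_view("ap", 0.0, size_px=(256, 256))
        img = np.full((256, 256), 7, dtype=np.uint8)
        a = recon3d.render_overlay(self._placed(), g, img)
        b = recon3d.render_overlay(self._placed(), g, img)
        assert np.array_equal(a, b)
        touched = a != img
        assert 0 < touched.sum() < 0.2 * img.size
        assert (a[~touched] == 7).all()

    def test_mesh_export_is_valid_obj(self, tmp_path):
        path = tmp_path / "balloon.obj"
        recon3d.export_mesh(self._placed(), str(path))
        lines = path.read_text().splitlines()
        n_v = sum(1 for ln in lines if ln.startswith("v "))
        n_f = sum(1 for ln in lines if ln.startswith("f "))
        assert n_v > 100 and n_f > 100
        for ln in lines:
            if ln.startswith("f "):
                idx = [int(t) for t in ln.split()[1:]]
                assert all(1 <= i <= n_v for i in idx)
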