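"""Semiautomatic annotation: template tracking, ridge filtering, skeleton graphs."""

import warnings

import networkx as nx
import numpy as np
import pytest

from cryoloc import annotate as ann
from cryoloc import phantom as ph
from cryoloc import postprocess as post


def _blank(value=200, shape=(64, 64)):
    return np.full(shape, value, dtype=np.uint8)


def _frame_with_marker(center_uv, shape=(64, 64), drop=120, radius=2):
    img = _blank(shape=shape).astype(float)
    uu, vv = np.meshgrid(np.arange(shape[1]), np.arange(shape[0]))
    d = np.hypot(uu - center_uv[0], vv - center_uv[1])
    img -= drop * (d <= radius)
    return np.clip(img, 0, 255).astype(np.uint8)


class TestTemplate:
    def test_template_is_exact_image_patch(self):
        img = np.arange(64 * 64, dtype=np.uint8).reshape(64, 64)
        track = ann.init_marker_template(img, (30, 20))
        assert np.array_equal(track.template, img[15:25, 25:35].astype(float))

    def test_click_near_border_rejected(self):
        with pytest.raises(ann.MarginError):
            ann.init_marker_template(_blank(), (2, 30))

    def test_clean_marker_yields_segmentable_threshold(self):
        img = _frame_with_marker((30, 30))
        track = ann.init_marker_template(img, (30, 30))
        assert (img[25:35, 25:35] < track.threshold_value).sum() >= 1

    def test_uniform_background_warns_empty_segmentation(self):
        with pytest.warns(UserWarning, match="empty"):
            ann.init_marker_template(_blank(), (30, 30))


class TestNccMatch:
    def test_self_match_is_exact_with_unit_score(self, rng):
        img = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        template = img[20:30, 40:50].astype(float)
        (u, v), score = ann.ncc_match(img, template, (45, 25), 8)
        assert (u, v) == (45, 25)
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_translation_equivariance(self, rng):
        img = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        template = img[20:30, 20:30].astype(float)
        shifted = np.roll(np.roll(img, 3, axis=0), -2, axis=1)  # (+3 v, -2 u)
        (u, v), _ = ann.ncc_match(shifted, template, (25, 25), 6)
        assert (u, v) == (23, 28)

    def test_matches_brute_force_ncc_oracle(self, rng):
        img = rng.random((40, 40))
        template = rng.random((8, 8))
        (u, v), score = ann.ncc_match(img, template, (20, 20), 16)
        # oracle: explicit zero-mean unit-variance correlation at every offset
        best = (-np.inf, None)
        t = template - template.mean()
        tn = np.sqrt((t**2).sum())
        for v0 in range(0, 33):
            for u0 in range(0, 33):
                w = img[v0:v0 + 8, u0:u0 + 8]
                wc = w - w.mean()
                denom = np.sqrt((wc**2).sum()) * tn
                if denom <= 0:
                    continue
                c = (wc * t).sum() / denom
                if c > best[0]:
                    best = (c, (u0 + 4, v0 + 4))
        assert (u, v) == best[1]
        assert score == pytest.approx(best[0], abs=1e-9)

    def test_flat_region_raises(self):
        with pytest.raises(ann.FlatRegionError):
            ann.ncc_match(_blank(), np.ones((10, 10)), (30, 30), 5)


class TestAnnotateMarkerRun:
    def test_tracks_drifting_marker_on_phantom_run(self, views_256, clean_config_256):
        scene = ph.sample_scene(clean_config_256, ph.BalloonModel(), views_256, rng_seed=11)
        truths = ph.drift_scene(scene, views_256, clean_config_256, 5)
        frames = [ph.render_view(t, views_256[0], clean_config_256) for t in truths]
        click = tuple(int(round(c)) for c in truths[0].per_view["frontal"]["true_seed_px"])
        run = ann.annotate_marker_run(frames, click)
        assert len(run.masks) == 5
        for mask, idx in zip(run.masks, run.kept_indices):
            cu, cv = ann.mask_centroid(mask)
            tu, tv = truths[idx].per_view["frontal"]["true_seed_px"]
            assert np.hypot(cu - tu, cv - tv) <= 2.0

    def test_single_frame_equals_direct_roi_threshold(self):
        img = _frame_with_marker((31, 29))
        run = ann.annotate_marker_run([img], (31, 29))
        track = ann.init_marker_template(img, (31, 29))
        expected = np.zeros_like(img, dtype=bool)
        expected[24:34, 26:36] = img[24:34, 26:36] < track.threshold_value
        assert len(run.masks) == 1
        assert np.array_equal(run.masks[0], expected)

    def test_background_frame_flagged_and_excluded(self, rng):
        good = _frame_with_marker((30, 30))
        noise_bg = np.clip(200 + rng.normal(0, 2, (64, 64)), 0, 255).astype(np.uint8)
        frames = [good, good, good, noise_bg, good]
        run = ann.annotate_marker_run(frames, (30, 30))
        assert 3 in run.flagged_indices
        assert len(run.masks) == 4
        assert run.truncated_at is None

    def test_persistent_loss_truncates_with_warning(self, rng):
        good = _frame_with_marker((30, 30))
        noise = [np.clip(200 + rng.normal(0, 2, (64, 64)), 0, 255).astype(np.uint8)
                 for _ in range(4)]
        with pytest.warns(UserWarning, match="truncated"):
            run = ann.annotate_marker_run([good, *noise], (30, 30))
        assert run.truncated_at is not None
        assert len(run.masks) == 1


class TestEnhanceShaft:
    def test_dark_line_enhanced_over_background(self):
        img = _blank(shape=(64, 64)).astype(float)
        img[:, 30:33] -= 80  # 3 px wide dark vertical line
        img = img.astype(np.uint8)
        resp = ann.enhance_shaft(img, scales_px=(1, 2, 3))
        on = resp[10:54, 30:33].mean()
        off = np.concatenate([resp[10:54, :25], resp[10:54, 38:]], axis=1).mean()
        assert on > 5 * off

    def test_constant_image_gives_zero_response(self):
        assert np.array_equal(ann.enhance_shaft(_blank()), np.zeros((64, 64)))

    def test_invariant_to_constant_offset(self):
        img = _blank(value=150).astype(float)
        img[:, 30:33] -= 60
        a = ann.enhance_shaft(img.astype(np.uint8), scales_px=(1, 2, 3))
        b = ann.enhance_shaft((img + 40).astype(np.uint8), scales_px=(1, 2, 3))
        assert np.allclose(a, b, atol=1e-6)


class TestBinarizeSkeletonize:
    def test_bar_skeleton_follows_axis(self):
        resp = np.zeros((40, 60))
        resp[18:23, 5:55] = 0.9  # 5 px wide bar
        resp += 0.01 * np.random.default_rng(0).random((40, 60))
        sk = ann.binarize_and_skeletonize(resp)
        vs, us = np.nonzero(sk)
        assert len(us) > 0
        assert (np.abs(vs - 20) <= 1).all()

    def test_gap_closed_into_single_component(self):
        resp = np.zeros((40, 60))
        resp[18:23, 5:28] = 0.9
        resp[18:23, 30:55] = 0.9  # 2 px gap
        sk = ann.binarize_and_skeletonize(resp)
        g = ann.build_skeleton_graph(sk, (30, 20), roi_size_px=60)
        assert nx.number_connected_components(g.graph) == 1
        assert min(n[1] for n in g.nodes) < 15 and max(n[1] for n in g.nodes) > 45

    def test_skeleton_not_larger_than_foreground(self):
        resp = np.zeros((40, 60))
        resp[10:30, 10:50] = 0.8
        sk = ann.binarize_and_skeletonize(resp)
        assert sk.sum() <= (resp > 0).sum()

    def test_empty_response_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            sk = ann.binarize_and_skeletonize(np.zeros((20, 20)))
        assert not sk.any()


def _skeleton_from_nodes(nodes, shape=(60, 60)):
    sk = np.zeros(shape, dtype=bool)
    for v, u in nodes:
        sk[v, u] = True
    return sk


class TestSkeletonGraph:
    def test_straight_segment_through_seed(self):
        nodes = [(30, u) for u in range(20, 40)]
        g = ann.build_skeleton_graph(_skeleton_from_nodes(nodes), (30, 30))
        assert len(g.nodes) == 20
        assert len(g.end_nodes) == 2
        assert g.end_nodes == [(30, 20), (30, 39)]

    def test_y_shape_has_three_ends_one_junction(self):
        nodes = [(30, u) for u in range(18, 31)]
        nodes += [(30 - k, 30 + k) for k in range(1, 9)]
        nodes += [(30 + k, 30 + k) for k in range(1, 9)]
        g = ann.build_skeleton_graph(_skeleton_from_nodes(nodes), (30, 30))
        assert len(g.end_nodes) == 3
        assert sum(1 for n in g.graph.nodes if g.graph.degree(n) == 3) == 1

    def test_disjoint_segments_keep_nearest_to_seed(self):
        near = [(30, u) for u in range(25, 36)]
        far = [(10, u) for u in range(10, 50)]
        g = ann.build_skeleton_graph(_skeleton_from_nodes(near + far), (30, 30))
        assert set(g.nodes) == set(near)

    def test_bridging_merges_components_within_gap(self):
        a = [(30, u) for u in range(14, 26)]
        b = [(30, u) for u in range(32, 46)]  # 6 px gap
        sk = _skeleton_from_nodes(a + b)
        plain = ann.build_skeleton_graph(sk, (29, 30))
        assert set(plain.nodes) == set(b)  # b's nearest pixel is closer to the seed
        bridged = ann.build_skeleton_graph(sk, (29, 30), bridge_gap_px=8.0)
        assert nx.number_connected_components(bridged.graph) == 1
        assert len(bridged.nodes) == len(a) + len(b)
        # bridge edge carries its Euclidean length
        assert bridged.graph[(30, 25)][(30, 32)]["weight"] == pytest.approx(7.0)

    def test_empty_roi_raises(self):
        with pytest.raises(ann.EmptyGraphError):
            ann.build_skeleton_graph(np.zeros((60, 60), dtype=bool), (30, 30))

    def test_edge_weights_axial_one_diagonal_sqrt2(self):
        nodes = [(30, 30), (30, 31), (31, 32)]
        g = ann.build_skeleton_graph(_skeleton_from_nodes(nodes), (30.5, 30.5))
        assert g.graph[(30, 30)][(30, 31)]["weight"] == 1.0
        assert g.graph[(30, 31)][(31, 32)]["weight"] == pytest.approx(np.sqrt(2))


class TestExtractShaftPath:
    def test_straight_segment_fully_recovered(self):
        nodes = [(30, u) for u in range(20, 40)]
        g = ann.build_skeleton_graph(_skeleton_from_nodes(nodes), (30, 30))
        path = ann.extract_shaft_path(g, (150.0, 30.0))  # interval covering 0 deg
        assert len(path) == 20
        assert np.allclose(path[:, 1], 30)

    def test_y_graph_selects_long_branch_pair(self):
        # 30 px horizontal shaft through the seed plus two short spurs
        shaft = [(30, u) for u in range(10, 41)]
        spur1 = [(30 - k, 40 + k) for k in range(1, 6)]
        spur2 = [(30 + k, 40 + k) for k in range(1, 6)]
        g = ann.build_skeleton_graph(
            _skeleton_from_nodes(shaft + spur1 + spur2), (30, 25), roi_size_px=70)
        path = ann.extract_shaft_path(g)
        # oracle: enumerate all end-node pair shortest paths, apply the rules
        ends = g.end_nodes
        best = None
        for i in range(len(ends)):
            for j in range(i + 1, len(ends)):
                length = nx.dijkstra_path_length(g.graph, ends[i], ends[j], weight="weight")
                p = min(tuple(q) for q in nx.all_shortest_paths(
                    g.graph, ends[i], ends[j], weight="weight"))
                sd = min(np.hypot(n[1] - 25, n[0] - 30) for n in p)
                if sd <= 5.0 and (best is None or length > best[0]):
                    best = (length, p)
        got = {(int(v), int(u)) for u, v in path}
        assert got == set(best[1])
        assert (30, 10) in got  # the long shaft branch is included

    def test_interval_excluding_orientation_raises(self):
        nodes = [(30, u) for u in range(20, 40)]  # 0 deg chord
        g = ann.build_skeleton_graph(_skeleton_from_nodes(nodes), (30, 30))
        with pytest.raises(ann.NoPathError):
            ann.extract_shaft_path(g, (45.0, 135.0))

    def test_seed_nearest_end_comes_first(self):
        nodes = [(30, u) for u in range(20, 40)]
        g = ann.build_skeleton_graph(_skeleton_from_nodes(nodes), (22, 30))
        path = ann.extract_shaft_path(g)
        assert tuple(path[0]) == (20.0, 30.0)

    def test_deterministic_across_repeats(self):
        rng = np.random.default_rng(5)
        sk = np.zeros((60, 60), dtype=bool)
        sk[rng.random((60, 60)) < 0.02] = True
        sk[30, 10:50] = True
        paths = []
        for _ in range(3):
            g = ann.build_skeleton_graph(sk, (30, 30), bridge_gap_px=6.0)
            paths.append(ann.extract_shaft_path(g, seed_distance_max_px=5.0))
        assert np.array_equal(paths[0], paths[1])
        assert np.array_equal(paths[1], paths[2])


class TestCenterlineSpline:
    def test_collinear_points_stay_collinear(self):
        path = np.stack([np.arange(30, dtype=float), np.full(30, 12.0)], axis=1)
        cl = ann.fit_centerline_spline(path)
        assert np.allclose(cl.points[:, 1], 12.0, atol=1e-6)
        assert np.linalg.norm(cl.points[0] - path[0]) < 1.0
        assert np.linalg.norm(cl.points[-1] - path[-1]) < 1.0

    def test_smooths_noisy_quadratic_arc(self, rng):
        x = np.linspace(0, 40, 41)
        y = 20 + 0.02 * (x - 20) ** 2
        noisy = np.stack([x, y + rng.normal(0, 0.5, x.size)], axis=1)
        cl = ann.fit_centerline_spline(noisy)
        true_dense = np.stack([np.linspace(0, 40, 400),
                               20 + 0.02 * (np.linspace(0, 40, 400) - 20) ** 2], axis=1)
        err = post.centerline_mean_error(cl.points, true_dense)
        dists = [np.min(np.linalg.norm(true_dense - p, axis=1)) for p in cl.points]
        assert max(dists) < 1.0
        assert err < 0.5

    def test_arc_length_within_five_percent_of_polyline(self, rng):
        x = np.linspace(0, 50, 51)
        y = 10 + 3 * np.sin(x / 8)
        path = np.stack([x, y], axis=1)
        cl = ann.fit_centerline_spline(path)
        poly_len = np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1))
        assert abs(cl.length_px - poly_len) / poly_len < 0.05

    def test_resampling_spacing_is_one_pixel(self):
        path = np.stack([np.arange(25, dtype=float), np.zeros(25)], axis=1)
        cl = ann.fit_centerline_spline(path)
        gaps = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        assert np.all(np.abs(gaps - 1.0) <= 0.1)

    def test_too_short_path_rejected(self):
        with pytest.raises(ann.TooShortPathError):
            ann.fit_centerline_spline(np.array([[0.0, 0], [1, 0], [2, 0]]))


class TestRasterize:
    def test_thickness_one_pixel_count(self):
        path = np.stack([np.arange(5, 35, dtype=float), np.full(30, 20.0)], axis=1)
        cl = ann.fit_centerline_spline(path)
        mask = ann.rasterize_centerline(cl, (64, 64), thickness_px=1)
        assert abs(int(mask.sum()) - 30) <= 1

    def test_thickness_three_area_scales_with_length(self):
        path = np.stack([np.arange(5, 45, dtype=float), np.full(40, 20.0)], axis=1)
        cl = ann.fit_centerline_spline(path)
        mask = ann.rasterize_centerline(cl, (64, 64), thickness_px=3)
        assert mask.sum() == pytest.approx(3 * cl.length_px, rel=0.15)

    def test_out_of_bounds_points_clipped_with_warning(self):
        path = np.stack([np.arange(-5, 20, dtype=float), np.full(25, 10.0)], axis=1)
        cl = ann.fit_centerline_spline(path)
        with pytest.warns(UserWarning, match="clipped"):
            mask = ann.rasterize_centerline(cl, (32, 32))
        assert mask[:, :1].sum() >= 1

    def test_roundtrip_reextraction_close_to_original(self):
        t = np.linspace(0, 1, 45)
        path = np.stack([10 + 40 * t, 20 + 15 * t + 4 * np.sin(3 * t)], axis=1)
        cl = ann.fit_centerline_spline(path)
        mask = ann.rasterize_centerline(cl, (64, 64), thickness_px=1)
        g = ann.build_skeleton_graph(mask, tuple(cl.points[0]), roi_size_px=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            repath = ann.extract_shaft_path(g)
            recl = ann.fit_centerline_spline(repath)
        assert post.centerline_mean_error(recl.points, cl.points) < 0.8
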