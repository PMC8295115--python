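"""Semiautomatic training-mask generation.

Marker masks come from a single manual click in the first frame of a run:
the click is grown to a small rectangular template, the template is tracked
through the run by normalized cross-correlation (local-sums normalization),
and the marker is segmented by a per-run intensity threshold inside the
tracked region of interest. Shaft centerline masks come from classical
curvilinear-structure extraction: invert, equalize, multiscale Hessian
ridge enhancement, binarize, close, skeletonize, convert the skeleton to an
8-connected weighted graph around the marker seed, pick the longest
Dijkstra path between end nodes near the seed inside an orientation
interval, and fit a smoothing spline through it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import interpolate
from skimage import exposure, feature, filters, morphology

__all__ = [
    "AnnotationError",
    "MarginError",
    "FlatRegionError",
    "EmptyGraphError",
    "NoPathError",
    "TooShortPathError",
    "TemplateTrack",
    "MarkerRunAnnotation",
    "SkeletonGraph",
    "Centerline",
    "init_marker_template",
    "ncc_match",
    "annotate_marker_run",
    "enhance_shaft",
    "binarize_and_skeletonize",
    "build_skeleton_graph",
    "extract_shaft_path",
    "fit_centerline_spline",
    "rasterize_centerline",
    "mask_centroid",
]

SQRT2 = float(np.sqrt(2.0))


class AnnotationError(ValueError):
    pass


class MarginError(AnnotationError):
    pass


class FlatRegionError(AnnotationError):
    pass


class EmptyGraphError(AnnotationError):
    pass


class NoPathError(AnnotationError):
    pass


class TooShortPathError(AnnotationError):
    pass


# ---------------------------------------------------------------------------
# Marker annotation: template, NCC tracking, threshold segmentation
# ---------------------------------------------------------------------------

@dataclass
class TemplateTrack:
    """A tracked marker template and its per-frame ROI centers."""

    template: np.ndarray  # (size, size) patch, raw intensities
    threshold_value: float
    roi_center_per_frame: list[tuple[int, int]] = field(default_factory=list)  # (u, v)


@dataclass
class MarkerRunAnnotation:
    """Result of annotating one run: kept masks plus bookkeeping."""

    masks: list[np.ndarray]  # boolean, full frame shape; flagged frames excluded
    kept_indices: list[int]
    flagged_indices: list[int]
    track: TemplateTrack
    truncated_at: int | None = None


def _patch_bounds(center_uv: tuple[int, int], size: int) -> tuple[int, int, int, int]:
    cu, cv = int(round(center_uv[0])), int(round(center_uv[1]))
    half = size // 2
    return cu - half, cu - half + size, cv - half, cv - half + size


def init_marker_template(
    image: np.ndarray,
    click_point: tuple[int, int],
    template_size: int = 10,
    annulus_size: int = 30,
) -> TemplateTrack:
    """Grow a manual click into a marker template with a per-run threshold.

    The segmentation threshold is the midpoint between the darkest pixel
    inside the template and the median of a surrounding annulus (a
    ``annulus_size`` box minus the template box), a seed-only rule standing
    in for the per-run manual calibration.
    """
    h, w = image.shape
    u0, u1, v0, v1 = _patch_bounds(click_point, template_size)
    if u0 < 0 or v0 < 0 or u1 > w or v1 > h:
        raise MarginError(
            f"click {click_point} leaves no {template_size}x{template_size} margin "
            f"inside a {w}x{h} image"
        )
    template = np.asarray(image[v0:v1, u0:u1], dtype=float).copy()

    a0, a1, b0, b1 = _patch_bounds(click_point, annulus_size)
    a0, b0 = max(a0, 0), max(b0, 0)
    a1, b1 = min(a1, w), min(b1, h)
    ring = np.asarray(image[b0:b1, a0:a1], dtype=float).copy()
    inner = np.zeros_like(ring, dtype=bool)
    inner[v0 - b0: v1 - b0, u0 - a0: u1 - a0] = True
    surround = ring[~inner]
    threshold = 0.5 * (float(template.min()) + float(np.median(surround)))
    if not (template < threshold).any():
        warnings.warn(
            "no template pixel falls below the derived threshold; "
            "segmentation of this run may be empty",
            stacklevel=2,
        )
    return TemplateTrack(template=template, threshold_value=threshold,
                         roi_center_per_frame=[(int(round(click_point[0])),
                                                int(round(click_point[1])))])


def ncc_match(
    image: np.ndarray,
    template: np.ndarray,
    search_center: tuple[int, int],
    search_radius_px: int,
) -> tuple[tuple[int, int], float]:
    """Locate the template near ``search_center`` by normalized cross-correlation.

    Correlation uses zero-mean, unit-variance normalization per window (the
    local-sums NCC). Returns the matched template-center pixel ``(u, v)``
    and the peak correlation; ties break toward the smallest (v, then u).
    """
    th, tw = template.shape
    h, w = image.shape
    cu, cv = int(round(search_center[0])), int(round(search_center[1]))
    r = int(search_radius_px)
    u0 = max(cu - tw // 2 - r, 0)
    v0 = max(cv - th // 2 - r, 0)
    u1 = min(cu - tw // 2 + r + tw, w)
    v1 = min(cv - th // 2 + r + th, h)
    window = np.asarray(image[v0:v1, u0:u1], dtype=float)
    if window.shape[0] < th or window.shape[1] < tw:
        raise MarginError("search window smaller than template")
    if np.ptp(window) == 0:
        raise FlatRegionError("correlation undefined everywhere (flat search region)")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = feature.match_template(window, np.asarray(template, dtype=float))
    corr = np.where(np.isfinite(corr), corr, -np.inf)
    if not np.isfinite(corr).any():
        raise FlatRegionError("correlation undefined everywhere (flat search region)")
    idx = int(np.argmax(corr))  # C-order scan = smallest v, then u
    pv, pu = np.unravel_index(idx, corr.shape)
    score = float(corr[pv, pu])
    return (u0 + pu + tw // 2, v0 + pv + th // 2), score


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (u, v) of a boolean mask as the mean of foreground coordinates."""
    vs, us = np.nonzero(mask)
    if len(us) == 0:
        raise AnnotationError("empty mask has no centroid")
    return float(us.mean()), float(vs.mean())


def annotate_marker_run(
    frames: Sequence[np.ndarray],
    click_point: tuple[int, int],
    template_size: int = 10,
    search_radius_px: int = 8,
    area_range_px: tuple[int, int] = (2, 60),
    centroid_jump_max_px: float = 5.0,
    ncc_min: float = 0.5,
    max_consecutive_losses: int = 3,
) -> MarkerRunAnnotation:
    """Annotate the marker through a run from one first-frame click.

    Per frame, the ROI is re-centered by NCC matching around the previous
    center and the marker is segmented by thresholding inside the ROI.
    Outlier frames — segmented area outside ``area_range_px`` or a centroid
    jump above ``centroid_jump_max_px`` — are flagged and excluded from the
    output, as are frames whose NCC peak falls below ``ncc_min`` (the ROI
    then stays put); the run is truncated with a warning after
    ``max_consecutive_losses`` consecutive tracking losses.
    """
    if len(frames) == 0:
        raise AnnotationError("need at least one frame")
    track = init_marker_template(frames[0], click_point, template_size)
    masks: list[np.ndarray] = []
    kept: list[int] = []
    flagged: list[int] = []
    truncated_at: int | None = None
    prev_centroid: tuple[float, float] | None = None
    center = track.roi_center_per_frame[0]
    losses = 0

    for i, frame in enumerate(frames):
        tracked_ok = True
        if i > 0:
            try:
                match, score = ncc_match(frame, track.template, center, search_radius_px)
            except FlatRegionError:
                match, score = center, -1.0
            if score < ncc_min:
                tracked_ok = False
                losses += 1
                if losses >= max_consecutive_losses:
                    warnings.warn(
                        f"tracking lost at frame {i} "
                        f"({losses} consecutive NCC peaks < {ncc_min}); run truncated",
                        stacklevel=2,
                    )
                    truncated_at = i
                    flagged.append(i)
                    break
            else:
                losses = 0
                center = match
            track.roi_center_per_frame.append(center)

        h, w = frame.shape
        u0, u1, v0, v1 = _patch_bounds(center, template_size)
        u0, v0 = max(u0, 0), max(v0, 0)
        u1, v1 = min(u1, w), min(v1, h)
        mask = np.zeros(frame.shape, dtype=bool)
        mask[v0:v1, u0:u1] = frame[v0:v1, u0:u1] < track.threshold_value

        area = int(mask.sum())
        ok = tracked_ok and (area_range_px[0] <= area <= area_range_px[1])
        if ok and prev_centroid is not None:
            c = mask_centroid(mask)
            jump = float(np.hypot(c[0] - prev_centroid[0], c[1] - prev_centroid[1]))
            ok = jump <= centroid_jump_max_px
        if ok:
            prev_centroid = mask_centroid(mask)
            masks.append(mask)
            kept.append(i)
        else:
            flagged.append(i)
    return MarkerRunAnnotation(masks=masks, kept_indices=kept, flagged_indices=flagged,
                               track=track, truncated_at=truncated_at)


# ---------------------------------------------------------------------------
# Shaft annotation: ridge enhancement, skeleton, graph, path, spline
# ---------------------------------------------------------------------------

def enhance_shaft(
    image: np.ndarray,
    scales_px: Sequence[float] = (7.0, 9.0),
    clahe_kernel_px: int = 64,
    clahe_clip_limit: float = 0.02,
) -> np.ndarray:
    """Enhance dark tubular structures; returns a float response in [0, 1].

    Pipeline: invert (dark structures become bright), contrast-limited
    adaptive histogram equalization, multiscale Frangi vesselness (maximum
    over scales), normalize to [0, 1]. Equalization must be local: a global
    remap lets smooth background shading swallow the tube contrast
    wherever the background is locally dark. The vesselness scales should
    bracket the radius of the target tube in pixels; scales much smaller
    than the tube respond to its edges instead of its medial line. The
    defaults match the rendered catheter shaft (~7 px radius at the
    default geometry).
    """
    img = np.asarray(image, dtype=float)
    inverted = (255.0 - img) / 255.0
    if inverted.max() == inverted.min():
        return np.zeros_like(inverted)
    kernel = max(8, min(int(clahe_kernel_px), min(img.shape)))
    equalized = exposure.equalize_adapthist(
        np.clip(inverted, 0.0, 1.0), kernel_size=kernel, clip_limit=clahe_clip_limit)
    response = filters.frangi(equalized, sigmas=tuple(scales_px), black_ridges=False)
    m = float(response.max())
    return response / m if m > 0 else response


def binarize_and_skeletonize(response: np.ndarray, min_object_px: int = 8) -> np.ndarray:
    """Otsu-binarize a ridge response, close small gaps, and skeletonize.

    Foreground specks below ``min_object_px`` are discarded after closing;
    they are noise responses, never part of a curvilinear structure.
    """
    nonzero = response[response > 0]
    if nonzero.size == 0:
        warnings.warn("empty ridge response; returning empty skeleton", stacklevel=2)
        return np.zeros(response.shape, dtype=bool)
    if np.ptp(nonzero) == 0:  # constant positive response: everything is foreground
        binary = response > 0
    else:
        thresh = filters.threshold_otsu(nonzero, nbins=1024)
        binary = response >= thresh
    closed = morphology.closing(binary, footprint=np.ones((3, 3), dtype=bool))
    if min_object_px > 1:
        closed = morphology.remove_small_objects(closed, max_size=min_object_px - 1)
    return morphology.skeletonize(closed)


@dataclass
class SkeletonGraph:
    """Skeleton pixels as an 8-connected weighted graph near the seed.

    Nodes are ``(v, u)`` pixel coordinates; edge weights are 1 for axial
    and sqrt(2) for diagonal adjacency, so path length approximates
    Euclidean arc length.
    """

    graph: nx.Graph
    seed: tuple[float, float]  # (u, v)

    @property
    def nodes(self) -> list[tuple[int, int]]:
        return sorted(self.graph.nodes)

    @property
    def end_nodes(self) -> list[tuple[int, int]]:
        return sorted(n for n in self.graph.nodes if self.graph.degree(n) == 1)


def build_skeleton_graph(
    skeleton: np.ndarray,
    seed: tuple[float, float],
    roi_size_px: int = 50,
    bridge_gap_px: float = 0.0,
) -> SkeletonGraph:
    """Graph the skeleton pixels inside a ROI centered on the seed.

    Only the connected component nearest the seed is kept, yielding a
    single gapless graph. With ``bridge_gap_px > 0``, other components
    whose closest pixel lies within that distance are merged into the seed
    component through straight bridge edges (weighted by Euclidean length)
    before the selection — this closes the skeleton gap that ridge filters
    leave at the blob-like marker.
    """
    h, w = skeleton.shape
    cu, cv = float(seed[0]), float(seed[1])
    if not (0 <= cu <= w - 1 and 0 <= cv <= h - 1):
        raise AnnotationError(f"seed {seed} outside image of shape {skeleton.shape}")
    half = roi_size_px // 2
    u0, u1 = max(int(round(cu)) - half, 0), min(int(round(cu)) - half + roi_size_px, w)
    v0, v1 = max(int(round(cv)) - half, 0), min(int(round(cv)) - half + roi_size_px, h)

    vs, us = np.nonzero(skeleton[v0:v1, u0:u1])
    if len(us) == 0:
        raise EmptyGraphError(
            f"no skeleton pixels inside the {roi_size_px}x{roi_size_px} ROI around {seed}"
        )
    nodes = sorted(zip((vs + v0).tolist(), (us + u0).tolist()))
    node_set = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (nv, nu) in nodes:
        for dv, du in ((0, 1), (1, -1), (1, 0), (1, 1)):  # forward half-neighborhood
            nb = (nv + dv, nu + du)
            if nb in node_set:
                g.add_edge((nv, nu), nb, weight=SQRT2 if dv and du else 1.0)

    if bridge_gap_px > 0:
        while True:
            components = [sorted(c) for c in nx.connected_components(g)]
            if len(components) < 2:
                break
            seed_comp = min(
                components,
                key=lambda c: (min(np.hypot(n[1] - cu, n[0] - cv) for n in c), c[0]),
            )
            best_bridge = None
            sc = np.asarray(seed_comp, dtype=float)
            for other in components:
                if other is seed_comp:
                    continue
                oc = np.asarray(other, dtype=float)
                d2 = ((sc[:, None, :] - oc[None, :, :]) ** 2).sum(axis=2)
                k = int(np.argmin(d2))
                i, j = np.unravel_index(k, d2.shape)
                dist = float(np.sqrt(d2[i, j]))
                cand = (dist, seed_comp[i], other[j])
                if dist <= bridge_gap_px and (best_bridge is None or cand < best_bridge):
                    best_bridge = cand
            if best_bridge is None:
                break
            dist, na, nb = best_bridge
            g.add_edge(na, nb, weight=dist)

    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    best = min(
        components,
        key=lambda c: (min(np.hypot(n[1] - cu, n[0] - cv) for n in c), sorted(c)[0]),
    )
    return SkeletonGraph(graph=g.subgraph(best).copy(), seed=(cu, cv))


def _chord_angle_deg(a: tuple[int, int], b: tuple[int, int]) -> float:
    du, dv = b[1] - a[1], b[0] - a[0]
    return float(np.degrees(np.arctan2(dv, du)) % 180.0)


def _angle_in_interval(angle: float, interval: tuple[float, float]) -> bool:
    lo, hi = interval[0] % 180.0, interval[1] % 180.0
    if interval == (0.0, 180.0) or interval[1] - interval[0] >= 180.0:
        return True
    if lo <= hi:
        return lo <= angle <= hi
    return angle >= lo or angle <= hi


def _seed_to_path_distance(path: list, cu: float, cv: float) -> float:
    """Distance from the seed to the path polyline (point-to-segment)."""
    pts = np.array([(n[1], n[0]) for n in path], dtype=float)
    if len(pts) == 1:
        return float(np.hypot(pts[0, 0] - cu, pts[0, 1] - cv))
    p = np.array([cu, cv])
    a = pts[:-1]
    d = pts[1:] - a
    len2 = np.maximum((d**2).sum(axis=1), 1e-300)
    t = np.clip(((p - a) * d).sum(axis=1) / len2, 0.0, 1.0)
    closest = a + t[:, None] * d
    return float(np.linalg.norm(closest - p, axis=1).min())


def _lex_min_shortest_path(g: nx.Graph, a, b) -> tuple[list, float]:
    length = nx.dijkstra_path_length(g, a, b, weight="weight")
    path = min(tuple(p) for p in nx.all_shortest_paths(g, a, b, weight="weight"))
    return list(path), float(length)


def extract_shaft_path(
    graph: SkeletonGraph,
    orientation_interval_deg: tuple[float, float] = (0.0, 180.0),
    seed_distance_max_px: float = 5.0,
) -> np.ndarray:
    """Select the shaft as the longest end-node shortest path near the seed.

    Dijkstra shortest paths are computed between every end-node pair;
    candidates must have an end-to-end chord orientation (mod 180 degrees)
    inside the interval and pass within ``seed_distance_max_px`` of the
    seed. Among candidates the maximal weighted length wins; ties break
    toward smaller seed distance, then lexicographic end-node order. The
    returned path is an ordered float array of (u, v), seed-nearest end
    first.
    """
    ends = graph.end_nodes
    if len(ends) < 2:
        raise NoPathError(f"graph has {len(ends)} end node(s); need at least 2")
    cu, cv = graph.seed
    candidates = []
    for i in range(len(ends)):
        for j in range(i + 1, len(ends)):
            a, b = ends[i], ends[j]
            path, length = _lex_min_shortest_path(graph.graph, a, b)
            seed_dist = _seed_to_path_distance(path, cu, cv)
            angle = _chord_angle_deg(a, b)
            if seed_dist <= seed_distance_max_px and _angle_in_interval(
                angle, orientation_interval_deg
            ):
                candidates.append((length, seed_dist, (a, b), path))
    if not candidates:
        raise NoPathError(
            f"no end-node path within {seed_distance_max_px} px of the seed has "
            f"orientation in {orientation_interval_deg}"
        )
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    path = candidates[0][3]
    # orient seed-nearest end first
    d_first = np.hypot(path[0][1] - cu, path[0][0] - cv)
    d_last = np.hypot(path[-1][1] - cu, path[-1][0] - cv)
    if d_last < d_first or (d_last == d_first and path[-1] < path[0]):
        path = path[::-1]
    return np.array([(u, v) for (v, u) in path], dtype=float)


@dataclass
class Centerline:
    """Sub-pixel centerline: points at ~1 px arc spacing plus its spline."""

    points: np.ndarray  # (n, 2) of (u, v)
    spline_params: tuple  # scipy (t, c, k) representation
    length_px: float

    def to_dict(self) -> dict:
        return {"points": self.points.tolist(), "length_px": float(self.length_px)}


def fit_centerline_spline(path: np.ndarray, smoothing_sigma_px: float = 0.5) -> Centerline:
    """Fit a cubic smoothing spline through an ordered pixel path.

    Parameterized by cumulative chord length and resampled at 1 px arc
    spacing. ``smoothing_sigma_px`` is the assumed per-point noise scale
    driving the smoothing amount.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 4:
        raise TooShortPathError(f"need at least 4 path points, got {len(path)}")
    # collapse consecutive duplicates, which break the parameterization
    keep = np.ones(len(path), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(path, axis=0), axis=1) > 1e-12
    path = path[keep]
    if len(path) < 4:
        raise TooShortPathError("fewer than 4 distinct path points")

    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))])
    s = len(path) * smoothing_sigma_px**2
    tck, _ = interpolate.splprep([path[:, 0], path[:, 1]], u=chord, k=3, s=s)

    dense_u = np.linspace(chord[0], chord[-1], max(10 * len(path), 100))
    dx, dy = interpolate.splev(dense_u, tck)
    dense = np.stack([dx, dy], axis=1)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    total = float(arc[-1])
    n_out = max(int(round(total)), 1) + 1
    target = np.linspace(0.0, total, n_out)
    u_of_arc = np.interp(target, arc, dense_u)
    px, py = interpolate.splev(u_of_arc, tck)
    points = np.stack([px, py], axis=1)
    return Centerline(points=points, spline_params=tck, length_px=total)


def rasterize_centerline(
    centerline: Centerline,
    image_shape: tuple[int, int],
    thickness_px: int = 1,
) -> np.ndarray:
    """Rasterize a centerline into a binary mask of given thickness.

    Points are rounded to the pixel grid (no anti-aliasing) and dilated to
    the requested thickness; out-of-bounds points are clipped with a
    warning. This is the shaft-net training target.
    """
    h, w = image_shape
    pts = np.asarray(centerline.points, dtype=float)
    cols = np.rint(pts[:, 0]).astype(int)
    rows = np.rint(pts[:, 1]).astype(int)
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} centerline point(s) outside {image_shape}; clipped",
            stacklevel=2,
        )
    mask = np.zeros(image_shape, dtype=bool)
    mask[rows[inside], cols[inside]] = True
    if thickness_px > 1:
        mask = morphology.dilation(mask, morphology.disk((thickness_px - 1) // 2))
    return mask
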