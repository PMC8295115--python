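"""Synthetic biplane fluoroscopy phantom with exact 2D/3D ground truth.

Real cryo-balloon fluoroscopy runs are not distributable, so this module
emulates their salient appearance: a small, very dark elliptical
radio-opaque marker sitting on a dark tubular catheter shaft, over a bright
background with smooth low-frequency variation, anatomy-like clutter
(blobs, vessel-like curves, occasional contrast-agent clouds) and Gaussian
noise. Rendering is additive darkness on an 8-bit canvas — no physical
attenuation model — because every downstream algorithm consumes relative
intensity only.

Ground truth is exact by construction: 3D marker position and shaft curve
are projected through :mod:`cryoloc.geometry`, so the per-view seed point
and centerline truths agree with the projective model to machine precision.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ViewGeometry, build_view, project_point, project_points

__all__ = [
    "BalloonModel",
    "PhantomConfig",
    "SceneTruth",
    "SceneOutOfViewError",
    "default_views",
    "sample_scene",
    "drift_scene",
    "render_view",
    "generate_dataset",
]


class SceneOutOfViewError(ValueError):
    """Raised when the marker projects outside the detector."""


@dataclass(frozen=True)
class BalloonModel:
    """Analytic cryo-balloon model: ellipsoid + shaft with tip + marker.

    Defaults describe a 28 mm device (14 mm equatorial semi-axes). The
    radio-opaque marker is a small ellipsoid centered on the shaft axis,
    offset from the balloon center by ``marker_offset_mm`` along the shaft
    direction (negative: on the balloon side, away from the visible shaft).
    """

    balloon_semi_axes_mm: tuple[float, float, float] = (14.0, 14.0, 12.0)
    shaft_radius_mm: float = 1.75
    shaft_length_mm: float = 45.0
    tip_length_mm: float = 8.0
    marker_offset_mm: float = -20.0
    marker_semi_axes_mm: tuple[float, float, float] = (0.8, 0.8, 0.5)

    def __post_init__(self):
        dims = (*self.balloon_semi_axes_mm, self.shaft_radius_mm,
                self.shaft_length_mm, self.tip_length_mm, *self.marker_semi_axes_mm)
        if any(d <= 0 for d in dims):
            raise ValueError("all balloon model dimensions must be positive")

    @property
    def diameter_mm(self) -> float:
        return 2.0 * max(self.balloon_semi_axes_mm[0], self.balloon_semi_axes_mm[1])


@dataclass(frozen=True)
class PhantomConfig:
    """Rendering and dataset parameters for the phantom."""

    n_frames: int = 5
    image_size_px: tuple[int, int] = (512, 512)
    marker_intensity_drop: float = 120.0
    shaft_intensity_drop: float = 60.0
    background_level: float = 200.0
    background_variation: float = 10.0
    clutter_count: int = 4
    clutter_amplitude: float = 30.0
    contrast_blob_probability: float = 0.2
    noise_sigma: float = 2.0
    drift_px_per_frame: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.contrast_blob_probability <= 1.0):
            raise ValueError("contrast_blob_probability must be in [0, 1]")
        if self.background_level > 255 or self.background_level < 0:
            raise ValueError("background_level must keep pixels in [0, 255]")
        if self.marker_intensity_drop < 0 or self.shaft_intensity_drop < 0:
            raise ValueError("intensity drops must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class SceneTruth:
    """Exact ground truth for one rendered frame.

    ``shaft_direction`` points from the marker along the visible catheter
    shaft; the shaft curve extends from the marker along this direction.
    ``per_view`` maps view label to ``{"true_seed_px": (u, v),
    "true_centerline_px": [(u, v), ...]}``.
    """

    marker_position_mm: np.ndarray
    shaft_direction: np.ndarray
    shaft_curve_3d: np.ndarray
    per_view: dict = field(default_factory=dict)
    rng_seed: int = 0
    scene_id: int = 0
    frame_index: int = 0

    def to_dict(self) -> dict:
        return {
            "scene_id": int(self.scene_id),
            "frame_index": int(self.frame_index),
            "rng_seed": int(self.rng_seed),
            "marker_position_mm": [float(x) for x in self.marker_position_mm],
            "shaft_direction": [float(x) for x in self.shaft_direction],
            "shaft_curve_3d": np.asarray(self.shaft_curve_3d).tolist(),
            "per_view": {
                label: {
                    "true_seed_px": [float(x) for x in d["true_seed_px"]],
                    "true_centerline_px": np.asarray(d["true_centerline_px"]).tolist(),
                }
                for label, d in self.per_view.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneTruth":
        return cls(
            marker_position_mm=np.asarray(d["marker_position_mm"], dtype=float),
            shaft_direction=np.asarray(d["shaft_direction"], dtype=float),
            shaft_curve_3d=np.asarray(d["shaft_curve_3d"], dtype=float),
            per_view={
                label: {
                    "true_seed_px": tuple(v["true_seed_px"]),
                    "true_centerline_px": np.asarray(v["true_centerline_px"], dtype=float),
                }
                for label, v in d["per_view"].items()
            },
            rng_seed=int(d["rng_seed"]),
            scene_id=int(d["scene_id"]),
            frame_index=int(d["frame_index"]),
        )


def default_views(image_size_px: tuple[int, int] = (512, 512)) -> list[ViewGeometry]:
    """The standard biplane pair: frontal RAO30 and lateral LAO40."""
    return [
        build_view("frontal", primary_angle_deg=-30.0, size_px=image_size_px),
        build_view("lateral", primary_angle_deg=40.0, size_px=image_size_px),
    ]


def _view_rng(scene: SceneTruth, geom: ViewGeometry, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        [scene.rng_seed & 0x7FFFFFFF, zlib.crc32(geom.label.encode()), salt]
    )


def _in_plane_half_fov_mm(geom: ViewGeometry) -> float:
    rows, cols = geom.detector_size_px
    half_det_mm = 0.5 * min(rows, cols) * geom.pixel_spacing_mm
    return half_det_mm / geom.magnification


def _compute_per_view(
    marker: np.ndarray, curve: np.ndarray, views: Sequence[ViewGeometry]
) -> dict:
    return {
        g.label: {
            "true_seed_px": project_point(g, marker),
            "true_centerline_px": project_points(g, curve),
        }
        for g in views
    }


def sample_scene(
    config: PhantomConfig,
    balloon: BalloonModel,
    views: Sequence[ViewGeometry],
    rng_seed: int,
    allow_degenerate: bool = False,
    scene_id: int = 0,
) -> SceneTruth:
    """Sample a random 3D scene visible in every view.

    The marker position is uniform in a box around the isocenter (half-width
    50 mm, shrunk to 60% of the smallest in-plane half field of view when
    the detector is small); the shaft direction is uniform on the sphere,
    rejecting directions within 10 degrees of any view's central ray so the
    biplane reconstruction is well posed (``allow_degenerate`` disables the
    rejection for negative tests). The marker is re-sampled until it
    projects at least 16 px inside every detector.
    """
    rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, 0xC0FFEE])
    half_box = min(50.0, 0.6 * min(_in_plane_half_fov_mm(g) for g in views))
    cos_excl = np.cos(np.deg2rad(10.0))

    for _ in range(1000):
        marker = rng.uniform(-half_box, half_box, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        if not allow_degenerate and any(
            abs(float(np.dot(direction, g.projection_vector))) > cos_excl for g in views
        ):
            continue
        margin = 16.0
        ok = True
        for g in views:
            u, v = project_point(g, marker)
            rows, cols = g.detector_size_px
            if not (margin <= u <= cols - 1 - margin and margin <= v <= rows - 1 - margin):
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - rejection loop is generous
        raise RuntimeError("could not sample an in-view, non-degenerate scene")

    # visible shaft runs proximally from the marker along +direction; a short
    # tip stub continues distally into the balloon (-direction)
    s = np.arange(-balloon.tip_length_mm, balloon.shaft_length_mm + 1e-9, 1.0)
    curve = marker[None, :] + s[:, None] * direction[None, :]
    return SceneTruth(
        marker_position_mm=marker,
        shaft_direction=direction,
        shaft_curve_3d=curve,
        per_view=_compute_per_view(marker, curve, views),
        rng_seed=int(rng_seed),
        scene_id=int(scene_id),
    )


def drift_scene(
    scene: SceneTruth,
    views: Sequence[ViewGeometry],
    config: PhantomConfig,
    n_frames: int,
) -> list[SceneTruth]:
    """Derive a run of frames from one scene with small marker drift.

    The marker performs a 3D random walk whose projected step is at most
    ``drift_px_per_frame`` in every view; direction and clutter stay fixed,
    emulating a fluoroscopic run over a static anatomy.
    """
    rng = np.random.default_rng([scene.rng_seed & 0x7FFFFFFF, 0xD217F])

    def step_limit_mm(pos: np.ndarray) -> float:
        # projected step <= drift_px in every view for the current depth
        return config.drift_px_per_frame * min(
            g.pixel_spacing_mm
            * float(np.dot(pos - g.source_position_mm, g.projection_vector))
            / g.source_to_detector_mm
            for g in views
        ) * 0.95

    frames = []
    marker = scene.marker_position_mm.copy()
    for k in range(n_frames):
        if k > 0:
            delta = rng.uniform(-1.0, 1.0, size=3)
            delta *= step_limit_mm(marker) / max(np.linalg.norm(delta), 1e-12)
            marker = marker + delta
        curve = scene.shaft_curve_3d + (marker - scene.marker_position_mm)
        frames.append(
            replace(
                scene,
                marker_position_mm=marker.copy(),
                shaft_curve_3d=curve,
                per_view=_compute_per_view(marker, curve, views),
                frame_index=k,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _smooth_background(shape: tuple[int, int], level: float, amplitude: float,
                       rng: np.random.Generator) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    zoom = (shape[0] / 8.0, shape[1] / 8.0)
    smooth = ndimage.zoom(coarse, zoom, order=3, mode="nearest")[: shape[0], : shape[1]]
    smooth *= amplitude / max(np.abs(smooth).max(), 1e-12)
    return level + smooth


def _distance_to_polyline(shape: tuple[int, int], pts_uv: np.ndarray) -> np.ndarray:
    """Approximate per-pixel distance to a densely resampled polyline."""
    canvas = np.ones(shape, dtype=bool)
    if len(pts_uv) == 0:
        return np.full(shape, np.inf)
    seg = np.diff(pts_uv, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    dense = [pts_uv[:1]]
    for i, L in enumerate(seglen):
        n = max(int(np.ceil(L / 0.25)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        dense.append(pts_uv[i][None, :] + t * seg[i][None, :])
    dense = np.vstack(dense)
    cols = np.rint(dense[:, 0]).astype(int)
    rows = np.rint(dense[:, 1]).astype(int)
    keep = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    if not keep.any():
        return np.full(shape, np.inf)
    canvas[rows[keep], cols[keep]] = False
    return ndimage.distance_transform_edt(canvas)


def _draw_marker(dark: np.ndarray, center_uv: tuple[float, float],
                 axis_uv: np.ndarray, a_px: float, b_px: float, drop: float) -> None:
    h, w = dark.shape
    cu, cv = center_uv
    r = int(np.ceil(max(a_px, b_px))) + 3
    u0, u1 = max(int(cu) - r, 0), min(int(cu) + r + 1, w)
    v0, v1 = max(int(cv) - r, 0), min(int(cv) + r + 1, h)
    if u0 >= u1 or v0 >= v1:
        return
    uu, vv = np.meshgrid(np.arange(u0, u1, dtype=float), np.arange(v0, v1, dtype=float))
    du, dv = uu - cu, vv - cv
    ax = axis_uv / max(np.linalg.norm(axis_uv), 1e-12)
    along = du * ax[0] + dv * ax[1]
    perp = -du * ax[1] + dv * ax[0]
    q = np.sqrt((along / a_px) ** 2 + (perp / b_px) ** 2)
    soft = np.clip((1.0 - q) * min(a_px, b_px) + 0.5, 0.0, 1.0)
    dark[v0:v1, u0:u1] += drop * soft


def render_view(
    scene: SceneTruth, geom: ViewGeometry, config: PhantomConfig,
    balloon: BalloonModel | None = None,
) -> np.ndarray:
    """Render one 8-bit fluoroscopy-like frame of the scene in one view.

    Deterministic per (scene seed, view label, frame index): background and
    clutter depend only on scene and view, noise also on the frame index.
    """
    balloon = balloon or BalloonModel()
    shape = config.image_size_px
    if tuple(geom.detector_size_px) != tuple(shape):
        raise ValueError(
            f"view {geom.label!r} detector size {geom.detector_size_px} differs "
            f"from config image size {shape}"
        )
    seed_uv = scene.per_view[geom.label]["true_seed_px"]
    rows, cols = shape
    if not (0 <= seed_uv[0] <= cols - 1 and 0 <= seed_uv[1] <= rows - 1):
        raise SceneOutOfViewError(
            f"marker projects to {seed_uv} outside the {shape} detector in view {geom.label!r}"
        )

    scene_rng = _view_rng(scene, geom, salt=1)
    img = _smooth_background(shape, config.background_level, config.background_variation, scene_rng)

    dark = np.zeros(shape, dtype=float)
    depth = float(np.dot(scene.marker_position_mm - geom.source_position_mm,
                         geom.projection_vector))
    px_per_mm = geom.source_to_detector_mm / depth / geom.pixel_spacing_mm

    # catheter shaft: anti-aliased dark tube along the projected curve
    center_px = np.asarray(scene.per_view[geom.label]["true_centerline_px"], dtype=float)
    tube_r = balloon.shaft_radius_mm * px_per_mm
    dist = _distance_to_polyline(shape, center_px)
    dark += config.shaft_intensity_drop * np.clip(tube_r + 0.5 - dist, 0.0, 1.0)

    # clutter: alternate dark blobs and vessel-like random-walk curves
    amp = config.clutter_amplitude
    for i in range(config.clutter_count):
        if i % 2 == 0:
            c = scene_rng.uniform(0, [cols - 1, rows - 1])
            sigma = scene_rng.uniform(2.0, 8.0)
            uu, vv = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
            dark += amp * np.exp(-(((uu - c[0]) ** 2 + (vv - c[1]) ** 2) / (2 * sigma**2)))
        else:
            start = scene_rng.uniform(0, [cols - 1, rows - 1])
            heading = scene_rng.uniform(0, 2 * np.pi)
            pts = [start]
            for _ in range(30):
                heading += scene_rng.normal(0.0, 0.3)
                pts.append(pts[-1] + 6.0 * np.array([np.cos(heading), np.sin(heading)]))
            d = _distance_to_polyline(shape, np.asarray(pts))
            dark += amp * np.clip(2.0 - d, 0.0, 1.0) * 0.5
    if scene_rng.uniform() < config.contrast_blob_probability:
        c = scene_rng.uniform(0.25, 0.75, size=2) * [cols - 1, rows - 1]
        sigma = scene_rng.uniform(20.0, 50.0)
        uu, vv = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
        dark += 0.6 * amp * np.exp(-(((uu - c[0]) ** 2 + (vv - c[1]) ** 2) / (2 * sigma**2)))

    # marker: the darkest structure, an ellipse elongated along the shaft
    a_px = max(balloon.marker_semi_axes_mm[2] * px_per_mm, 1.2)
    b_px = max(balloon.marker_semi_axes_mm[0] * px_per_mm, 1.2)
    if len(center_px) >= 2:
        axis_uv = center_px[min(3, len(center_px) - 1)] - center_px[0]
    else:  # pragma: no cover
        axis_uv = np.array([1.0, 0.0])
    _draw_marker(dark, seed_uv, axis_uv, max(a_px, b_px), min(a_px, b_px),
                 config.marker_intensity_drop)

    img = img - dark
    if config.noise_sigma > 0:
        noise_rng = _view_rng(scene, geom, salt=1000 + scene.frame_index)
        img = img + noise_rng.normal(0.0, config.noise_sigma, size=shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _split_counts(n: int, fractions: Sequence[float]) -> list[int]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    bounds = np.floor(np.cumsum(fractions) * n + 1e-9).astype(int)
    counts = np.diff(np.concatenate([[0], bounds]))
    counts[-1] += n - counts.sum()
    return counts.tolist()


def generate_dataset(
    n_scenes: int,
    frames_per_scene: int,
    split_fractions: Sequence[float],
    config: PhantomConfig,
    out_dir: str | Path,
    balloon: BalloonModel | None = None,
    views: Sequence[ViewGeometry] | None = None,
) -> pd.DataFrame:
    """Generate a phantom dataset on disk and return its manifest.

    Scenes (not frames) are assigned to train/val/test splits so frames of
    one run never leak across splits. Layout: ``images/*.png`` (8-bit
    grayscale, one file per frame per view), ``truth/*.json`` (one per
    frame, both views), and ``manifest.csv``.
    """
    balloon = balloon or BalloonModel()
    views = list(views) if views is not None else default_views(config.image_size_px)
    out_dir = Path(out_dir)
    split_names = ["train", "val", "test"][: len(split_fractions)]
    counts = _split_counts(n_scenes, split_fractions)

    rng = np.random.default_rng([config.rng_seed & 0x7FFFFFFF, 0xDA7A])
    order = rng.permutation(n_scenes)
    split_of = {}
    pos = 0
    for name, cnt in zip(split_names, counts):
        for sid in order[pos: pos + cnt]:
            split_of[int(sid)] = name
        pos += cnt

    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    records = []
    try:
        for sid in range(n_scenes):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            base = sample_scene(config, balloon, views, rng_seed=scene_seed, scene_id=sid)
            for frame in drift_scene(base, views, config, frames_per_scene):
                stem = f"scene{sid:04d}_frame{frame.frame_index:03d}"
                truth_path = out_dir / "truth" / f"{stem}.json"
                truth_path.write_text(json.dumps(frame.to_dict()))
                for g in views:
                    img = render_view(frame, g, config, balloon)
                    img_path = out_dir / "images" / f"{stem}_{g.label}.png"
                    iio.imwrite(img_path, img)
                    records.append(
                        {
                            "frame_id": f"{stem}_{g.label}",
                            "scene_id": sid,
                            "frame_index": frame.frame_index,
                            "view": g.label,
                            "split": split_of[sid],
                            "image_path": str(img_path.relative_to(out_dir)),
                            "truth_path": str(truth_path.relative_to(out_dir)),
                        }
                    )
    except OSError as exc:  # pragma: no cover - I/O failure context
        raise OSError(f"phantom dataset write failed under {out_dir}: {exc}") from exc

    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
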