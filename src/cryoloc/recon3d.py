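"""Biplane 3D reconstruction of the marker and catheter direction.

The seed points observed in two views are back-projected and triangulated
(midpoint of the common perpendicular) into the 3D marker position. Each
view's centerline is reduced to a total-least-squares 2D line; embedding
the line direction into the detector plane and crossing it with the view's
projection vector gives the unit normal of the plane spanned by the X-ray
source and the image line. The catheter direction is the cross-product of
the two plane normals — the intersection direction of the two planes — with
its sign chosen so its projections agree with the tip-ward 2D line
directions. The reconstruction is validated by back-projecting the marker
into both views and comparing against the observed seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotate import Centerline
from .geometry import (
    DegenerateTriangulationError,
    Pose3D,
    Ray3D,
    ViewGeometry,
    backproject_pixel,
    project_point,
    project_points,
    triangulate,
)
from .phantom import BalloonModel
from .postprocess import SeedPoint

__all__ = [
    "ReconstructionError",
    "DegenerateDirectionError",
    "MissingDetectionError",
    "FittedLine2D",
    "ViewObservation",
    "BiplaneObservation",
    "PlacedBalloon",
    "fit_line_2d",
    "view_orthonormal",
    "reconstruct_pose",
    "align_balloon",
    "backprojection_error",
    "render_overlay",
    "export_mesh",
]


class ReconstructionError(ValueError):
    pass


class DegenerateDirectionError(ReconstructionError):
    pass


class MissingDetectionError(ReconstructionError):
    pass


@dataclass(frozen=True)
class FittedLine2D:
    """Total-least-squares line through centerline points."""

    point: tuple[float, float]  # centroid (u, v)
    direction: np.ndarray  # unit 2-vector, tip-ward (away from the seed end)
    rms_px: float


@dataclass(frozen=True)
class ViewObservation:
    geometry: ViewGeometry
    seed: SeedPoint | None
    centerline: Centerline | None


@dataclass(frozen=True)
class BiplaneObservation:
    """Paired frontal/lateral observations of the same instant."""

    frontal: ViewObservation
    lateral: ViewObservation

    def views(self) -> tuple[ViewObservation, ViewObservation]:
        return self.frontal, self.lateral


def fit_line_2d(points: np.ndarray) -> FittedLine2D:
    """Fit a line to ordered centerline points by total least squares.

    The direction is the principal axis through the centroid (minimal mean
    squared perpendicular distance); its sign points from the first point
    (the seed end) toward the last, the tip-ward convention. An isotropic
    point cloud (principal-axis ratio below 1.05) triggers an
    ill-conditioned warning.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        raise ReconstructionError("need at least 2 non-coincident points for a line fit")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if len(svals) > 1 and svals[1] > 0 and svals[0] / svals[1] < 1.05:
        warnings.warn(
            f"nearly isotropic point cloud (axis ratio "
            f"{svals[0] / max(svals[1], 1e-300):.3f}); line direction ill-conditioned",
            stacklevel=2,
        )
    chord = pts[-1] - pts[0]
    if float(np.dot(direction, chord)) < 0:
        direction = -direction
    perp = centered - np.outer(centered @ direction, direction)
    rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return FittedLine2D(point=(float(centroid[0]), float(centroid[1])),
                        direction=direction, rms_px=rms)


def embed_line_direction(line: FittedLine2D, geom: ViewGeometry) -> np.ndarray:
    """Lift a 2D detector-plane direction into a world-frame unit 3-vector."""
    d = line.direction
    e = d[0] * geom.u_axis + d[1] * geom.v_axis
    return e / np.linalg.norm(e)


def view_orthonormal(line: FittedLine2D, geom: ViewGeometry) -> np.ndarray:
    """Unit normal of the plane containing the X-ray source and the image line.

    The 2D line direction is embedded into the detector plane and crossed
    with the source-to-line ray through the line's centroid. Any 3D line
    projecting onto the fitted 2D line lies in the plane perpendicular to
    this normal. For a line through the detector center the source ray is
    the projection vector and this reduces to the plain
    line-direction x projection-vector cross-product.
    """
    e = embed_line_direction(line, geom)
    ray = backproject_pixel(geom, line.point)
    n = np.cross(e, ray.direction)
    norm = float(np.linalg.norm(n))
    if norm < 1e-12:
        raise DegenerateDirectionError(
            "embedded line direction parallel to the projection vector"
        )
    return n / norm


def reconstruct_pose(
    obs: BiplaneObservation,
    min_orthonormal_angle_deg: float = 1.0,
) -> Pose3D:
    """Reconstruct the 3D marker position and catheter direction.

    The marker is the triangulation of the back-projected seed points; the
    direction is the cross-product of the two view orthonormals, its sign
    picked so its projection into each view has the larger summed dot
    product with the tip-ward 2D line directions. Orthonormals within
    ``min_orthonormal_angle_deg`` of parallel raise a degeneracy error
    instead of returning a wild estimate.
    """
    for v in obs.views():
        if v.seed is None or v.centerline is None:
            raise MissingDetectionError(
                f"view {v.geometry.label!r} lacks a seed or centerline detection"
            )
    gf, gl = obs.frontal.geometry, obs.lateral.geometry
    ray_f = backproject_pixel(gf, obs.frontal.seed.uv)
    ray_l = backproject_pixel(gl, obs.lateral.seed.uv)
    marker, residual = triangulate(ray_f, ray_l)

    line_f = fit_line_2d(obs.frontal.centerline.points)
    line_l = fit_line_2d(obs.lateral.centerline.points)
    n_f = view_orthonormal(line_f, gf)
    n_l = view_orthonormal(line_l, gl)
    cross = np.cross(n_f, n_l)
    sin_angle = float(np.linalg.norm(cross))
    if sin_angle < np.sin(np.deg2rad(min_orthonormal_angle_deg)):
        raise DegenerateDirectionError(
            f"view orthonormals within {min_orthonormal_angle_deg} deg of parallel "
            f"(sin angle {sin_angle:.3g}); catheter direction unrecoverable"
        )
    direction = cross / sin_angle

    # sign disambiguation: projections must point tip-ward in both views
    score = 0.0
    for geom, line in ((gf, line_f), (gl, line_l)):
        u0, v0 = project_point(geom, marker)
        step = 1.0  # mm along the candidate direction
        u1, v1 = project_point(geom, marker + step * direction)
        proj = np.array([u1 - u0, v1 - v0])
        norm = np.linalg.norm(proj)
        if norm > 1e-12:
            score += float(np.dot(proj / norm, line.direction))
    if score < 0:
        direction = -direction
    return Pose3D(marker_position_mm=marker, shaft_direction=direction,
                  triangulation_residual_mm=residual)


@dataclass(frozen=True)
class PlacedBalloon:
    """A balloon model placed at a reconstructed pose (roll fixed to 0)."""

    model: BalloonModel
    marker_center_mm: np.ndarray
    axis: np.ndarray  # unit vector along the shaft direction

    @property
    def balloon_center_mm(self) -> np.ndarray:
        return self.marker_center_mm + self.model.marker_offset_mm * self.axis

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal frame (axis, e1, e2) with e1, e2 spanning the cross-section."""
        a = self.axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(float(np.dot(a, helper))) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return a, e1, e2


def align_balloon(pose: Pose3D, model: BalloonModel) -> PlacedBalloon:
    """Place the balloon model: marker at the pose position, axis along the shaft."""
    return PlacedBalloon(model=model,
                         marker_center_mm=np.asarray(pose.marker_position_mm, dtype=float),
                         axis=np.asarray(pose.shaft_direction, dtype=float))


def backprojection_error(pose: Pose3D, obs: BiplaneObservation) -> dict:
    """Back-project the reconstructed marker and compare with observed seeds.

    Returns per view label ``{"px": distance, "mm": distance, "in_view":
    bool}``; the distance is always reported even when the projection falls
    outside the detector.
    """
    out = {}
    for v in obs.views():
        if v.seed is None:
            raise MissingDetectionError(f"view {v.geometry.label!r} has no seed")
        geom = v.geometry
        u, p = project_point(geom, pose.marker_position_mm)
        d_px = float(np.hypot(u - v.seed.uv[0], p - v.seed.uv[1]))
        rows, cols = geom.detector_size_px
        out[geom.label] = {
            "px": d_px,
            "mm": d_px * geom.pixel_spacing_mm,
            "in_view": bool(0 <= u <= cols - 1 and 0 <= p <= rows - 1),
        }
    return out


# ---------------------------------------------------------------------------
# Diagnostics: overlay rendering and mesh export
# ---------------------------------------------------------------------------

def _draw_points(canvas: np.ndarray, pts_uv: np.ndarray, value: int) -> None:
    h, w = canvas.shape
    cols = np.rint(pts_uv[:, 0]).astype(int)
    rows = np.rint(pts_uv[:, 1]).astype(int)
    keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    canvas[rows[keep], cols[keep]] = value


def render_overlay(placed: PlacedBalloon, geom: ViewGeometry, image: np.ndarray,
                   value: int = 255) -> np.ndarray:
    """Project model silhouettes onto a frame for visual QC.

    Draws the balloon ellipsoid outline (its limb approximated by three
    great circles), the shaft line, and the marker ellipse outline by
    sampling each curve in 3D and projecting the samples. Pixels off the
    drawn curves are untouched.
    """
    out = np.asarray(image).copy()
    a, e1, e2 = placed.frame()
    t = np.linspace(0.0, 2 * np.pi, 256)
    m = placed.model
    bc = placed.balloon_center_mm
    req = 0.5 * (m.balloon_semi_axes_mm[0] + m.balloon_semi_axes_mm[1])
    rpol = m.balloon_semi_axes_mm[2]
    circles = [
        bc + req * np.outer(np.cos(t), e1) + req * np.outer(np.sin(t), e2),
        bc + rpol * np.outer(np.cos(t), a) + req * np.outer(np.sin(t), e1),
        bc + rpol * np.outer(np.cos(t), a) + req * np.outer(np.sin(t), e2),
    ]
    for c3d in circles:
        _draw_points(out, project_points(geom, c3d), value)
    s = np.linspace(0.0, m.shaft_length_mm, 256)
    shaft = placed.marker_center_mm[None, :] + s[:, None] * a[None, :]
    _draw_points(out, project_points(geom, shaft), value)
    ma, mb = m.marker_semi_axes_mm[2], m.marker_semi_axes_mm[0]
    marker = (placed.marker_center_mm
              + ma * np.outer(np.cos(t), a) + mb * np.outer(np.sin(t), e1))
    _draw_points(out, project_points(geom, marker), value)
    return out


def export_mesh(placed: PlacedBalloon, path: str, n_theta: int = 32, n_phi: int = 16) -> None:
    """Write the placed model as an ASCII OBJ triangle mesh (ellipsoid + shaft tube)."""
    a, e1, e2 = placed.frame()
    m = placed.model
    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []

    def add_grid(grid: np.ndarray) -> None:
        base = len(verts)
        ni, nj = grid.shape[:2]
        verts.extend(grid.reshape(-1, 3))
        for i in range(ni - 1):
            for j in range(nj):
                j2 = (j + 1) % nj
                p = base + i * nj
                faces.append((p + j, p + j2, p + nj + j))
                faces.append((p + j2, p + nj + j2, p + nj + j))

    phi = np.linspace(0.0, np.pi, n_phi)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    req = 0.5 * (m.balloon_semi_axes_mm[0] + m.balloon_semi_axes_mm[1])
    ell = (placed.balloon_center_mm[None, None, :]
           + m.balloon_semi_axes_mm[2] * np.cos(phi)[:, None, None] * a[None, None, :]
           + req * (np.sin(phi)[:, None, None] * np.cos(theta)[None, :, None]) * e1
           + req * (np.sin(phi)[:, None, None] * np.sin(theta)[None, :, None]) * e2)
    add_grid(ell)
    s = np.linspace(0.0, m.shaft_length_mm, 8)
    tube = (placed.marker_center_mm[None, None, :] + s[:, None, None] * a[None, None, :]
            + m.shaft_radius_mm * np.cos(theta)[None, :, None] * e1
            + m.shaft_radius_mm * np.sin(theta)[None, :, None] * e2)
    add_grid(tube)

    with open(path, "w") as fh:
        for v in verts:
            fh.write(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        for f in faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
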