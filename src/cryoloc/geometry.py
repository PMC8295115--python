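"""C-arm projective geometry for biplane fluoroscopy.

A view is an idealized point-source / flat-detector projection model. The
world frame is right-handed with its origin at the isocenter and z pointing
head-ward. At zero angulation the source sits at ``(0, -SOD, 0)`` and the
central ray points along +y; the detector column axis (u) is world +x and
the row axis (v) is world -z, so v increases downward in the image, matching
raster indexing. The primary angle rotates the gantry about the patient's
longitudinal z axis (LAO positive, RAO negative); the secondary angle
rotates about the resulting lateral axis (cranial positive).

Pixels are (u=column, v=row), 0-based, with pixel centers at integer
coordinates; the isocenter projects onto the detector center pixel
``((cols-1)/2, (rows-1)/2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GeometryError",
    "InvalidGeometryError",
    "DegenerateProjectionError",
    "DegenerateTriangulationError",
    "ViewGeometry",
    "Ray3D",
    "Pose3D",
    "build_view",
    "project_point",
    "backproject_pixel",
    "triangulate",
    "load_biplane",
    "save_biplane",
    "DEFAULT_SID_MM",
    "DEFAULT_SOD_MM",
    "DEFAULT_PIXEL_SPACING_MM",
    "DEFAULT_DETECTOR_SIZE_PX",
]

#: Default source-to-detector distance [mm].
DEFAULT_SID_MM = 1200.0
#: Default source-to-isocenter distance [mm].
DEFAULT_SOD_MM = 800.0
#: Default detector pixel spacing [mm/px], derived from the clinical
#: pixel<->mm conversion 1.52 px = 0.56 mm.
DEFAULT_PIXEL_SPACING_MM = 0.56 / 1.52
#: Default detector size (rows, cols).
DEFAULT_DETECTOR_SIZE_PX = (512, 512)


class GeometryError(ValueError):
    """Base class for geometry failures."""


class InvalidGeometryError(GeometryError):
    """Raised for non-physical view parameters."""


class DegenerateProjectionError(GeometryError):
    """Raised when a point cannot be projected (zero or negative depth)."""


class DegenerateTriangulationError(GeometryError):
    """Raised for (near-)parallel rays; carries the inter-ray angle."""

    def __init__(self, message: str, angle_rad: float):
        super().__init__(message)
        self.angle_rad = angle_rad


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


@dataclass(frozen=True)
class ViewGeometry:
    """One C-arm view's projection model."""

    label: str
    primary_angle_deg: float
    secondary_angle_deg: float
    source_to_isocenter_mm: float
    source_to_detector_mm: float
    pixel_spacing_mm: float
    detector_size_px: tuple[int, int]  # (rows, cols)
    projection_vector: np.ndarray = field(repr=False)  # unit, source -> detector center
    u_axis: np.ndarray = field(repr=False)  # detector column axis in world
    v_axis: np.ndarray = field(repr=False)  # detector row axis in world

    @property
    def source_position_mm(self) -> np.ndarray:
        """X-ray source position in world coordinates [mm]."""
        return -self.source_to_isocenter_mm * self.projection_vector

    @property
    def detector_center_px(self) -> tuple[float, float]:
        """(u, v) of the detector center pixel."""
        rows, cols = self.detector_size_px
        return (cols - 1) / 2.0, (rows - 1) / 2.0

    @property
    def magnification(self) -> float:
        """Geometric magnification SID/SOD for objects at isocenter depth."""
        return self.source_to_detector_mm / self.source_to_isocenter_mm

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "primary_angle_deg": float(self.primary_angle_deg),
            "secondary_angle_deg": float(self.secondary_angle_deg),
            "source_to_isocenter_mm": float(self.source_to_isocenter_mm),
            "source_to_detector_mm": float(self.source_to_detector_mm),
            "pixel_spacing_mm": float(self.pixel_spacing_mm),
            "detector_size_px": [int(self.detector_size_px[0]), int(self.detector_size_px[1])],
            "projection_vector": [float(x) for x in self.projection_vector],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ViewGeometry":
        geom = build_view(
            label=d["label"],
            primary_angle_deg=d["primary_angle_deg"],
            secondary_angle_deg=d.get("secondary_angle_deg", 0.0),
            sid_mm=d["source_to_detector_mm"],
            sod_mm=d["source_to_isocenter_mm"],
            spacing_mm=d["pixel_spacing_mm"],
            size_px=tuple(d["detector_size_px"]),
        )
        if "projection_vector" in d:
            stored = np.asarray(d["projection_vector"], dtype=float)
            if not np.allclose(stored, geom.projection_vector, atol=1e-6):
                raise InvalidGeometryError(
                    f"stored projection_vector {stored.tolist()} inconsistent with "
                    f"angles of view {d['label']!r}"
                )
        return geom


@dataclass(frozen=True)
class Ray3D:
    """A 3D ray: origin [mm] plus unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(direction))
        if abs(n - 1.0) > 1e-9:
            direction = direction / n
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction

    def distance_to_point(self, p: Sequence[float]) -> float:
        d = np.asarray(p, dtype=float) - self.origin
        return float(np.linalg.norm(d - np.dot(d, self.direction) * self.direction))


@dataclass(frozen=True)
class Pose3D:
    """Reconstructed 3D marker position and unit catheter-shaft direction."""

    marker_position_mm: np.ndarray
    shaft_direction: np.ndarray
    triangulation_residual_mm: float

    def __post_init__(self):
        pos = np.asarray(self.marker_position_mm, dtype=float)
        d = np.asarray(self.shaft_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("shaft_direction must be a unit vector")
        if self.triangulation_residual_mm < 0:
            raise ValueError("triangulation residual must be non-negative")
        object.__setattr__(self, "marker_position_mm", pos)
        object.__setattr__(self, "shaft_direction", d)

    def to_dict(self) -> dict:
        return {
            "marker_position_mm": [float(x) for x in self.marker_position_mm],
            "shaft_direction": [float(x) for x in self.shaft_direction],
            "triangulation_residual_mm": float(self.triangulation_residual_mm),
        }


def build_view(
    label: str,
    primary_angle_deg: float,
    secondary_angle_deg: float = 0.0,
    sid_mm: float = DEFAULT_SID_MM,
    sod_mm: float = DEFAULT_SOD_MM,
    spacing_mm: float = DEFAULT_PIXEL_SPACING_MM,
    size_px: tuple[int, int] = DEFAULT_DETECTOR_SIZE_PX,
) -> ViewGeometry:
    """Construct a view from clinical C-arm angulation parameters.

    Parameters
    ----------
    label : view name, e.g. ``"frontal"`` or ``"lateral"``.
    primary_angle_deg : rotation about the patient longitudinal axis,
        LAO positive, RAO negative.
    secondary_angle_deg : rotation about the resulting lateral axis,
        cranial positive.
    sid_mm, sod_mm : source-to-detector and source-to-isocenter distances.
    spacing_mm : detector pixel spacing.
    size_px : detector size as (rows, cols).
    """
    if not (sid_mm > sod_mm > 0):
        raise InvalidGeometryError(
            f"require sid > sod > 0, got sid={sid_mm}, sod={sod_mm}"
        )
    if spacing_mm <= 0:
        raise InvalidGeometryError(f"pixel spacing must be positive, got {spacing_mm}")
    rows, cols = int(size_px[0]), int(size_px[1])
    if rows <= 0 or cols <= 0:
        raise InvalidGeometryError(f"detector size must be positive, got {size_px}")

    rot = _rot_z(np.deg2rad(primary_angle_deg)) @ _rot_x(np.deg2rad(secondary_angle_deg))
    n = rot @ np.array([0.0, 1.0, 0.0])
    u_axis = rot @ np.array([1.0, 0.0, 0.0])
    v_axis = rot @ np.array([0.0, 0.0, -1.0])
    return ViewGeometry(
        label=label,
        primary_angle_deg=float(primary_angle_deg),
        secondary_angle_deg=float(secondary_angle_deg),
        source_to_isocenter_mm=float(sod_mm),
        source_to_detector_mm=float(sid_mm),
        pixel_spacing_mm=float(spacing_mm),
        detector_size_px=(rows, cols),
        projection_vector=n,
        u_axis=u_axis,
        v_axis=v_axis,
    )


def project_point(geom: ViewGeometry, p: Sequence[float]) -> tuple[float, float]:
    """Project a 3D world point [mm] to sub-pixel detector coordinates (u, v).

    Perspective projection with division by the source-to-point depth along
    the central ray. The result may lie outside the detector bounds; callers
    check visibility.
    """
    p = np.asarray(p, dtype=float)
    d = p - geom.source_position_mm
    depth = float(np.dot(d, geom.projection_vector))
    if depth <= 1e-9:
        raise DegenerateProjectionError(
            f"point at or behind the source (depth={depth:.3g} mm) in view {geom.label!r}"
        )
    scale = geom.source_to_detector_mm / depth
    cu, cv = geom.detector_center_px
    u = cu + scale * float(np.dot(d, geom.u_axis)) / geom.pixel_spacing_mm
    v = cv + scale * float(np.dot(d, geom.v_axis)) / geom.pixel_spacing_mm
    return u, v


def project_points(geom: ViewGeometry, pts: np.ndarray) -> np.ndarray:
    """Vectorized :func:`project_point` for an (N, 3) array; returns (N, 2)."""
    pts = np.asarray(pts, dtype=float)
    d = pts - geom.source_position_mm
    depth = d @ geom.projection_vector
    if np.any(depth <= 1e-9):
        raise DegenerateProjectionError("point at or behind the source")
    scale = geom.source_to_detector_mm / depth
    cu, cv = geom.detector_center_px
    u = cu + scale * (d @ geom.u_axis) / geom.pixel_spacing_mm
    v = cv + scale * (d @ geom.v_axis) / geom.pixel_spacing_mm
    return np.stack([u, v], axis=-1)


def backproject_pixel(geom: ViewGeometry, uv: Sequence[float]) -> Ray3D:
    """Back-project a detector pixel to the 3D ray from the source through it."""
    u, v = float(uv[0]), float(uv[1])
    cu, cv = geom.detector_center_px
    src = geom.source_position_mm
    det = (
        src
        + geom.source_to_detector_mm * geom.projection_vector
        + (u - cu) * geom.pixel_spacing_mm * geom.u_axis
        + (v - cv) * geom.pixel_spacing_mm * geom.v_axis
    )
    direction = det - src
    return Ray3D(origin=src, direction=direction / np.linalg.norm(direction))


def triangulate(
    ray_a: Ray3D, ray_b: Ray3D, min_angle_rad: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Triangulate two rays as the midpoint of their common perpendicular.

    Returns ``(point_mm, residual_mm)`` where the residual is half the length
    of the common perpendicular segment (the distance from the returned point
    to either ray). Symmetric in argument order.
    """
    da, db = ray_a.direction, ray_b.direction
    cross = np.cross(da, db)
    sin_angle = float(np.linalg.norm(cross))
    angle = float(np.arcsin(min(1.0, sin_angle)))
    if sin_angle < min_angle_rad:
        raise DegenerateTriangulationError(
            f"rays nearly parallel (angle {angle:.3g} rad)", angle_rad=angle
        )
    w0 = ray_a.origin - ray_b.origin
    a = float(np.dot(da, da))
    b = float(np.dot(da, db))
    c = float(np.dot(db, db))
    d = float(np.dot(da, w0))
    e = float(np.dot(db, w0))
    denom = a * c - b * b
    ta = (b * e - c * d) / denom
    tb = (a * e - b * d) / denom
    pa = ray_a.point_at(ta)
    pb = ray_b.point_at(tb)
    midpoint = 0.5 * (pa + pb)
    residual = 0.5 * float(np.linalg.norm(pa - pb))
    return midpoint, residual


# ---------------------------------------------------------------------------
# Biplane configuration I/O
# ---------------------------------------------------------------------------

def save_biplane(views: Sequence[ViewGeometry], path: str | Path) -> None:
    """Write a biplane configuration (two labeled views) as JSON or YAML."""
    path = Path(path)
    payload = {"views": [g.to_dict() for g in views]}
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_biplane(path: str | Path) -> list[ViewGeometry]:
    """Load labeled views from a JSON or YAML biplane configuration file."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in {".yaml", ".yml"}:
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise InvalidGeometryError(f"cannot parse geometry file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "views" not in payload:
        raise InvalidGeometryError(f"geometry file {path} lacks a 'views' list")
    return [ViewGeometry.from_dict(d) for d in payload["views"]]
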