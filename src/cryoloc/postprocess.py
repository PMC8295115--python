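"""Post-processing of predicted soft masks into geometric primitives.

The marker soft mask is thresholded at 20% of its maximum; the centroid of
the largest detected contour (filled-region image moments) becomes the
sub-pixel seed point. The shaft soft mask is thresholded at 1.5% of its
maximum, skeletonized, converted to a skeleton graph around the seed, and
the longest near-seed path is spline fitted into the centerline.

A frame where nothing survives the threshold yields a typed absent result
(``None``), never an exception: non-detection is an expected outcome that
feeds detection-rate statistics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .annotate import (
    AnnotationError,
    Centerline,
    NoPathError,
    TooShortPathError,
    build_skeleton_graph,
    extract_shaft_path,
    fit_centerline_spline,
)

__all__ = [
    "SeedPoint",
    "DetectionRate",
    "MARKER_THRESHOLD_FRACTION",
    "SHAFT_THRESHOLD_FRACTION",
    "marker_seed_from_softmask",
    "centerline_from_softmask",
    "detection_rate",
    "px_to_mm",
    "seed_error",
    "centerline_mean_error",
]

logger = logging.getLogger(__name__)

#: Marker soft masks are binarized at this fraction of their maximum.
MARKER_THRESHOLD_FRACTION = 0.20
#: Shaft soft masks are binarized at this fraction of their maximum.
SHAFT_THRESHOLD_FRACTION = 0.015


@dataclass(frozen=True)
class SeedPoint:
    """Sub-pixel 2D marker location."""

    uv: tuple[float, float]
    source: str  # "annotated" or "predicted"
    contour_area_px: float

    def to_dict(self) -> dict:
        return {
            "uv": [float(self.uv[0]), float(self.uv[1])],
            "source": self.source,
            "contour_area_px": float(self.contour_area_px),
        }


def marker_seed_from_softmask(
    mask: np.ndarray,
    threshold_fraction: float = MARKER_THRESHOLD_FRACTION,
    source: str = "predicted",
) -> Optional[SeedPoint]:
    """Extract the marker seed point from a soft mask.

    Binarizes at ``threshold_fraction`` of the mask maximum, keeps the
    largest connected component, fills it, and returns the centroid of the
    filled region computed from image moments (m10/m00, m01/m00). Returns
    ``None`` when nothing survives the threshold. With multiple components
    the largest is chosen deterministically and the count is logged.
    """
    mask = np.asarray(mask, dtype=float)
    peak = float(mask.max())
    if peak <= 0:
        logger.info("marker soft mask has no positive response; no detection")
        return None
    binary = mask >= threshold_fraction * peak
    labels, n = ndimage.label(binary)
    if n == 0:
        logger.info("marker soft mask empty after thresholding; no detection")
        return None
    if n > 1:
        logger.info("marker soft mask has %d regions; keeping the largest", n)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    region = ndimage.binary_fill_holes(labels == largest)
    vs, us = np.nonzero(region)
    m00 = float(len(us))
    return SeedPoint(
        uv=(float(us.sum() / m00), float(vs.sum() / m00)),
        source=source,
        contour_area_px=m00,
    )


def centerline_from_softmask(
    mask: np.ndarray,
    seed: Optional[SeedPoint],
    threshold_fraction: float = SHAFT_THRESHOLD_FRACTION,
    roi_size_px: int = 50,
    orientation_interval_deg: tuple[float, float] = (0.0, 180.0),
) -> Optional[Centerline]:
    """Extract the shaft centerline from a soft mask around a seed point.

    Binarizes at ``threshold_fraction`` of the mask maximum, closes and
    skeletonizes, builds the skeleton graph restricted to a ROI around the
    seed, selects the longest near-seed path (orientation interval fully
    open by default at inference), and fits the centerline spline. Returns
    ``None`` when the seed is absent or no path is found.
    """
    if seed is None:
        logger.info("no seed point available; shaft extraction skipped")
        return None
    mask = np.asarray(mask, dtype=float)
    peak = float(mask.max())
    if peak <= 0:
        logger.info("shaft soft mask has no positive response; no detection")
        return None
    binary = mask >= threshold_fraction * peak
    closed = morphology.closing(binary, footprint=np.ones((3, 3), dtype=bool))
    skeleton = morphology.skeletonize(closed)
    try:
        graph = build_skeleton_graph(skeleton, seed.uv, roi_size_px=roi_size_px)
        path = extract_shaft_path(graph, orientation_interval_deg)
        return fit_centerline_spline(path)
    except (NoPathError, TooShortPathError, AnnotationError) as exc:
        logger.info("shaft extraction failed: %s", exc)
        return None


@dataclass(frozen=True)
class DetectionRate:
    """Detection statistics over a set of frames."""

    n_detected: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_detected / self.n_total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    def __str__(self) -> str:
        return f"{self.n_detected}/{self.n_total} ({self.percent:.1f}%)"


def detection_rate(results: Sequence[object]) -> DetectionRate:
    """Fraction of non-``None`` entries, reported as a percent with counts."""
    if len(results) == 0:
        raise ValueError("detection rate undefined for an empty result list")
    n_det = sum(1 for r in results if r is not None)
    return DetectionRate(n_detected=n_det, n_total=len(results))


def px_to_mm(d_px: float, pixel_spacing_mm: float) -> float:
    """Convert a pixel distance to millimeters on the detector."""
    if pixel_spacing_mm <= 0:
        raise ValueError(f"pixel spacing must be positive, got {pixel_spacing_mm}")
    return float(d_px) * float(pixel_spacing_mm)


def seed_error(seed: SeedPoint, truth_uv: Sequence[float]) -> float:
    """Euclidean pixel distance between a seed point and a reference point."""
    return float(np.hypot(seed.uv[0] - float(truth_uv[0]), seed.uv[1] - float(truth_uv[1])))


def centerline_mean_error(points: np.ndarray, reference_polyline: np.ndarray) -> float:
    """Mean distance from extracted centerline points to a reference polyline.

    Each point is matched to its nearest point on any segment of the
    reference (exact point-to-segment distances, not vertex snapping).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_polyline, dtype=float))
    if len(ref) == 1:
        return float(np.mean(np.linalg.norm(pts - ref[0], axis=1)))
    a = ref[:-1]  # (M, 2) segment starts
    d = ref[1:] - a  # (M, 2) segment vectors
    len2 = np.maximum((d**2).sum(axis=1), 1e-300)
    # t[n, m]: projection parameter of point n on segment m, clamped to [0, 1]
    t = np.clip(((pts[:, None, :] - a[None, :, :]) * d[None, :, :]).sum(axis=2) / len2,
                0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dists = np.linalg.norm(pts[:, None, :] - closest, axis=2).min(axis=1)
    return float(dists.mean())
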