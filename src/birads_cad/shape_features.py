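"""The 9 mass-shape features (feature ids 1-9).

Three boundary descriptors — continuity, curvature and irregularity — are
computed from an arc-length-uniform resampling of the traced contour, and
six region descriptors come from the convex hull (difference area) and the
"variation" function: the Feret diameter of the mass sampled over a grid
of directions, summarized by its mean, variance, skewness, kurtosis and
Shannon entropy.  Round/oval masses give flat variation profiles and zero
difference area; irregular and spiculated masses raise every one of these
numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from ._stats import shannon_entropy_bits
from .imaging import Contour, MassMask, extract_contour

logger = logging.getLogger(__name__)

DEFAULT_TURN_TOLERANCE = np.pi / 12


@dataclass
class VariationProfile:
    """Feret extent of the mass per projection angle over [0, pi)."""

    angles: np.ndarray
    extent: np.ndarray

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.extent):
            raise ValueError("angle grid and extent profile must align")


@dataclass
class ShapeFeatures:
    continuity: float
    curvature: float
    irregularity: int
    difference_area: float
    mean_variation: float
    variance_variation: float
    skewness_variation: float
    kurtosis_variation: float
    entropy_variation: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.continuity,
                self.curvature,
                float(self.irregularity),
                self.difference_area,
                self.mean_variation,
                self.variance_variation,
                self.skewness_variation,
                self.kurtosis_variation,
                self.entropy_variation,
            ]
        )


def _as_points(contour: Contour | np.ndarray) -> np.ndarray:
    if isinstance(contour, Contour):
        return contour.as_array()
    return np.asarray(contour, dtype=float)


def resample_contour(points: np.ndarray, n_points: int, closed: bool = True) -> np.ndarray:
    """Resample a polyline at ``n_points`` arc-length-uniform positions."""
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0.0:
        return np.repeat(pts[:1], n_points, axis=0)
    if closed:
        targets = np.arange(n_points) * total / n_points
    else:
        targets = np.linspace(0.0, total, n_points)
    rows = np.interp(targets, arc, pts[:, 0])
    cols = np.interp(targets, arc, pts[:, 1])
    return np.column_stack([rows, cols])


def boundary_geometry(
    contour: Contour | np.ndarray,
    n_points: int = 128,
    turn_tolerance: float = DEFAULT_TURN_TOLERANCE,
    closed: bool = True,
) -> tuple[float, float, int]:
    """Continuity, curvature and irregularity of the mass boundary.

    After resampling the boundary at ``n_points`` arc-length-uniform
    positions:

    * continuity — mean squared deviation of the consecutive-point spacing
      from its mean (a smooth evenly-traced boundary gives ~0);
    * curvature — mean squared norm of the discrete second difference of
      the resampled points;
    * irregularity — the number of resampled points where the boundary
      changes direction, i.e. where the turning angle between successive
      segments exceeds ``turn_tolerance`` (default pi/12).
    """
    pts = _as_points(contour)
    if pts.shape[0] < 3:
        raise ValueError("boundary geometry needs at least 3 contour points")
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    res = resample_contour(pts, n_points, closed=closed)
    # suppress rasterization jitter: a ~1-px staircase step is not a
    # direction change of the lesion edge, so the resampled boundary is
    # smoothed with a short circular moving average before the turning
    # angles are measured (window grows with the sampling density)
    window = max(1, n_points // 32)
    if closed and window > 1:
        kernel = np.ones(window) / window
        padded = np.vstack([res[-window:], res, res[:window]])
        res = np.column_stack(
            [
                np.convolve(padded[:, 0], kernel, mode="same")[window:-window],
                np.convolve(padded[:, 1], kernel, mode="same")[window:-window],
            ]
        )
    if closed:
        diffs = np.diff(np.vstack([res, res[:1]]), axis=0)
    else:
        diffs = np.diff(res, axis=0)
    spacing = np.linalg.norm(diffs, axis=1)
    continuity = float(np.mean((spacing - spacing.mean()) ** 2))
    if closed:
        second = np.diff(np.vstack([diffs, diffs[:1]]), axis=0)
        pairs = zip(diffs, np.vstack([diffs[1:], diffs[:1]]))
    else:
        second = np.diff(diffs, axis=0)
        pairs = zip(diffs[:-1], diffs[1:])
    curvature = float(np.mean(np.sum(second**2, axis=1)))
    irregularity = 0
    for a, b in pairs:
        cross = a[0] * b[1] - a[1] * b[0]
        dot = float(np.dot(a, b))
        if abs(np.arctan2(cross, dot)) > turn_tolerance:
            irregularity += 1
    return continuity, curvature, irregularity


def _mask_array(mask: MassMask | np.ndarray) -> np.ndarray:
    return np.asarray(getattr(mask, "mask", mask), dtype=bool)


def hull_pixel_count(mask: MassMask | np.ndarray) -> int:
    """Number of pixel centers inside the convex hull of the mask pixels."""
    pts = np.argwhere(_mask_array(mask))
    if pts.shape[0] == 0:
        raise ValueError("empty mask")
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:
        # Degenerate (single pixel / collinear) sets are their own hull.
        return pts.shape[0]
    r0, c0 = pts.min(axis=0)
    r1, c1 = pts.max(axis=0)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    cand = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    inside = np.all(cand @ a.T + b <= 1e-9, axis=1)
    return int(inside.sum())


def difference_area(mask: MassMask | np.ndarray) -> int:
    """Convex hull pixel count minus mass pixel count (0 for convex masses)."""
    grid = _mask_array(mask)
    return hull_pixel_count(grid) - int(grid.sum())


def variation_profile(mask: MassMask | np.ndarray, n_angles: int = 180) -> VariationProfile:
    """Feret diameter of the mass at ``n_angles`` directions over [0, pi).

    extent(phi) is the maximal absolute projection, onto direction phi, of
    the difference vector between any two mass pixels.  The maximum is
    attained on convex-hull vertices, so only those are projected.
    """
    pts = np.argwhere(_mask_array(mask)).astype(float)
    angles = np.arange(n_angles) * np.pi / n_angles
    if pts.shape[0] < 2:
        logger.warning("variation profile of a <2-pixel mask is all zero")
        return VariationProfile(angles, np.zeros(n_angles))
    try:
        verts = pts[ConvexHull(pts).vertices]
    except QhullError:
        verts = pts
    # direction phi = (cos, sin) in (col, row) axes
    xy = np.column_stack([verts[:, 1], verts[:, 0]])
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = xy @ dirs.T
    extent = proj.max(axis=0) - proj.min(axis=0)
    return VariationProfile(angles, extent)


def variation_stats(profile: VariationProfile) -> tuple[float, float, float, float, float]:
    """Mean, variance, skewness, kurtosis and entropy of the variation.

    Moments use the population convention with non-excess kurtosis; the
    entropy is the Shannon entropy (bits) of the extent sequence
    normalized to sum 1.  A zero-variance profile reports skewness and
    kurtosis of 0 by convention.
    """
    x = np.asarray(profile.extent, dtype=float)
    if x.size == 0:
        raise ValueError("empty variation profile")
    mean = float(x.mean())
    d = x - mean
    var = float(np.mean(d**2))
    if var == 0.0:
        logger.info("zero-variance variation profile: skewness/kurtosis set to 0")
        skew = kurt = 0.0
    else:
        skew = float(np.mean(d**3)) / var**1.5
        kurt = float(np.mean(d**4)) / var**2
    total = x.sum()
    entropy = shannon_entropy_bits(x / total) if total > 0 else 0.0
    return mean, var, skew, kurt, entropy


def shape_features(
    mask: MassMask | np.ndarray,
    contour: Contour | None = None,
    n_points: int = 128,
    n_angles: int = 180,
) -> ShapeFeatures:
    """Assemble the 9 shape features in their fixed id order (1-9)."""
    if contour is None:
        contour = extract_contour(mask)
    continuity, curvature, irregularity = boundary_geometry(contour, n_points=n_points)
    diff_area = difference_area(mask)
    mean, var, skew, kurt, entropy = variation_stats(variation_profile(mask, n_angles))
    return ShapeFeatures(
        continuity=continuity,
        curvature=curvature,
        irregularity=irregularity,
        difference_area=float(diff_area),
        mean_variation=mean,
        variance_variation=var,
        skewness_variation=skew,
        kurtosis_variation=kurt,
        entropy_variation=entropy,
    )
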