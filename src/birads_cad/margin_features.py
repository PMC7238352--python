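"""The 21 mass-margin features (feature ids 12-32).

The margin — the transition zone between the mass and surrounding tissue —
is probed with 32 intensity waveforms of length 64, one per angular sector
of pi/16 around the mass centroid, each sampled radially through a contour
anchor (32 samples inside the mass, 32 outside).  Per waveform an edge
probability vector localizes the intensity transition, and its kurtosis,
Shannon entropy and index of the maximum are summarized across the 32
waveforms with seven statistics.  Circumscribed margins give peaked,
low-entropy edge distributions; obscured or spiculated margins spread the
edge evidence and raise the entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from ._stats import seven_statistics, shannon_entropy_bits
from .imaging import Contour, ROIImage

logger = logging.getLogger(__name__)

N_WAVEFORMS = 32
WAVEFORM_LENGTH = 64
THETA_STEP = np.pi / 16
MARGIN_INDEX = WAVEFORM_LENGTH // 2  # sample coinciding with the anchor

DESCRIPTOR_NAMES = ("kurtosis", "entropy", "index_of_max")


@dataclass
class WaveformSet:
    """32 radial intensity profiles of length 64 around the margin."""

    profiles: np.ndarray  # (32, 64)
    centers: np.ndarray   # (32, 2) anchor (row, col) per waveform
    normals: np.ndarray   # (32, 2) outward unit direction per waveform
    theta_step: float = THETA_STEP

    def __post_init__(self) -> None:
        if self.profiles.shape != (N_WAVEFORMS, WAVEFORM_LENGTH):
            raise ValueError("waveform set must be 32 x 64")

    def to_csv(self, path: str) -> None:
        """Debug dump: one row per waveform, one column per sample."""
        np.savetxt(path, self.profiles, delimiter=",", fmt="%.6f")


@dataclass
class EdgeProbabilityVector:
    """Normalized per-position edge evidence along one waveform."""

    ep: np.ndarray
    offset_index: int  # argmax position relative to the margin (0 = on margin)

    def __post_init__(self) -> None:
        self.ep = np.asarray(self.ep, dtype=float)
        if abs(self.ep.sum() - 1.0) > 1e-9 or (self.ep < 0).any():
            raise ValueError("edge probabilities must be non-negative and sum to 1")


def sample_waveforms(roi: ROIImage, contour: Contour) -> WaveformSet:
    """Sample the 32 perpendicular intensity waveforms along the margin.

    Anchors are the contour points closest in angle (about the mass
    centroid) to the 32 rays spaced every pi/16; each waveform holds 64
    bilinearly interpolated samples at 1-px spacing along the
    centroid-to-anchor direction, with sample index 32 on the anchor.
    Samples falling outside the ROI take the nearest border value.
    """
    pts = contour.as_array()
    if pts.shape[0] < N_WAVEFORMS:
        raise ValueError(
            f"contour has {pts.shape[0]} points; {N_WAVEFORMS} distinct anchors needed"
        )
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    point_angles = np.arctan2(rel[:, 0], rel[:, 1]) % (2 * np.pi)
    ray_angles = np.arange(N_WAVEFORMS) * THETA_STEP
    profiles = np.empty((N_WAVEFORMS, WAVEFORM_LENGTH))
    centers = np.empty((N_WAVEFORMS, 2))
    normals = np.empty((N_WAVEFORMS, 2))
    image = roi.pixels.astype(float)
    offsets = np.arange(WAVEFORM_LENGTH) - MARGIN_INDEX
    for k, phi in enumerate(ray_angles):
        delta = np.angle(np.exp(1j * (point_angles - phi)))
        anchor = pts[np.argmin(np.abs(delta))]
        radial = anchor - centroid
        norm = np.linalg.norm(radial)
        unit = radial / norm if norm > 0 else np.array([np.sin(phi), np.cos(phi)])
        coords = anchor[None, :] + offsets[:, None] * unit[None, :]
        profiles[k] = map_coordinates(image, coords.T, order=1, mode="nearest")
        centers[k] = anchor
        normals[k] = unit
    return WaveformSet(profiles=profiles, centers=centers, normals=normals)


def edge_probability(profile: np.ndarray) -> EdgeProbabilityVector:
    """Edge probability vector of one waveform.

    The profile is smoothed with a 3-sample moving average; the absolute
    first difference (prepended with 0 to keep length 64) is normalized to
    sum 1.  A constant profile carries no edge evidence and yields the
    uniform vector with offset 0.  Ties in the maximum break toward the
    innermost sample.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size != WAVEFORM_LENGTH:
        raise ValueError(f"waveform must have length {WAVEFORM_LENGTH}")
    smoothed = uniform_filter1d(p, size=3, mode="nearest")
    ep = np.concatenate([[0.0], np.abs(np.diff(smoothed))])
    total = ep.sum()
    if total == 0.0:
        logger.info("constant waveform: uniform edge probabilities")
        return EdgeProbabilityVector(np.full(WAVEFORM_LENGTH, 1.0 / WAVEFORM_LENGTH), 0)
    ep /= total
    # round before the argmax so theoretically-equal maxima (a step spread
    # over the smoothing window) tie-break by position, not by float noise
    peak = int(np.argmax(np.round(ep, 9)))
    return EdgeProbabilityVector(ep, peak - MARGIN_INDEX)


def waveform_descriptors(
    ep: EdgeProbabilityVector | np.ndarray,
    offset_index: int | None = None,
) -> tuple[float, float, int]:
    """(kurtosis, entropy, index_of_max) of one edge probability vector.

    Kurtosis is the non-excess 4th-moment ratio of the positional
    distribution weighted by the edge probabilities (0 for a point mass by
    convention); entropy is the Shannon entropy in bits; index_of_max is
    the signed offset of the most probable edge position relative to the
    margin (positive outside the mass, negative inside).
    """
    if isinstance(ep, EdgeProbabilityVector):
        weights = ep.ep
        offset = ep.offset_index
    else:
        weights = np.asarray(ep, dtype=float)
        if offset_index is None:
            offset_index = int(np.argmax(weights)) - weights.size // 2
        offset = offset_index
    positions = np.arange(weights.size) - weights.size // 2
    mu = float(np.sum(weights * positions))
    var = float(np.sum(weights * (positions - mu) ** 2))
    kurt = float(np.sum(weights * (positions - mu) ** 4)) / var**2 if var > 0 else 0.0
    return kurt, shannon_entropy_bits(weights), int(offset)


def margin_features(roi: ROIImage, contour: Contour) -> np.ndarray:
    """The 21 margin features: 3 descriptors x 7 statistics, descriptor-major.

    For each of the 32 waveforms the edge probability vector is reduced to
    (kurtosis, entropy, index_of_max); each descriptor is then summarized
    across waveforms with mean, max, min, std, variance, skewness and
    kurtosis, in that order.
    """
    ws = sample_waveforms(roi, contour)
    descriptors = np.array(
        [waveform_descriptors(edge_probability(p)) for p in ws.profiles]
    )  # (32, 3)
    blocks = [seven_statistics(descriptors[:, j]) for j in range(3)]
    return np.concatenate(blocks)
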