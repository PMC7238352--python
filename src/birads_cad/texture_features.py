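"""The 98 mass-density texture features (feature ids 33-130).

Second-order grey-level statistics: the ROI is quantized to 64 grey
levels, co-occurrence matrices are accumulated at 8 angles
{0, pi/8, ..., 7pi/8} and every integer displacement d in 1..L/2 (L = ROI
side), and the 14 classical Haralick descriptors are computed per matrix.
Descriptors are averaged over the 8 angles at each distance, then each
descriptor's values across distances are summarized with seven statistics,
giving 14 x 7 = 98 features.  Entropic quantities are in bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from ._stats import seven_statistics
from .imaging import MassMask, ROIImage

logger = logging.getLogger(__name__)

ANGLES = tuple(k * np.pi / 8 for k in range(8))

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "mcc",
)

_EPS = np.finfo(float).tiny


@dataclass
class GLCMConfig:
    """Co-occurrence configuration: the 8 fixed angles, distances 1..L/2."""

    levels: int = 64
    symmetric: bool = True
    distances: tuple[int, ...] | None = None  # default derived from ROI side

    def resolve_distances(self, side: int) -> tuple[int, ...]:
        if self.distances is not None:
            if len(self.distances) == 0:
                raise ValueError("distance set must be non-empty")
            return self.distances
        if side < 4:
            raise ValueError(f"ROI side {side} too small for co-occurrence distances")
        return tuple(range(1, side // 2 + 1))


@dataclass
class TextureFeatures:
    values: np.ndarray  # (98,) descriptor-major: 7 statistics per descriptor

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (98,):
            raise ValueError("texture feature vector must have 98 entries")

    def as_array(self) -> np.ndarray:
        return self.values


def quantize(pixels: np.ndarray, levels: int = 64) -> np.ndarray:
    """Min-max quantize grey levels to ``levels`` bins (constant image -> 0)."""
    p = np.asarray(pixels, dtype=float)
    lo, hi = p.min(), p.max()
    if hi == lo:
        return np.zeros(p.shape, dtype=np.uint8)
    q = np.floor((p - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm(
    quantized: np.ndarray,
    d: int,
    alpha: float,
    levels: int = 64,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized (and by default symmetric) co-occurrence matrix.

    Pixel pairs are separated by the integer displacement
    (round(d sin a), round(d cos a)); entries sum to 1.
    """
    if d < 1:
        raise ValueError("distance must be >= 1")
    counts = graycomatrix(
        np.asarray(quantized, dtype=np.uint8),
        distances=[d],
        angles=[alpha],
        levels=levels,
        symmetric=symmetric,
        normed=False,
    )[:, :, 0, 0].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"displacement d={d}, alpha={alpha} exceeds the image")
    return counts / total


def haralick14(P: np.ndarray) -> np.ndarray:
    """The 14 Haralick descriptors of a normalized co-occurrence matrix.

    Order: angular second moment, contrast, correlation, variance (sum of
    squares), inverse difference moment, sum average, sum variance, sum
    entropy, entropy, difference variance, difference entropy, information
    measures of correlation 1 and 2, maximal correlation coefficient
    (square root of the second-largest eigenvalue of the Q matrix).
    Degenerate marginals report correlation and MCC of 0.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if P.ndim != 2 or P.shape[1] != n:
        raise ValueError("co-occurrence matrix must be square")
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)

    asm = float(np.sum(P**2))
    contrast = float(np.sum((ii - jj) ** 2 * P))

    mx = float(np.sum(i * px))
    my = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - mx) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - my) ** 2 * py)))
    if sx > 0 and sy > 0:
        correlation = (float(np.sum(ii * jj * P)) - mx * my) / (sx * sy)
    else:
        logger.info("degenerate GLCM marginals: correlation set to 0")
        correlation = 0.0

    sum_of_squares = float(np.sum((ii - mx) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (ii - jj) ** 2)))

    # distributions of i+j (0..2n-2) and |i-j| (0..n-1)
    psum = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * n - 1)
    pdiff = np.bincount(np.abs(ii - jj).ravel(), weights=P.ravel(), minlength=n)
    k_sum = np.arange(2 * n - 1)
    k_diff = np.arange(n)

    sum_average = float(np.sum(k_sum * psum))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * psum))
    sum_entropy = float(-np.sum(psum[psum > 0] * np.log2(psum[psum > 0])))
    entropy = float(-np.sum(P[P > 0] * np.log2(P[P > 0])))

    diff_mean = float(np.sum(k_diff * pdiff))
    difference_variance = float(np.sum((k_diff - diff_mean) ** 2 * pdiff))
    difference_entropy = float(-np.sum(pdiff[pdiff > 0] * np.log2(pdiff[pdiff > 0])))

    # information measures of correlation (bits throughout)
    pxy = np.outer(px, py)
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    hxy1 = float(-np.sum(P * np.log2(pxy + _EPS)))
    hxy2 = float(-np.sum(pxy * np.log2(pxy + _EPS)))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    mcc = _maximal_correlation_coefficient(P, px, py)

    return np.array(
        [
            asm, contrast, correlation, sum_of_squares, idm, sum_average,
            sum_variance, sum_entropy, entropy, difference_variance,
            difference_entropy, imc1, imc2, mcc,
        ]
    )


def _maximal_correlation_coefficient(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    keep = (px > 0) & (py > 0)
    if keep.sum() < 2:
        logger.info("degenerate GLCM marginals: MCC set to 0")
        return 0.0
    Pk = P[np.ix_(keep, keep)]
    pxk = px[keep]
    pyk = py[keep]
    Q = (Pk / pxk[:, None]) @ (Pk / pyk[None, :]).T
    eig = np.linalg.eigvals(Q)
    lam = np.sort(np.real(eig))[::-1]
    return float(np.sqrt(max(0.0, lam[1])))


def texture_features(
    roi: ROIImage,
    mask: MassMask | None = None,
    cfg: GLCMConfig | None = None,
) -> TextureFeatures:
    """The 98 texture features of a square ROI.

    Co-occurrence statistics are accumulated over the full rectangular ROI
    window (the mass sits at its center; surrounding tissue contributes to
    the density context), not restricted to the mask.  Per distance the 14
    descriptors are averaged over the 8 angles; the seven statistics are
    then taken across the distance axis, descriptor-major.
    """
    cfg = cfg or GLCMConfig()
    side = min(roi.shape)
    distances = cfg.resolve_distances(side)
    q = quantize(roi.pixels, cfg.levels)
    counts = graycomatrix(
        q,
        distances=list(distances),
        angles=list(ANGLES),
        levels=cfg.levels,
        symmetric=cfg.symmetric,
        normed=False,
    ).astype(float)
    per_distance = np.empty((len(distances), 14))
    for di in range(len(distances)):
        vals = np.empty((len(ANGLES), 14))
        for ai in range(len(ANGLES)):
            C = counts[:, :, di, ai]
            total = C.sum()
            if total == 0:
                raise ValueError(
                    f"displacement d={distances[di]} exceeds the ROI at angle index {ai}"
                )
            vals[ai] = haralick14(C / total)
        per_distance[di] = vals.mean(axis=0)
    blocks = [seven_statistics(per_distance[:, k]) for k in range(14)]
    return TextureFeatures(np.concatenate(blocks))
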