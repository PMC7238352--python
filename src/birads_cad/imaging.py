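"""ROI preprocessing and semiautomatic mass segmentation.

Masses are cropped from the mammogram around the reported abnormality
center, contrast-enhanced with classical histogram equalization, and
segmented by seeded region growing: the 8-connected component of pixels at
or above a grey-level threshold, grown from the ROI center pixel.  Because
no single threshold suits every mass, a family of candidate masks is grown
over thresholds spanning the ROI's grey range and one candidate is selected
— automatically (closest equivalent-circle radius to the dataset's
approximate lesion radius) or interactively in place of the expert
radiologist the original protocol relied on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

# Moore neighbourhood in clockwise screen order (row grows downward).
_MOORE = (
    (-1, 0),   # N
    (-1, 1),   # NE
    (0, 1),    # E
    (1, 1),    # SE
    (1, 0),    # S
    (1, -1),   # SW
    (0, -1),   # W
    (-1, -1),  # NW
)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ROIImage:
    """A grey-level region of interest.

    Parameters
    ----------
    pixels
        2-D integer matrix of grey levels in ``0..255``.
    spacing_mm
        Physical pixel size in millimetres (default 0.05 mm = 50 microns,
        a typical digitization resolution for screen-film mammograms).
    source_id
        Free-text provenance tag.
    """

    pixels: np.ndarray
    spacing_mm: float = 0.05
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("ROI must be a non-empty 2-D matrix")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("grey levels must lie in 0..255")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def center(self) -> tuple[int, int]:
        return (self.pixels.shape[0] // 2, self.pixels.shape[1] // 2)


@dataclass
class MassMask:
    """Binary mass region grown from a seed pixel."""

    mask: np.ndarray
    seed: tuple[int, int]
    validate: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.validate:
            if not self.mask[self.seed]:
                raise ValueError("seed pixel must belong to the mask")
            _, n = ndimage.label(self.mask, structure=_EIGHT)
            if n != 1:
                raise ValueError("mask must be a single 8-connected region")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def equivalent_radius(self) -> float:
        """Radius of the circle with the same pixel area."""
        return float(np.sqrt(self.area_px / np.pi))


@dataclass
class Contour:
    """Ordered closed boundary pixel sequence of a mask."""

    points: list[tuple[int, int]]
    orientation: str = "clockwise"

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Fill the closed contour back into a binary mask."""
        canvas = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.points)
        canvas[rows, cols] = True
        return ndimage.binary_fill_holes(canvas)


def crop_roi(
    image: np.ndarray,
    center: tuple[int, int],
    radius: int,
    spacing_mm: float = 0.05,
    source_id: str = "",
) -> ROIImage:
    """Crop the square window of side ``2*radius + 1`` around ``center``.

    The window is clamped at the image borders; coordinates are 0-based
    ``(row, col)`` and the window bounds are inclusive.
    """
    image = np.asarray(image)
    r, c = center
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"center {center} outside image of shape {image.shape}")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r0, r1 = max(0, r - radius), min(image.shape[0] - 1, r + radius)
    c0, c1 = max(0, c - radius), min(image.shape[1] - 1, c + radius)
    window = image[r0 : r1 + 1, c0 : c1 + 1].copy()
    return ROIImage(window, spacing_mm=spacing_mm, source_id=source_id)


def equalize_histogram(roi: ROIImage) -> ROIImage:
    """Classical cumulative-distribution histogram equalization.

    Each grey level ``v`` is remapped to ``round(255 * CDF(v))`` where the
    CDF is taken over the full declared range 0..255.  The mapping is
    monotone non-decreasing, so the rank order of grey levels is preserved.
    """
    pixels = roi.pixels.astype(np.int64)
    hist = np.bincount(pixels.ravel(), minlength=256)
    cdf = np.cumsum(hist) / pixels.size
    lut = np.rint(255.0 * cdf).astype(np.int64)
    return ROIImage(lut[pixels], spacing_mm=roi.spacing_mm, source_id=roi.source_id)


def region_grow(roi: ROIImage, threshold: float) -> MassMask:
    """Grow the mass region from the ROI center pixel at a grey threshold.

    The mask is the 8-connected component, containing the center seed, of
    all pixels with grey level >= ``threshold`` (masses are hyperintense
    relative to surrounding tissue).  If the seed itself fails the test the
    mask degenerates to the seed alone.
    """
    seed = roi.center
    above = roi.pixels >= threshold
    if not above[seed]:
        mask = np.zeros_like(above)
        mask[seed] = True
        return MassMask(mask, seed=seed)
    labels, _ = ndimage.label(above, structure=_EIGHT)
    return MassMask(labels == labels[seed], seed=seed)


def generate_candidates(roi: ROIImage, n_thresholds: int = 16) -> list[MassMask]:
    """Grow one candidate mask per threshold spanning the ROI grey range.

    Thresholds are ``n_thresholds`` values evenly spaced over the ROI's
    [min, max] grey levels (the midpoint when a single threshold is
    requested).  Because the growth predicate is ``>= threshold``, masks
    for increasing thresholds are nested.
    """
    if n_thresholds < 1:
        raise ValueError("n_thresholds must be >= 1")
    gmin, gmax = float(roi.pixels.min()), float(roi.pixels.max())
    if gmin == gmax:
        logger.warning("constant ROI: single region-growing candidate")
        return [region_grow(roi, gmin)]
    if n_thresholds == 1:
        thresholds = [(gmin + gmax) / 2.0]
    else:
        thresholds = np.linspace(gmin, gmax, n_thresholds)
    return [region_grow(roi, t) for t in thresholds]


def select_candidate(
    candidates: Sequence[MassMask],
    target_radius: float | None = None,
    strategy: str = "auto",
    chooser: Callable[[Sequence[MassMask]], int] | None = None,
) -> MassMask:
    """Pick the final mask from the grown candidates.

    ``auto`` returns the candidate whose equivalent-circle radius
    ``sqrt(area / pi)`` is closest to ``target_radius`` (the approximate
    lesion radius reported with the dataset), breaking ties toward the
    larger mask.  ``interactive`` delegates to ``chooser`` (or a terminal
    prompt), standing in for the expert radiologist of the original
    protocol.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    if strategy == "auto":
        if target_radius is None:
            raise ValueError("auto selection requires a target radius")
        return min(
            candidates,
            key=lambda m: (abs(m.equivalent_radius - target_radius), -m.area_px),
        )
    if strategy == "interactive":
        if chooser is None:
            chooser = _prompt_chooser
        index = int(chooser(candidates))
        return candidates[index]
    raise ValueError(f"unknown strategy {strategy!r}")


def _prompt_chooser(candidates: Sequence[MassMask]) -> int:
    for i, m in enumerate(candidates):
        print(f"[{i}] area={m.area_px} px, equivalent radius={m.equivalent_radius:.1f} px")
    return int(input("candidate index: "))


def fill_holes(mask: MassMask) -> MassMask:
    """Fill interior holes so the boundary is a single closed loop."""
    return MassMask(ndimage.binary_fill_holes(mask.mask), seed=mask.seed)


def extract_contour(mask: MassMask | np.ndarray) -> Contour:
    """Moore boundary tracing, clockwise from the topmost-leftmost pixel.

    Returns the closed boundary pixel sequence without repeating the start
    point (closure is implicit).  The mask must be non-empty and
    8-connected; for masks with interior holes only the outer boundary is
    traced (fill holes first if the round trip must be exact).
    """
    grid = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    coords = np.argwhere(grid)
    if coords.size == 0:
        raise ValueError("empty mask has no contour")
    _, n = ndimage.label(grid, structure=_EIGHT)
    if n != 1:
        raise ValueError("contour tracing requires a single connected region")
    start = tuple(coords[np.lexsort((coords[:, 1], coords[:, 0]))[0]])
    if coords.shape[0] == 1:
        return Contour([start])

    def in_mask(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < grid.shape[0] and 0 <= c < grid.shape[1] and grid[r, c]

    def step(current, prev):
        prev_idx = _MOORE.index((prev[0] - current[0], prev[1] - current[1]))
        for i in range(1, 9):
            d = _MOORE[(prev_idx + i) % 8]
            cand = (current[0] + d[0], current[1] + d[1])
            if in_mask(cand):
                before = _MOORE[(prev_idx + i - 1) % 8]
                return cand, (current[0] + before[0], current[1] + before[1])
        return None, None

    # The west neighbour of the topmost-leftmost pixel is guaranteed
    # outside the mask, so it is a valid initial backtrack position.  The
    # walk stops when it is about to repeat its first transition (the
    # next state is fully determined by the pixel entered and the
    # direction of entry, so the cycle closes exactly there).
    points = [start]
    current, prev = start, (start[0], start[1] - 1)
    second = None
    for _ in range(8 * coords.shape[0] + 16):
        nxt, new_prev = step(current, prev)
        if nxt is None:  # isolated pixel; handled above, defensive only
            break
        if second is None:
            second = nxt
        elif current == start and nxt == second:
            break
        points.append(nxt)
        current, prev = nxt, new_prev
    else:
        raise RuntimeError("boundary tracing failed to close")
    if len(points) > 1 and points[-1] == start:
        points.pop()
    return Contour(points)


def read_roi(path: str, spacing_mm: float = 0.05) -> ROIImage:
    """Read an 8-bit greyscale PNG/TIFF/PGM file as an ROI."""
    with Image.open(path) as img:
        data = np.asarray(img.convert("L"))
    return ROIImage(data, spacing_mm=spacing_mm, source_id=str(path))


def write_mask(path: str, mask: MassMask) -> None:
    """Write a binary mask as a 0/255 greyscale PNG."""
    Image.fromarray(np.where(mask.mask, 255, 0).astype(np.uint8)).save(path)


def write_candidate_gallery(directory: str, candidates: Sequence[MassMask]) -> list[str]:
    """Write indexed candidate-mask PNGs for interactive inspection."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, mask in enumerate(candidates):
        path = os.path.join(directory, f"candidate_{i:02d}.png")
        write_mask(path, mask)
        paths.append(path)
    return paths
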