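"""Deterministic lesion phantoms and synthetic feature tables.

Every pipeline stage is testable without mammography data.  A phantom is
a star-convex bright lesion on a darker background, parameterized along
the three descriptor axes the feature families measure:

* shape — the boundary radius is modulated by low-order cosine harmonics
  of a given total amplitude (0 = perfect disc, large = irregular or
  spiculated outline);
* margin — the rasterized edge is blurred with a Gaussian of given sigma
  (0 = circumscribed, large = obscured/ill-defined margin);
* density — the interior grey contrast over the background.

The four category archetypes map monotonically onto these axes: B2 is a
round, sharp, high-contrast lesion and B5 an irregular, blurred,
low-contrast one, mirroring how the BI-RADS lexicon orders descriptors
from least to most suspicious.  Synthetic patient ages drift upward with
category.  Feature tables for GA testing plant a chosen subset of
informative columns whose class-conditional means drift ordinally with
the category at a given standardized effect size; all other columns are
class-independent standard normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .feature_table import LABELS, N_FEATURES, feature_column
from .imaging import MassMask, ROIImage

BACKGROUND_GREY = 60.0

#: per-category (boundary amplitude px, harmonics, edge blur px, contrast, age mean)
CATEGORY_DEFAULTS: dict[str, dict] = {
    "B2": dict(amplitude=0.0, harmonics=(), edge_blur_sigma=0.5, interior_contrast=110.0, age_mean=46.0),
    "B3": dict(amplitude=1.5, harmonics=(3, 4), edge_blur_sigma=1.0, interior_contrast=95.0, age_mean=53.0),
    "B4": dict(amplitude=3.0, harmonics=(5, 7), edge_blur_sigma=2.0, interior_contrast=80.0, age_mean=60.0),
    "B5": dict(amplitude=5.0, harmonics=(8, 11, 13), edge_blur_sigma=3.0, interior_contrast=65.0, age_mean=67.0),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic lesion.

    Unset fields default to the archetype of ``category``.
    """

    category: str = "B2"
    radius_px: float = 20.0
    amplitude: float | None = None
    harmonics: tuple[int, ...] | None = None
    edge_blur_sigma: float | None = None
    interior_contrast: float | None = None
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in LABELS:
            raise ValueError(f"unknown category {self.category!r}")
        defaults = CATEGORY_DEFAULTS[self.category]
        if self.amplitude is None:
            self.amplitude = defaults["amplitude"]
        if self.harmonics is None:
            self.harmonics = defaults["harmonics"]
        if self.edge_blur_sigma is None:
            self.edge_blur_sigma = defaults["edge_blur_sigma"]
        if self.interior_contrast is None:
            self.interior_contrast = defaults["interior_contrast"]
        if min(self.amplitude, self.edge_blur_sigma, self.interior_contrast) < 0:
            raise ValueError("amplitude, blur and contrast must be non-negative")
        if self.radius_px < 5:
            raise ValueError("phantom radius must be >= 5 px")


@dataclass
class SyntheticTableSpec:
    """Parameters of a synthetic labeled feature table."""

    n_cases: int = 200
    informative_ids: tuple[int, ...] = (3, 17, 60)
    class_effect_size: float = 2.0
    n_features: int = N_FEATURES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases % len(LABELS) != 0:
            raise ValueError("n_cases must be divisible by the 4 classes")
        bad = [i for i in self.informative_ids if not 1 <= i <= self.n_features]
        if bad:
            raise ValueError(f"informative ids outside 1..{self.n_features}: {bad}")


def make_phantom(spec: PhantomSpec) -> tuple[ROIImage, MassMask, dict]:
    """Rasterize one lesion phantom with its ground-truth mask.

    The boundary is r(phi) = R + sum_k a_k cos(k phi + phase_k) with the
    total amplitude split over the harmonics and phases drawn from the
    seed; the interior is brightened by the contrast, the edge blurred,
    and Gaussian noise added.  Fully determined by the parameters and seed.
    """
    rng = np.random.default_rng(spec.seed)
    harmonics = spec.harmonics or ()
    amps = (
        np.full(len(harmonics), spec.amplitude / len(harmonics))
        if harmonics
        else np.zeros(0)
    )
    phases = rng.uniform(0, 2 * np.pi, size=len(amps))

    pad = int(np.ceil(spec.amplitude + 4 * spec.edge_blur_sigma + 6))
    half = int(np.ceil(spec.radius_px)) + pad
    side = 2 * half + 1
    center = half
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    dr, dc = rr - center, cc - center
    phi = np.arctan2(dr, dc)
    rho = np.hypot(dr, dc)
    boundary = spec.radius_px + sum(
        a * np.cos(k * phi + p) for a, k, p in zip(amps, harmonics, phases)
    )
    if np.ndim(boundary) and float(np.min(boundary)) < 2.0:
        raise ValueError("boundary harmonics too strong: self-intersecting outline")
    truth = rho <= boundary

    image = BACKGROUND_GREY + spec.interior_contrast * truth.astype(float)
    if spec.edge_blur_sigma > 0:
        image = gaussian_filter(image, sigma=spec.edge_blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    roi = ROIImage(image, source_id=f"phantom-{spec.category}-{spec.seed}")
    mask = MassMask(truth, seed=(center, center))
    age_defaults = CATEGORY_DEFAULTS[spec.category]["age_mean"]
    meta = {
        "category": spec.category,
        "age_years": float(np.clip(rng.normal(age_defaults, 8.0), 25.0, 90.0)),
        "approx_radius_px": float(np.sqrt(mask.area_px / np.pi)),
        "spacing_mm": roi.spacing_mm,
    }
    return roi, mask, meta


def make_feature_table(spec: SyntheticTableSpec) -> pd.DataFrame:
    """Balanced labeled table with planted informative features.

    Every informative column is a class-shifted unit-variance Gaussian:
    its mean for class k (B2..B5 -> k = 0..3) is ``effect_size * k``, a
    standardized separation of ``effect_size`` between adjacent
    categories, mirroring how BI-RADS descriptors drift monotonically
    with the suspicion level.  Informative features are therefore
    individually discriminative and jointly complementary (averaging
    independent noise); all other columns are class-independent standard
    normal noise.
    """
    rng = np.random.default_rng(spec.seed)
    per_class = spec.n_cases // len(LABELS)
    labels = np.repeat(LABELS, per_class)
    class_idx = np.repeat(np.arange(len(LABELS)), per_class)
    X = rng.standard_normal((spec.n_cases, spec.n_features))
    for fid in spec.informative_ids:
        X[:, fid - 1] += spec.class_effect_size * class_idx
    table = pd.DataFrame(
        X, columns=[feature_column(fid) for fid in range(1, spec.n_features + 1)]
    )
    table.insert(0, "label", labels)
    table.insert(0, "case_id", [f"case_{i:04d}" for i in range(spec.n_cases)])
    return table


def make_cohort(
    n_cases: int,
    radius_px: float = 20.0,
    seed: int = 0,
) -> list[tuple[ROIImage, MassMask, dict]]:
    """A balanced phantom cohort cycling through the four categories."""
    if n_cases % len(LABELS) != 0:
        raise ValueError("cohort size must be divisible by 4")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_cases):
        category = LABELS[i % len(LABELS)]
        jitter = float(rng.uniform(-2.0, 2.0))
        spec = PhantomSpec(
            category=category,
            radius_px=radius_px + jitter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(make_phantom(spec))
    return cohort
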