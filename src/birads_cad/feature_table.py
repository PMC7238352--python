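"""Assembly, normalization and I/O of the 130-feature vector.

Feature ids follow a fixed registry: 1-9 shape, 10 mass size (mm^2),
11 patient age (years), 12-32 margin, 33-130 density (texture).  Feature
tables are CSV files with one row per case and columns
``case_id, label, f001..f130`` (labels B2..B5).  Min-max scaling maps each
feature through (d - d_min) / (d_max - d_min) with the extrema learned
from a training table; unseen values are clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import STAT_NAMES
from .imaging import MassMask
from .texture_features import HARALICK_NAMES

LABELS = ("B2", "B3", "B4", "B5")

SHAPE_NAMES = (
    "continuity",
    "curvature",
    "irregularity",
    "difference_area",
    "mean_variation",
    "variance_variation",
    "skewness_variation",
    "kurtosis_variation",
    "entropy_variation",
)

MARGIN_DESCRIPTORS = ("margin_kurtosis", "margin_entropy", "margin_index_of_max")


def _build_registry() -> dict[int, tuple[str, str]]:
    registry: dict[int, tuple[str, str]] = {}
    fid = 1
    for name in SHAPE_NAMES:
        registry[fid] = ("shape", name)
        fid += 1
    registry[10] = ("additional", "mass_size")
    registry[11] = ("additional", "patient_age")
    fid = 12
    for desc in MARGIN_DESCRIPTORS:
        for stat in STAT_NAMES:
            registry[fid] = ("margin", f"{desc}_{stat}")
            fid += 1
    fid = 33
    for desc in HARALICK_NAMES:
        for stat in STAT_NAMES:
            registry[fid] = ("density", f"{desc}_{stat}")
            fid += 1
    assert fid == 131
    return registry


#: id -> (category, name); a bijection over ids 1..130
FEATURE_REGISTRY: dict[int, tuple[str, str]] = _build_registry()
N_FEATURES = len(FEATURE_REGISTRY)
NAME_TO_ID: dict[str, int] = {name: fid for fid, (_, name) in FEATURE_REGISTRY.items()}

CATEGORY_IDS: dict[str, tuple[int, ...]] = {
    cat: tuple(fid for fid, (c, _) in FEATURE_REGISTRY.items() if c == cat)
    for cat in ("shape", "additional", "margin", "density")
}


def feature_column(fid: int) -> str:
    return f"f{fid:03d}"


FEATURE_COLUMNS = [feature_column(fid) for fid in range(1, N_FEATURES + 1)]


@dataclass
class FeatureVector:
    """The 130 named features of one mass, indexed by id 1..130."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} entries")

    def __getitem__(self, fid: int) -> float:
        return float(self.values[fid - 1])

    def by_name(self, name: str) -> float:
        return self[NAME_TO_ID[name]]


def mass_size_mm2(mask: MassMask, spacing_mm: float = 0.05) -> float:
    """Mass area in mm^2: pixel count times the squared pixel spacing."""
    return mask.area_px * spacing_mm**2


def assemble(
    shape: np.ndarray,
    size_mm2: float,
    age_years: float,
    margin: np.ndarray,
    texture: np.ndarray,
) -> FeatureVector:
    """Concatenate the feature families in registry id order."""
    shape = np.asarray(shape, dtype=float).ravel()
    margin = np.asarray(margin, dtype=float).ravel()
    texture = np.asarray(texture, dtype=float).ravel()
    if shape.shape != (9,):
        raise ValueError(f"shape family must have 9 values, got {shape.shape}")
    if margin.shape != (21,):
        raise ValueError(f"margin family must have 21 values, got {margin.shape}")
    if texture.shape != (98,):
        raise ValueError(f"density family must have 98 values, got {texture.shape}")
    return FeatureVector(
        np.concatenate([shape, [float(size_mm2), float(age_years)], margin, texture])
    )


@dataclass
class FeatureScaler:
    """Per-feature min-max normalizer learned from a training table."""

    d_min: np.ndarray
    d_max: np.ndarray

    def __post_init__(self) -> None:
        self.d_min = np.asarray(self.d_min, dtype=float)
        self.d_max = np.asarray(self.d_max, dtype=float)
        if (self.d_min > self.d_max).any():
            raise ValueError("scaler minima exceed maxima")


def fit_scaler(table: pd.DataFrame | np.ndarray) -> FeatureScaler:
    """Learn per-feature minima and maxima from a training feature matrix."""
    X = _feature_matrix(table)
    if X.shape[0] == 0:
        raise ValueError("training table is empty")
    return FeatureScaler(X.min(axis=0), X.max(axis=0))


def apply_scaler(scaler: FeatureScaler, vector: pd.DataFrame | np.ndarray):
    """Map features through (d - d_min)/(d_max - d_min), clamped to [0, 1].

    Constant training features (d_min == d_max) map to 0 by convention.
    Accepts a single vector, a matrix, or a feature table (whose feature
    columns are replaced in a copy).
    """
    if isinstance(vector, pd.DataFrame):
        out = vector.copy()
        out[_feature_cols(vector)] = apply_scaler(scaler, _feature_matrix(vector))
        return out
    X = np.asarray(vector, dtype=float)
    span = scaler.d_max - scaler.d_min
    safe = np.where(span == 0, 1.0, span)
    scaled = (X - scaler.d_min) / safe
    scaled = np.where(span == 0, 0.0, scaled)
    return np.clip(scaled, 0.0, 1.0)


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]


def _feature_matrix(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table[_feature_cols(table)].to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def make_table(rows: list[tuple[str, str, FeatureVector]]) -> pd.DataFrame:
    """Build a feature table from (case_id, label, features) triples."""
    records = []
    for case_id, label, fv in rows:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        rec = {"case_id": case_id, "label": label}
        rec.update({feature_column(i + 1): fv.values[i] for i in range(N_FEATURES)})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def read_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column")
    return table
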