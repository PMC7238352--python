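"""Shared statistical summaries used by the feature families.

All moments use the population convention (divide by n); skewness is
``m3 / m2^1.5`` and kurtosis is the non-excess ``m4 / m2^2``.  Degenerate
zero-variance sequences report skewness and kurtosis of 0.
"""

from __future__ import annotations

import numpy as np

STAT_NAMES = ("mean", "max", "min", "std", "var", "skew", "kurt")


def population_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, kurtosis) with population conventions."""
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return mean, 0.0, 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def seven_statistics(x: np.ndarray) -> np.ndarray:
    """mean, max, min, std, variance, skewness, kurtosis of a sequence."""
    x = np.asarray(x, dtype=float)
    mean, var, skew, kurt = population_moments(x)
    return np.array(
        [mean, float(x.max()), float(x.min()), float(np.sqrt(var)), var, skew, kurt]
    )


def shannon_entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector (0·log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    if nz.size == 0:
        return 0.0
    return float(-np.sum(nz * np.log2(nz)))
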