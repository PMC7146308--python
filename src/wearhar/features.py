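"""Time-domain feature extraction over sample windows.

Per axis and per sensor the features are maximum, median, minimum, mean and
population variance, plus the Integral of the Modulus of Acceleration (IMA,
accelerometer only): 16 accelerometer features and 15 gyroscope features.

Feature names follow ``{acc|gyr}_{max|median|min|mean|var}_{x|y|z}`` plus
``ima``.  Subsetting is first-class: only requested features are computed and
the resulting mask drives per-feature energy accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .windowing import SampleWindow

STATS = ("max", "median", "min", "mean", "var")
AXES = ("x", "y", "z")

ACC_FEATURES = tuple(f"acc_{s}_{a}" for s in STATS for a in AXES) + ("ima",)
GYR_FEATURES = tuple(f"gyr_{s}_{a}" for s in STATS for a in AXES)
ALL_FEATURES = ACC_FEATURES + GYR_FEATURES


class AxisStats(NamedTuple):
    max: float
    median: float
    min: float
    mean: float
    var: float


def axis_stats(values) -> AxisStats:
    """Max, median, min, mean and population variance of one axis sequence."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sequence")
    return AxisStats(
        float(np.max(v)), float(np.median(v)), float(np.min(v)),
        float(np.mean(v)), float(np.var(v)),
    )


def ima(accel_window, sample_period: float) -> float:
    """Integral of the Modulus of Acceleration over a window.

    Rectangular integration of the summed absolute triaxial components:
    ``dt * sum_t (|ax_t| + |ay_t| + |az_t|)``, in g*s.
    """
    w = np.asarray(accel_window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(sample_period * np.abs(w).sum())


@dataclass
class FeatureVector:
    """Named feature values plus the mask of which ones were computed."""

    values: dict[str, float]

    @property
    def mask(self) -> frozenset[str]:
        return frozenset(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)


def extract(window: SampleWindow, subset: Iterable[str],
            sample_period: float = 1.0 / 14.0) -> FeatureVector:
    """Compute the requested features on one window.

    Requesting a gyro feature on a window without gyro data is a contract
    breach (it indicates a gating bug upstream) and raises ``ValueError``.
    """
    subset = list(subset)
    unknown = set(subset) - set(ALL_FEATURES)
    if unknown:
        raise KeyError(f"unknown feature names: {sorted(unknown)}")
    needs_gyro = any(name.startswith("gyr_") for name in subset)
    if needs_gyro and window.gyro is None:
        raise ValueError("gyro features requested on a window without gyro data")

    values: dict[str, float] = {}
    stats_cache: dict[tuple[str, str], AxisStats] = {}
    for name in subset:
        if name == "ima":
            values[name] = ima(window.accel, sample_period)
            continue
        sensor, stat, axis = name.split("_")
        key = (sensor, axis)
        if key not in stats_cache:
            data = window.accel if sensor == "acc" else window.gyro
            stats_cache[key] = axis_stats(data[:, AXES.index(axis)])
        values[name] = getattr(stats_cache[key], stat)
    return FeatureVector(values)


def feature_matrix(windows, subset: Iterable[str],
                   sample_period: float = 1.0 / 14.0) -> pd.DataFrame:
    """Vectorized feature extraction over many windows.

    Returns a DataFrame with one row per window and one column per feature,
    numerically identical to per-window :func:`extract`.
    """
    subset = list(subset)
    acc = np.stack([w.accel for w in windows])  # (n, 32, 3)
    gyr = None
    if any(name.startswith("gyr_") for name in subset):
        if any(w.gyro is None for w in windows):
            raise ValueError("gyro features requested but some windows lack gyro data")
        gyr = np.stack([w.gyro for w in windows])

    cols = {}
    for name in subset:
        if name == "ima":
            cols[name] = sample_period * np.abs(acc).sum(axis=(1, 2))
            continue
        sensor, stat, axis = name.split("_")
        data = (acc if sensor == "acc" else gyr)[:, :, AXES.index(axis)]
        fn = {"max": np.max, "median": np.median, "min": np.min,
              "mean": np.mean, "var": np.var}[stat]
        cols[name] = fn(data, axis=1)
    return pd.DataFrame(cols, columns=subset)


__all__ = [
    "STATS",
    "AXES",
    "ACC_FEATURES",
    "GYR_FEATURES",
    "ALL_FEATURES",
    "AxisStats",
    "axis_stats",
    "ima",
    "FeatureVector",
    "extract",
    "feature_matrix",
]
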