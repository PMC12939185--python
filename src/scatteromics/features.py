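"""First-order feature extraction over ROI-masked parametric maps.

Each subject contributes four parametric maps (m, alpha, k, H); an ROI mask
drawn on the envelope/B-mode grid is resampled onto each map grid (a map
cell is in-ROI iff its window center falls inside the mask) and 13
first-order statistics are computed per map, giving the 52-feature
"simplified feature set" per subject:

mean, median, mode, variance, standard deviation, kurtosis (excess),
skewness, minimum, maximum, 75th percentile (Q3), 25th percentile (Q1),
IQR and range.

Conventions: variance and standard deviation use the 1/n (population)
normalization; skewness and kurtosis are the standardized third and fourth
moments (kurtosis minus 3, so the normal baseline is 0); quantiles use
linear interpolation between order statistics; the mode of continuous data
is the center of the fullest bin of a 50-bin equal-width histogram (ties ->
lowest bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import ParametricMap

__all__ = [
    "ROIMask",
    "STAT_NAMES",
    "PARAM_NAMES",
    "FEATURE_COLUMNS",
    "roi_values",
    "first_order_features",
    "build_feature_table",
]

STAT_NAMES = (
    "mean",
    "median",
    "mode",
    "variance",
    "std",
    "kurtosis",
    "skewness",
    "min",
    "max",
    "q3",
    "q1",
    "iqr",
    "range",
)
PARAM_NAMES = ("m", "alpha", "k", "H")
#: the 52 feature column names, parameter-major
FEATURE_COLUMNS = tuple(f"{p}_{s}" for p in PARAM_NAMES for s in STAT_NAMES)

MODE_BINS = 50
MIN_ROI_CELLS = 5


@dataclass
class ROIMask:
    """Binary region-of-interest mask on the envelope image grid."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("mask must be 2-D with at least one true cell")


def roi_values(pmap: ParametricMap, mask: ROIMask | np.ndarray) -> np.ndarray:
    """Finite in-ROI map values; invalid (NaN) cells are dropped.

    A map cell is inside the ROI iff its window center (rounded to the
    nearest image pixel) lies in the mask.
    """
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    ax, lat = pmap.center_coords()
    ai = np.clip(np.round(ax).astype(int), 0, m.shape[0] - 1)
    li = np.clip(np.round(lat).astype(int), 0, m.shape[1] - 1)
    in_roi = m[np.ix_(ai, li)]
    vals = pmap.values[in_roi]
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_ROI_CELLS:
        raise ValueError(
            f"ROI covers {vals.size} valid map cells; >= {MIN_ROI_CELLS} required"
        )
    return vals


def _mode_histogram(values: np.ndarray) -> float:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(values, bins=MODE_BINS, range=(lo, hi))
    b = int(np.argmax(counts))  # argmax takes the first (lowest) maximal bin
    return float(0.5 * (edges[b] + edges[b + 1]))


def first_order_features(values) -> dict[str, float]:
    """The 13 first-order statistics of a value vector.

    Zero-variance input yields NaN skewness and kurtosis (flagged-invalid,
    not an error).
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < MIN_ROI_CELLS:
        raise ValueError(f"need >= {MIN_ROI_CELLS} finite values, got {v.size}")
    mu = float(np.mean(v))
    var = float(np.var(v))  # 1/n
    sd = float(np.sqrt(var))
    if sd > 0:
        z = (v - mu) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)  # excess kurtosis
    else:
        skew = float("nan")
        kurt = float("nan")
    q1, med, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75]))
    vmin, vmax = float(v.min()), float(v.max())
    return {
        "mean": mu,
        "median": med,
        "mode": _mode_histogram(v),
        "variance": var,
        "std": sd,
        "kurtosis": kurt,
        "skewness": skew,
        "min": vmin,
        "max": vmax,
        "q3": q3,
        "q1": q1,
        "iqr": q3 - q1,
        "range": vmax - vmin,
    }


def build_feature_table(
    maps: Sequence[Mapping[str, ParametricMap]],
    masks: Sequence[ROIMask | np.ndarray],
    labels: Sequence[int],
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the subjects x 52 feature table.

    Parameters
    ----------
    maps:
        One mapping per subject with keys "m", "alpha", "k", "H".
    masks, labels:
        Aligned per-subject ROI masks and binary outcomes.

    Returns a DataFrame with columns ``subject_id``, ``label`` and the 52
    features in parameter-major order.
    """
    if not (len(maps) == len(masks) == len(labels)):
        raise ValueError("maps, masks and labels must be aligned")
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(len(maps))]
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicated subject_id")
    rows = []
    for sid, subject_maps, mask, label in zip(subject_ids, maps, masks, labels):
        if int(label) not in (0, 1):
            raise ValueError(f"label for {sid} must be 0 or 1")
        row: dict[str, object] = {"subject_id": sid, "label": int(label)}
        for p in PARAM_NAMES:
            if p not in subject_maps:
                raise ValueError(f"subject {sid} is missing the {p!r} map")
            try:
                vals = roi_values(subject_maps[p], mask)
            except ValueError as exc:
                raise ValueError(f"subject {sid}: {exc}") from exc
            stats = first_order_features(vals)
            for s in STAT_NAMES:
                row[f"{p}_{s}"] = stats[s]
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_COLUMNS])
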