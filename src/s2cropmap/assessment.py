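"""Thematic-map accuracy assessment and map-vs-statistics area comparison.

Confusion matrices follow the map-as-rows convention: cell (i, j) counts
samples mapped to class i whose reference class is j.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import linregress

CLASS_ORDER = ("rice", "maize", "soybean", "other")


def round2(x: float) -> float:
    """2-decimal half-up rounding used for report output."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion(pred, ref, n_classes: int = 4) -> np.ndarray:
    """Count matrix with predicted (map) classes as rows, reference as columns."""
    pred = np.asarray(pred, dtype=int)
    ref = np.asarray(ref, dtype=int)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference label vectors differ in length")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    if ((pred < 0) | (pred >= n_classes) | (ref < 0) | (ref >= n_classes)).any():
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (pred, ref), 1)
    return cm


def metrics(cm: np.ndarray) -> dict:
    """OA, per-class UA/PA/F1 of a confusion matrix (NaN where undefined)."""
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    diag = np.diag(cm)
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ua = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), np.nan)
        pa = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), np.nan)
        den = ua + pa
        f1 = np.where(den > 0, 2 * ua * pa / np.where(den > 0, den, 1), np.nan)
    if np.isnan(ua).any() or np.isnan(pa).any():
        warnings.warn("empty row/column in confusion matrix: some UA/PA undefined",
                      stacklevel=2)
    return {"oa": float(diag.sum() / total), "ua": ua, "pa": pa, "f1": f1}


def metrics_table(cm: np.ndarray, class_names=CLASS_ORDER) -> pd.DataFrame:
    """Per-class UA/PA/F1 plus OA, rounded for reporting (2 dp, half-up)."""
    m = metrics(cm)
    df = pd.DataFrame({
        "class": list(class_names),
        "ua": [round2(v) for v in m["ua"]],
        "pa": [round2(v) for v in m["pa"]],
        "f1": [round2(v) for v in m["f1"]],
    })
    df.attrs["oa"] = round2(m["oa"])
    return df


def mean_f1(cms: list[np.ndarray], class_idx: int) -> float:
    """Unweighted mean of one class's F1 across several confusion matrices."""
    return float(np.mean([metrics(cm)["f1"][class_idx] for cm in cms]))


def area_table(map_raster: np.ndarray, region_raster: np.ndarray,
               reference: pd.DataFrame, *, pixel_area_ha: float = 0.01,
               n_classes: int = 4, class_names=CLASS_ORDER) -> pd.DataFrame:
    """Mapped vs reference area (ha) per region and crop.

    ``reference`` needs columns region, crop, reference_ha.
    """
    rows = []
    for region in np.unique(region_raster):
        in_region = region_raster == region
        for code in range(n_classes):
            mapped = float(np.count_nonzero(in_region & (map_raster == code))) * pixel_area_ha
            rows.append({"region": int(region), "crop": class_names[code],
                         "mapped_ha": mapped})
    at = pd.DataFrame(rows)
    return at.merge(reference, on=["region", "crop"], how="left")


def area_compare(at: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-crop OLS of mapped on reference area; reports R2, slope, intercept."""
    out = {}
    for crop, sub in at.groupby("crop"):
        sub = sub.dropna(subset=["mapped_ha", "reference_ha"])
        if len(sub) < 3:
            raise ValueError(f"need >= 3 regions for crop {crop!r}, got {len(sub)}")
        if np.ptp(sub["reference_ha"].to_numpy()) == 0:
            raise ValueError(f"zero variance in reference areas for crop {crop!r}")
        fit = linregress(sub["reference_ha"], sub["mapped_ha"])
        out[crop] = {"r2": float(fit.rvalue ** 2), "slope": float(fit.slope),
                     "intercept": float(fit.intercept), "n": int(len(sub))}
    return out
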