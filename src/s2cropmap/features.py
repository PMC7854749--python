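"""Feature banks for cropland masking (184 candidates) and crop typing (255).

Cropland bank: 30 stage medians + 100 annual statistics + 54 GLCM texture
metrics, computed on three-year-merged observations in the real workflow
(here: on whatever observations a pixel carries).

Crop bank: 220 ten-day time-series values + 20 greenest/wettest-composite
proxies + 15 harmonic coefficients. Time-series features come from the
smoothed regular series; composites and harmonics from the original valid
observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import PROXIES, compute_index, compute_proxies
from .synthetic import SceneRaster
from .temporal import GRID_STARTS, SmoothingConfig, regularize_stack
from .texture import GLCM_STATS, glcm_textures

log = logging.getLogger(__name__)

ANNUAL_STATS = ("min", "max", "mean", "std", "amplitude", "p5", "p25", "p50", "p75", "p95")
HARMONIC_PROXIES = ("ndvi", "evi", "lswi")
HARMONIC_COEFS = ("c", "a1", "b1", "a2", "b2")
STAGES = ("seeding", "growth", "harvest")


@dataclass(frozen=True)
class StageWindows:
    """Crop-calendar stages (DOY windows) used for seasonal metrics and textures."""

    seeding: tuple[int, int] = (109, 169)
    growth: tuple[int, int] = (170, 230)
    harvest: tuple[int, int] = (231, 291)
    season: tuple[int, int] = (90, 300)

    def window(self, stage: str) -> tuple[int, int]:
        return getattr(self, stage)

    def interval_mask(self, stage: str) -> np.ndarray:
        lo, hi = self.window(stage)
        return (GRID_STARTS >= lo) & (GRID_STARTS <= hi)

    def doy_mask(self, doys: np.ndarray, stage: str) -> np.ndarray:
        lo, hi = self.window(stage)
        return (np.asarray(doys) >= lo) & (np.asarray(doys) <= hi)


DEFAULT_WINDOWS = StageWindows()


# ---------------------------------------------------------------------------
# feature name enumeration

def cropland_feature_names() -> list[str]:
    names = [f"{stage}_{p}_median" for stage in STAGES for p in PROXIES]
    names += [f"annual_{p}_{s}" for p in PROXIES for s in ANNUAL_STATS]
    names += [f"texture_{stage}_{s}" for stage in STAGES for s in GLCM_STATS]
    return names


def crop_feature_names() -> list[str]:
    names = [f"ts_{p}_d{d:03d}" for p in PROXIES for d in GRID_STARTS]
    names += [f"greenest_{p}" for p in PROXIES] + [f"wettest_{p}" for p in PROXIES]
    names += [f"harm_{p}_{c}" for p in HARMONIC_PROXIES for c in HARMONIC_COEFS]
    return names


def bank_manifest(mode: str) -> pd.DataFrame:
    """Name/group/proxy/period/metric table describing one feature bank."""
    rows = []
    if mode == "cropland":
        for stage in STAGES:
            for p in PROXIES:
                rows.append((f"{stage}_{p}_median", "seasonal", p, stage, "median"))
        for p in PROXIES:
            for s in ANNUAL_STATS:
                rows.append((f"annual_{p}_{s}", "annual", p, "season", s))
        for stage in STAGES:
            for s in GLCM_STATS:
                rows.append((f"texture_{stage}_{s}", "texture", "ndvi", stage, s))
    elif mode == "crop":
        for p in PROXIES:
            for d in GRID_STARTS:
                rows.append((f"ts_{p}_d{d:03d}", "timeseries", p, f"d{d:03d}", "value"))
        for kind in ("greenest", "wettest"):
            for p in PROXIES:
                rows.append((f"{kind}_{p}", "composite", p, "season", kind))
        for p in HARMONIC_PROXIES:
            for c in HARMONIC_COEFS:
                rows.append((f"harm_{p}_{c}", "harmonic", p, "season", c))
    else:
        raise ValueError(f"unknown bank mode {mode!r}")
    return pd.DataFrame(rows, columns=["name", "group", "proxy", "period", "metric"])


# ---------------------------------------------------------------------------
# metric operations

def seasonal_metrics(regular: np.ndarray, windows: StageWindows = DEFAULT_WINDOWS) -> dict[str, float]:
    """Stage medians of the 10 regular proxy series (30 features).

    ``regular`` is a (10, 22) array, proxy rows in :data:`PROXIES` order.
    """
    regular = np.asarray(regular, dtype=float)
    out = {}
    for stage in STAGES:
        mask = windows.interval_mask(stage)
        if not mask.any():
            raise ValueError(f"stage {stage!r} covers no 10-day interval")
        for k, p in enumerate(PROXIES):
            out[f"{stage}_{p}_median"] = float(np.median(regular[k, mask]))
    return out


def annual_metrics(regular: np.ndarray) -> dict[str, float]:
    """10 growing-season statistics per proxy series (100 features)."""
    regular = np.asarray(regular, dtype=float)
    out = {}
    for k, p in enumerate(PROXIES):
        v = regular[k]
        q = np.percentile(v, [5, 25, 50, 75, 95])
        out[f"annual_{p}_min"] = float(v.min())
        out[f"annual_{p}_max"] = float(v.max())
        out[f"annual_{p}_mean"] = float(v.mean())
        out[f"annual_{p}_std"] = float(v.std())
        out[f"annual_{p}_amplitude"] = float(v.max() - v.min())
        for name, val in zip(("p5", "p25", "p50", "p75", "p95"), q):
            out[f"annual_{p}_{name}"] = float(val)
    return out


def temporal_composites(doys, reflectance, valid) -> dict[str, float]:
    """Greenest (max NDVI) and wettest (max LSWI) composite proxies (20 features).

    Ties are broken by the earliest DOY. Raises on a series without valid
    observations.
    """
    refl = np.asarray(reflectance, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    proxies = compute_proxies(refl)                     # (t, 10)
    ok = valid & np.isfinite(proxies).all(axis=1)
    if not ok.any():
        raise ValueError("no valid observations for temporal compositing")
    idx = np.flatnonzero(ok)
    ndvi = compute_index(refl, "ndvi")[idx]
    lswi = compute_index(refl, "lswi")[idx]
    greenest = idx[np.argmax(ndvi)]
    wettest = idx[np.argmax(lswi)]
    out = {f"greenest_{p}": float(proxies[greenest, k]) for k, p in enumerate(PROXIES)}
    out.update({f"wettest_{p}": float(proxies[wettest, k]) for k, p in enumerate(PROXIES)})
    return out


def harmonic_design(doys) -> np.ndarray:
    """Design matrix [1, cos(3πt), sin(3πt), cos(6πt), sin(6πt)], t=(DOY-1)/365."""
    t = (np.asarray(doys, dtype=float) - 1.0) / 365.0
    return np.column_stack([np.ones_like(t),
                            np.cos(3 * np.pi * t), np.sin(3 * np.pi * t),
                            np.cos(6 * np.pi * t), np.sin(6 * np.pi * t)])


def fit_harmonics(doys, values, valid=None) -> np.ndarray:
    """OLS harmonic coefficients (c, a1, b1, a2, b2) of one index series.

    Requires >= 5 valid finite observations and a full-rank design.
    """
    values = np.asarray(values, dtype=float)
    doys = np.asarray(doys)
    ok = np.isfinite(values)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    if ok.sum() < 5:
        raise ValueError("harmonic fit needs at least 5 valid observations")
    x = harmonic_design(doys[ok])
    if np.linalg.matrix_rank(x) < 5:
        raise ValueError("singular harmonic design (degenerate observation dates)")
    coef, *_ = np.linalg.lstsq(x, values[ok], rcond=None)
    return coef


def harmonic_features(doys, reflectance, valid) -> dict[str, float]:
    """15 harmonic-coefficient features (NDVI, EVI, LSWI x 5 coefficients)."""
    out = {}
    for p in HARMONIC_PROXIES:
        v = compute_index(reflectance, p)
        coef = fit_harmonics(doys, v, valid)
        for name, val in zip(HARMONIC_COEFS, coef):
            out[f"harm_{p}_{name}"] = float(val)
    return out


# ---------------------------------------------------------------------------
# bank assembly

def _regular_proxy_stack(doys, reflectance, valid,
                         cfg: SmoothingConfig | None = None) -> np.ndarray:
    """(n, 10, 22) smoothed regular series for every sample and proxy."""
    refl = np.asarray(reflectance, dtype=float)
    proxies = compute_proxies(refl)                          # (n, t, 10)
    n = proxies.shape[0]
    out = np.empty((n, len(PROXIES), len(GRID_STARTS)))
    for k in range(len(PROXIES)):
        out[:, k, :] = regularize_stack(doys, proxies[:, :, k], valid, cfg)
    return out


def build_crop_bank(doys, reflectance, valid, *, windows: StageWindows = DEFAULT_WINDOWS,
                    cfg: SmoothingConfig | None = None) -> pd.DataFrame:
    """255-column crop feature matrix for a batch of series.

    ``reflectance``: (n, t, 8); ``valid``: (n, t); ``doys``: shared (t,).
    Samples whose series cannot be processed (no valid observations, or
    fewer than 5 for the harmonic fit) are dropped; the returned frame's
    index holds the surviving sample positions.
    """
    refl = np.asarray(reflectance, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n = refl.shape[0]
    regular = _regular_proxy_stack(doys, refl, valid, cfg)   # (n, 10, 22)

    names = crop_feature_names()
    rows, kept = [], []
    for s in range(n):
        if np.isnan(regular[s]).any():
            continue
        feats = {f"ts_{p}_d{d:03d}": regular[s, k, j]
                 for k, p in enumerate(PROXIES)
                 for j, d in enumerate(GRID_STARTS)}
        try:
            feats.update(temporal_composites(doys, refl[s], valid[s]))
            feats.update(harmonic_features(doys, refl[s], valid[s]))
        except ValueError:
            continue
        rows.append([feats[nm] for nm in names])
        kept.append(s)
    dropped = n - len(kept)
    if dropped:
        log.warning("crop bank: dropped %d of %d samples with unusable series", dropped, n)
    return pd.DataFrame(rows, columns=names, index=kept)


def _stage_ndvi_images(scene: SceneRaster, windows: StageWindows) -> dict[str, np.ndarray]:
    """Per-stage median-NDVI images over the whole scene."""
    ndvi = compute_index(scene.reflectance, "ndvi")          # (npix, t)
    ok = scene.valid & np.isfinite(ndvi)
    images = {}
    for stage in STAGES:
        m = windows.doy_mask(scene.doys, stage)
        sub = np.where(ok[:, m], ndvi[:, m], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # fully clouded pixels
            img = np.nanmedian(sub, axis=1)
        img = np.where(np.isfinite(img), img, np.nanmean(img[np.isfinite(img)]) if np.isfinite(img).any() else 0.0)
        images[stage] = img.reshape(scene.shape)
    return images


def build_cropland_bank(scene: SceneRaster, sample_idx, *,
                        windows: StageWindows = DEFAULT_WINDOWS,
                        cfg: SmoothingConfig | None = None,
                        texture_window: int = 9,
                        glcm_levels: int = 32) -> pd.DataFrame:
    """184-column cropland feature matrix for sample pixels of a scene.

    Textures are computed on a ``texture_window``-sized square of the
    stage-median NDVI images centered on each sample (clipped at edges).
    """
    sample_idx = np.asarray(sample_idx, dtype=int)
    refl = scene.reflectance[sample_idx]
    valid = scene.valid[sample_idx]
    regular = _regular_proxy_stack(scene.doys, refl, valid, cfg)

    images = _stage_ndvi_images(scene, windows)
    rows_, cols_ = scene.shape
    half = texture_window // 2
    names = cropland_feature_names()
    rows, kept = [], []
    for s, pix in enumerate(sample_idx):
        if np.isnan(regular[s]).any():
            continue
        feats = seasonal_metrics(regular[s], windows)
        feats.update(annual_metrics(regular[s]))
        r, c = divmod(int(pix), cols_)
        r0, r1 = max(0, r - half), min(rows_, r + half + 1)
        c0, c1 = max(0, c - half), min(cols_, c + half + 1)
        for stage in STAGES:
            tex = glcm_textures(images[stage][r0:r1, c0:c1], glcm_levels)
            feats.update({f"texture_{stage}_{k}": v for k, v in tex.items()})
        rows.append([feats[nm] for nm in names])
        kept.append(int(pix))
    dropped = len(sample_idx) - len(kept)
    if dropped:
        log.warning("cropland bank: dropped %d of %d samples", dropped, len(sample_idx))
    return pd.DataFrame(rows, columns=names, index=kept)


def build_bank(mode: str, scene: SceneRaster, sample_idx, **kwargs) -> pd.DataFrame:
    """Dispatch to the cropland (184) or crop (255) bank for scene samples."""
    if mode == "cropland":
        return build_cropland_bank(scene, sample_idx, **kwargs)
    if mode == "crop":
        sample_idx = np.asarray(sample_idx, dtype=int)
        fm = build_crop_bank(scene.doys, scene.reflectance[sample_idx],
                             scene.valid[sample_idx], **kwargs)
        fm.index = sample_idx[np.asarray(fm.index, dtype=int)]
        return fm
    raise ValueError(f"unknown bank mode {mode!r}")
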