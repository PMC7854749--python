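"""Spectral indices and cloud screening for 8-band reflectance observations.

Band layout used throughout the package (axis order of every reflectance
array): blue, red, RE1, RE2, RE3, NIR, SWIR1, SWIR2 — i.e. Sentinel-2 MSI
bands 2, 4, 5, 6, 7, 8A, 11, 12 as top-of-atmosphere reflectance in [0, 1].
"""

from __future__ import annotations

import numpy as np

#: Index positions of the 8 core bands in every reflectance vector.
BANDS = ("blue", "red", "re1", "re2", "re3", "nir", "swir1", "swir2")
BAND_INDEX = {name: i for i, name in enumerate(BANDS)}

#: The 10 per-observation proxies all features derive from:
#: 3 reflectance bands + 7 spectral indices.
PROXIES = (
    "re2", "swir1", "swir2",
    "ndvi", "evi", "lswi", "ndsvi", "ndti", "rendvi", "rep",
)

#: Names accepted by :func:`compute_index` (proxies; bands pass through).
INDEX_NAMES = ("ndvi", "evi", "lswi", "ndsvi", "ndti", "rendvi", "rep")


def _nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Normalized difference (a-b)/(a+b); NaN where the denominator is 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    den = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, np.nan, (a - b) / np.where(den == 0, 1.0, den))
    return out


def compute_index(
    reflectance: np.ndarray,
    name: str,
    *,
    rep_form: str = "standard",
) -> np.ndarray:
    """Evaluate one spectral index (or band passthrough) on reflectance data.

    Parameters
    ----------
    reflectance
        Array whose last axis holds the 8 bands in :data:`BANDS` order.
    name
        Case-insensitive proxy name: one of ``ndvi, evi, lswi, ndsvi, ndti,
        rendvi, rep`` or a band name (e.g. ``re2``, ``swir1``) which is
        returned unchanged.
    rep_form
        ``"standard"`` (default) evaluates the conventional red-edge
        position ``705 + 35 * ((0.5*(RE3+red) - RE1) / (RE2 - RE1))``;
        ``"literal"`` places the whole ``705 + 35*(...)`` numerator over
        ``RE2 - RE1``.

    Returns
    -------
    numpy.ndarray
        Index values with the band axis removed. Zero denominators yield
        NaN (callers treat those observations as invalid).
    """
    r = np.asarray(reflectance, dtype=float)
    if r.shape[-1] != len(BANDS):
        raise ValueError(f"expected {len(BANDS)} bands on the last axis, got {r.shape[-1]}")
    name = name.lower()
    if name in BAND_INDEX:
        return r[..., BAND_INDEX[name]]

    blue, red, re1, re2, re3, nir, swir1, swir2 = (r[..., i] for i in range(8))
    if name == "ndvi":
        return _nd(nir, red)
    if name == "lswi":
        return _nd(nir, swir1)
    if name == "ndsvi":
        return _nd(swir1, red)
    if name == "ndti":
        return _nd(swir1, swir2)
    if name == "rendvi":
        return _nd(nir, re2)
    if name == "evi":
        den = nir + 6.0 * red - 7.5 * blue + 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den == 0, np.nan,
                            2.5 * (nir - red) / np.where(den == 0, 1.0, den))
    if name == "rep":
        den = re2 - re1
        num = 0.5 * (re3 + red) - re1
        with np.errstate(divide="ignore", invalid="ignore"):
            safe = np.where(den == 0, 1.0, den)
            if rep_form == "standard":
                out = 705.0 + 35.0 * num / safe
            elif rep_form == "literal":
                out = (705.0 + 35.0 * num) / safe
            else:
                raise ValueError(f"unknown rep_form {rep_form!r}")
        return np.where(den == 0, np.nan, out)
    raise ValueError(f"unknown index {name!r}")


def compute_proxies(reflectance: np.ndarray, *, rep_form: str = "standard") -> np.ndarray:
    """Stack the 10 proxies (:data:`PROXIES`) along a new last axis."""
    vals = [compute_index(reflectance, p, rep_form=rep_form) for p in PROXIES]
    return np.stack(vals, axis=-1)


def _rescale(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((np.asarray(v, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def cloud_score(
    aerosols: np.ndarray,
    blue: np.ndarray,
    green: np.ndarray,
    red: np.ndarray,
    nir: np.ndarray,
    swir1: np.ndarray,
) -> np.ndarray:
    """Surrogate cloud score in [0, 1].

    Combines brightness in the aerosol/blue band, brightness across all
    visible bands, moisture (NDMI = (NIR-SWIR1)/(NIR+SWIR1)) and a
    not-snow criterion (NDSI = (green-SWIR1)/(green+SWIR1), high NDSI
    down-weighted), each linearly rescaled to [0, 1]; the final score is
    the minimum of the criteria, so a cloud must look bright, moist and
    not snow-like. The score is non-decreasing in visible-band brightness.
    """
    for name, v in (("aerosols", aerosols), ("blue", blue), ("green", green),
                    ("red", red), ("nir", nir), ("swir1", swir1)):
        if v is None:
            raise ValueError(f"missing band {name!r} for cloud score")
    score = _rescale(np.asarray(blue, dtype=float) + np.asarray(aerosols, dtype=float),
                     0.2, 0.6)
    visible = np.asarray(blue, dtype=float) + np.asarray(green, dtype=float) \
        + np.asarray(red, dtype=float)
    score = np.minimum(score, _rescale(visible, 0.3, 0.9))
    ndmi = _nd(nir, swir1)
    score = np.minimum(score, _rescale(np.nan_to_num(ndmi, nan=-1.0), -0.1, 0.1))
    ndsi = _nd(green, swir1)
    # high NDSI = snow, not cloud: rescale with inverted bounds
    score = np.minimum(score, 1.0 - _rescale(np.nan_to_num(ndsi, nan=1.0), 0.6, 0.8))
    return score


DEFAULT_CLOUD_THRESHOLD = 0.2


def is_cloudy(score: np.ndarray, threshold: float = DEFAULT_CLOUD_THRESHOLD) -> np.ndarray:
    """Flag observations whose cloud score is at or above ``threshold``."""
    return np.asarray(score) >= threshold
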