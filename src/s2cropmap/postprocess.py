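"""Despeckling of classified rasters.

Pixels belonging to connected patches smaller than 0.1 ha (strictly fewer
than 10 pixels at 10 m resolution) are reassigned to the majority class
inside a 100 m-radius (10 px) circular window, computed on the original
raster so the result is independent of processing order. A single pass is
applied; idempotence is not guaranteed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

NODATA = 255

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def disc_kernel(radius: int) -> np.ndarray:
    """Boolean Euclidean disc of the given pixel radius, center included."""
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius ** 2


def small_patch_mask(raster: np.ndarray, min_pixels: int = 10, *,
                     nodata: int = NODATA, connectivity: int = 8) -> np.ndarray:
    """True where a pixel's equal-code connected patch has < min_pixels pixels."""
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    mask = np.zeros(raster.shape, dtype=bool)
    for code in np.unique(raster):
        if code == nodata:
            continue
        labeled, n = ndimage.label(raster == code, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())
        small = np.flatnonzero(sizes < min_pixels)
        small = small[small > 0]  # label 0 is background
        if small.size:
            mask |= np.isin(labeled, small)
    return mask


def despeckle(raster: np.ndarray, *, min_pixels: int = 10, radius: int = 10,
              nodata: int = NODATA, connectivity: int = 8) -> np.ndarray:
    """Apply the small-patch circular majority filter once."""
    raster = np.asarray(raster)
    if raster.ndim != 2 or raster.size == 0:
        raise ValueError("raster must be a nonempty 2-D array")
    codes = sorted(int(c) for c in np.unique(raster) if c != nodata)
    if not codes:
        raise ValueError("raster contains only nodata")
    to_fix = small_patch_mask(raster, min_pixels, nodata=nodata,
                              connectivity=connectivity)
    if not to_fix.any():
        return raster.copy()
    kernel = disc_kernel(radius).astype(float)
    counts = np.stack([
        ndimage.convolve((raster == c).astype(float), kernel,
                         mode="constant", cval=0.0)
        for c in codes
    ])
    # argmax returns the first (smallest) code on ties; nodata never competes
    majority = np.asarray(codes)[np.argmax(np.round(counts), axis=0)]
    out = raster.copy()
    out[to_fix] = majority[to_fix]
    out[raster == nodata] = nodata
    return out
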