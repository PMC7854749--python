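"""Regularization of irregular observations onto a smoothed 10-day grid.

Pipeline: 10-day median composites → linear gap filling → Savitzky-Golay
smoothing (70-day window = 7 grid points, cubic polynomial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

#: Start DOYs of the 22 ten-day intervals covering the growing season.
#: The last interval covers [300, 310).
GRID_STARTS = np.arange(90, 301, 10)
N_INTERVALS = len(GRID_STARTS)  # 22
GRID_STEP = 10


@dataclass
class SmoothingConfig:
    """Savitzky-Golay settings: 70-day window = 7 grid points, cubic fit."""

    window_days: int = 70
    window_points: int = 7
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0:
            raise ValueError("window_points must be odd")
        if self.poly_order >= self.window_points:
            raise ValueError("poly_order must be < window_points")


@dataclass
class RegularSeries:
    """Values of one proxy on the 10-day grid, with a gap/fill bookkeeping mask.

    ``values[i]`` belongs to the interval starting at ``GRID_STARTS[i]``;
    NaN marks a gap. ``filled[i]`` is True where the value was interpolated
    rather than composited from observations.
    """

    values: np.ndarray
    filled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_INTERVALS,):
            raise ValueError(f"expected {N_INTERVALS} interval values, got {self.values.shape}")
        if self.filled is None:
            self.filled = np.zeros(N_INTERVALS, dtype=bool)
        else:
            self.filled = np.asarray(self.filled, dtype=bool)

    @property
    def gaps(self) -> np.ndarray:
        return np.isnan(self.values)


def composite_10day(doys, values, valid=None) -> RegularSeries:
    """Median-composite observations of one proxy into the 10-day grid.

    Each interval value is the median of the valid, finite observations
    whose DOY falls in [start, start+10); intervals without any such
    observation are gaps (NaN).
    """
    doys = np.asarray(doys)
    values = np.asarray(values, dtype=float)
    valid = np.ones(len(doys), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    ok = valid & np.isfinite(values)
    out = np.full(N_INTERVALS, np.nan)
    if ok.any():
        idx = (doys[ok] - GRID_STARTS[0]) // GRID_STEP
        vals = values[ok]
        in_grid = (idx >= 0) & (idx < N_INTERVALS)
        idx, vals = idx[in_grid].astype(int), vals[in_grid]
        for i in np.unique(idx):
            out[i] = np.median(vals[idx == i])
    return RegularSeries(out)


def fill_gaps(rs: RegularSeries) -> RegularSeries:
    """Linearly interpolate interior gaps; edge gaps take the nearest value.

    Raises ``ValueError`` on an all-gap series (unclassifiable pixel).
    """
    gaps = rs.gaps
    if gaps.all():
        raise ValueError("all intervals are gaps; series cannot be filled")
    if not gaps.any():
        return RegularSeries(rs.values.copy(), rs.filled.copy())
    x = GRID_STARTS.astype(float)
    # np.interp clamps outside the observed range -> nearest-value edges
    filled_vals = np.interp(x, x[~gaps], rs.values[~gaps])
    return RegularSeries(filled_vals, rs.filled | gaps)


def sg_smooth(rs: RegularSeries, cfg: SmoothingConfig | None = None) -> RegularSeries:
    """Apply the Savitzky-Golay filter to a gap-free series.

    Edges use polynomial extension (scipy's ``interp`` mode), so any series
    sampled from a polynomial up to ``poly_order`` passes through unchanged
    over the whole grid, endpoints included.
    """
    cfg = cfg or SmoothingConfig()
    if rs.gaps.any():
        raise ValueError("sg_smooth requires a gap-free series; call fill_gaps first")
    if cfg.window_points > N_INTERVALS:
        raise ValueError("smoothing window larger than the series")
    smoothed = savgol_filter(rs.values, cfg.window_points, cfg.poly_order, mode="interp")
    return RegularSeries(smoothed, rs.filled.copy())


def regularize(doys, values, valid=None, cfg: SmoothingConfig | None = None) -> RegularSeries:
    """composite → fill → smooth, the full regularization for one proxy."""
    return sg_smooth(fill_gaps(composite_10day(doys, values, valid)), cfg)


def regularize_stack(doys, proxy_values, valid, cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Vectorized regularization of many series sharing one acquisition calendar.

    Parameters
    ----------
    doys : (t,) observation DOYs shared by all series.
    proxy_values : (n, t) proxy values per series and observation.
    valid : (n, t) validity flags (cloud-free and finite).

    Returns
    -------
    (n, 22) array of composited, gap-filled, smoothed values. Rows whose
    observations are all invalid come back as NaN (caller drops them).
    """
    cfg = cfg or SmoothingConfig()
    doys = np.asarray(doys)
    vals = np.asarray(proxy_values, dtype=float)
    ok = np.asarray(valid, dtype=bool) & np.isfinite(vals)
    n = vals.shape[0]
    grid = np.full((n, N_INTERVALS), np.nan)
    idx = (doys - GRID_STARTS[0]) // GRID_STEP
    for i in range(N_INTERVALS):
        cols = np.flatnonzero(idx == i)
        if cols.size == 0:
            continue
        sub = np.where(ok[:, cols], vals[:, cols], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are gaps
            grid[:, i] = np.nanmedian(sub, axis=1)
    x = GRID_STARTS.astype(float)
    out = np.full_like(grid, np.nan)
    usable = ~np.isnan(grid).all(axis=1)
    for r in np.flatnonzero(usable):
        row = grid[r]
        g = np.isnan(row)
        out[r] = row if not g.any() else np.interp(x, x[~g], row[~g])
    out[usable] = savgol_filter(out[usable], cfg.window_points, cfg.poly_order,
                                axis=1, mode="interp")
    return out
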