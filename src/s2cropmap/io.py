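"""File I/O: class rasters (TIFF), scenes (NPZ), sample and feature tables (CSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .spectral import BANDS
from .synthetic import ObservationSeries, SceneRaster

NODATA = 255


def write_raster(path: str | Path, arr: np.ndarray) -> None:
    """Write a class raster as a single-band uint8 TIFF (nodata convention: 255)."""
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.uint8))


def read_raster(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def save_scene(path: str | Path, scene: SceneRaster) -> None:
    np.savez_compressed(
        str(path), truth=scene.truth, doys=scene.doys,
        reflectance=scene.reflectance, valid=scene.valid,
        zone=np.array(scene.zone), pixel_size=np.array(scene.pixel_size),
    )


def load_scene(path: str | Path) -> SceneRaster:
    with np.load(str(path)) as z:
        return SceneRaster(z["truth"], z["doys"], z["reflectance"], z["valid"],
                           str(z["zone"]), float(z["pixel_size"]))


def samples_to_frame(series_list: list[ObservationSeries]) -> pd.DataFrame:
    """Long-format sample table: id, zone, label, doy, 8 band columns, valid."""
    rows = []
    for sid, s in enumerate(series_list):
        for k, doy in enumerate(s.doys):
            rec = {"id": sid, "zone": s.zone, "label": s.label, "doy": int(doy)}
            rec.update({b: float(s.reflectance[k, j]) for j, b in enumerate(BANDS)})
            rec["valid"] = bool(s.valid[k])
            rows.append(rec)
    return pd.DataFrame(rows)


def frame_to_samples(df: pd.DataFrame) -> list[ObservationSeries]:
    out = []
    for sid, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("doy")
        out.append(ObservationSeries(
            sub["doy"].to_numpy(),
            sub[list(BANDS)].to_numpy(dtype=float),
            sub["valid"].to_numpy(dtype=bool),
            int(sub["label"].iloc[0]),
            str(sub["zone"].iloc[0]),
        ))
    return out


def write_features(path: str | Path, fm: pd.DataFrame, labels=None) -> None:
    df = fm.copy()
    if labels is not None:
        df.insert(0, "label", np.asarray(labels))
    df.to_csv(path, index_label="sample")


def read_features(path: str | Path) -> tuple[pd.DataFrame, np.ndarray | None]:
    df = pd.read_csv(path, index_col="sample")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    return df, labels
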