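# s2cropmap

Hierarchical crop-type mapping (rice / maize / soybean / other) from
regularized Sentinel-2-like reflectance time series, with a synthetic scene
generator standing in for the real imagery archive.

The pipeline mirrors an operational two-stage mapping workflow:

1. **synthetic scenes** (`s2cropmap.synthetic`) — labeled 8-band observation
   series (blue, red, RE1-3, NIR, SWIR1/2) on an irregular ~5-day calendar
   with cloud contamination, plus rasterized field scenes. Rice carries a
   DOY 120-150 flooding signal (depressed SWIR, elevated LSWI/NDSVI); maize
   shows higher RENDVI/REP than soybean at peak season.
2. **spectral proxies** (`s2cropmap.spectral`) — the 7 indices (NDVI, EVI,
   LSWI, NDSVI, NDTI, RENDVI, REP) plus RE2/SWIR1/SWIR2 passthroughs, and a
   surrogate cloud score.
3. **temporal regularization** (`s2cropmap.temporal`) — 10-day median
   composites on the 22-interval DOY 90-300 grid, linear gap filling,
   Savitzky-Golay smoothing (7-point window, cubic).
4. **feature banks** (`s2cropmap.features`, `s2cropmap.texture`) — 184
   cropland candidates (30 stage medians + 100 annual statistics + 54 GLCM
   textures) and 255 crop candidates (220 time-series values + 20
   greenest/wettest-composite proxies + 15 harmonic coefficients).
5. **feature selection** (`s2cropmap.selection`) — Gini-importance (MDI)
   ranking from a 100-tree forest, then Ward clustering of the top 50 on
   Spearman correlations cut at height 1, keeping one feature per cluster.
6. **classification** (`s2cropmap.classify`) — per-zone hierarchical random
   forest (cropland mask, then 4-class crop typing; 100 trees, min leaf 10,
   sqrt(p) variables/split, bag fraction 0.5) with spectral angle (SAM) and
   spectral correlation (SCM) baselines.
7. **postprocessing** (`s2cropmap.postprocess`) — patches under 0.1 ha are
   reassigned by a 100 m-radius circular majority filter.
8. **assessment** (`s2cropmap.assessment`) — confusion matrices
   (map rows × reference columns), OA/UA/PA/F1, and mapped-vs-statistical
   area regression. `s2cropmap.reference_data` ships the published
   2017-2019 validation matrices of the map product this package models.

## CLI

```sh
s2cropmap run-all --seed 1 --out-dir runs/demo        # full workflow
s2cropmap simulate --seed 1 --out-dir runs/sim        # scene + samples
s2cropmap features --scene runs/sim/scene.npz --mode crop --out crop.csv
s2cropmap select --features crop.csv --out selection.csv
s2cropmap assess --pred map.tif --truth truth.tif --out metrics.json
```

`run-all` simulates a scene, builds both feature banks, selects features,
trains the two-stage model, classifies every pixel, despeckles, and writes
`map.tif`, `map_despeckled.tif`, `selection_*.csv` and `metrics.json`.
Runs are deterministic per seed (byte-identical outputs). Defaults live in
`s2cropmap.config.RunConfig` and can be overridden with a YAML file
(`--config`).

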