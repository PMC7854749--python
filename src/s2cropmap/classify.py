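"""Zone-specific hierarchical classification: cropland mask, then crop type.

Random forest is the primary classifier (100 trees, min leaf population 10,
sqrt(p) variables per split, bag fraction 0.5); spectral angle (SAM) and
spectral correlation (SCM) mappers against per-class mean reference
spectra serve as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .synthetic import CLASS_LABELS, OTHER

ZONES = ("GK", "SJ", "LK", "SL", "LD", "IM")


@dataclass
class RFConfig:
    n_trees: int = 100
    min_leaf: int = 10
    variables_per_split: int | None = None   # None -> floor(sqrt(n_features))
    bag_fraction: float = 0.5
    seed: int = 0

    def make(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_leaf,
            max_features=self.variables_per_split or "sqrt",
            bootstrap=True,
            max_samples=self.bag_fraction,
            oob_score=False,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class ZoneModel:
    """Fitted two-stage classifier for one agro-climate zone."""

    zone: str
    cropland_features: list[str]
    crop_features: list[str]
    cropland_clf: RandomForestClassifier
    crop_clf: RandomForestClassifier
    config: RFConfig = field(default_factory=RFConfig)

    def _check(self, fm: pd.DataFrame, needed: list[str], stage: str) -> pd.DataFrame:
        missing = [c for c in needed if c not in fm.columns]
        if missing:
            raise ValueError(
                f"zone {self.zone}: {stage} prediction requires features "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
        return fm[needed]

    def predict_cropland(self, fm: pd.DataFrame) -> np.ndarray:
        x = self._check(fm, self.cropland_features, "cropland")
        return self.cropland_clf.predict(x.to_numpy()).astype(int)

    def predict_crop(self, fm: pd.DataFrame) -> np.ndarray:
        x = self._check(fm, self.crop_features, "crop")
        return self.crop_clf.predict(x.to_numpy()).astype(int)

    def predict_hierarchical(self, fm: pd.DataFrame) -> np.ndarray:
        """Stage 1 masks non-cropland to code 3; stage 2 types the cropland."""
        is_crop = self.predict_cropland(fm) == 1
        out = np.full(len(fm), OTHER, dtype=int)
        if is_crop.any():
            out[is_crop] = self.predict_crop(fm.iloc[np.flatnonzero(is_crop)])
        return out


def train_zone(cropland_fm: pd.DataFrame, cropland_labels,
               crop_fm: pd.DataFrame, crop_labels,
               zone: str = "SJ", cfg: RFConfig | None = None) -> ZoneModel:
    """Fit the binary cropland stage and the 4-class crop stage for one zone.

    ``cropland_labels`` are {0: non-cropland, 1: cropland}; ``crop_labels``
    are the class codes {0: rice, 1: maize, 2: soybean, 3: other}.
    """
    cfg = cfg or RFConfig()
    y1 = np.asarray(cropland_labels)
    for code in (0, 1):
        if code not in y1:
            kind = "cropland" if code else "non-cropland"
            raise ValueError(f"zone {zone}: no {kind} samples in stage-1 training data")
    y2 = np.asarray(crop_labels)
    for code, name in CLASS_LABELS.items():
        if code not in y2:
            raise ValueError(f"zone {zone}: missing class {name!r} in stage-2 training data")
    clf1 = cfg.make().fit(cropland_fm.to_numpy(), y1)
    clf2 = cfg.make().fit(crop_fm.to_numpy(), y2)
    return ZoneModel(zone, list(cropland_fm.columns), list(crop_fm.columns),
                     clf1, clf2, cfg)


def predict_hierarchical(models: dict[str, ZoneModel], fm: pd.DataFrame,
                         zones=None) -> np.ndarray:
    """Route samples to their zone's model; single-zone input may omit ``zones``."""
    if zones is None:
        if len(models) != 1:
            raise ValueError("zones required when several zone models are given")
        return next(iter(models.values())).predict_hierarchical(fm)
    zones = np.asarray(zones)
    out = np.empty(len(fm), dtype=int)
    for z in np.unique(zones):
        if z not in models:
            raise ValueError(f"no model for zone {z!r}")
        rows = np.flatnonzero(zones == z)
        out[rows] = models[z].predict_hierarchical(fm.iloc[rows])
    return out


# ---------------------------------------------------------------------------
# reference-spectrum baselines

def build_reference_spectra(fm: pd.DataFrame, labels) -> dict[int, np.ndarray]:
    """Per-class mean feature vector used as SAM/SCM reference."""
    y = np.asarray(labels)
    refs = {}
    for code in np.unique(y):
        vec = fm.to_numpy()[y == code].mean(axis=0)
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite reference spectrum for class {code}")
        refs[int(code)] = vec
    return refs


def sam_classify(fm: pd.DataFrame, refs: dict[int, np.ndarray]) -> np.ndarray:
    """Spectral angle mapper: argmin of arccos(<x,r>/(|x||r|)) over classes."""
    x = np.asarray(fm, dtype=float)
    xn = np.linalg.norm(x, axis=1)
    if (xn == 0).any():
        raise ValueError("zero-norm feature vector cannot be angle-classified")
    codes = sorted(refs)
    angles = np.empty((len(x), len(codes)))
    for k, code in enumerate(codes):
        r = refs[code]
        rn = np.linalg.norm(r)
        if rn == 0:
            raise ValueError(f"zero-norm reference spectrum for class {code}")
        cosine = np.clip(x @ r / (xn * rn), -1.0, 1.0)
        angles[:, k] = np.arccos(cosine)
    return np.asarray(codes)[np.argmin(angles, axis=1)]


def scm_classify(fm: pd.DataFrame, refs: dict[int, np.ndarray]) -> np.ndarray:
    """Spectral correlation mapper: argmax centered correlation with references."""
    x = np.asarray(fm, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("SCM needs feature vectors with at least 2 components")
    xc = x - x.mean(axis=1, keepdims=True)
    xs = np.linalg.norm(xc, axis=1)
    if (xs == 0).any():
        raise ValueError("zero-variance feature vector cannot be correlation-classified")
    codes = sorted(refs)
    corr = np.empty((len(x), len(codes)))
    for k, code in enumerate(codes):
        rc = refs[code] - refs[code].mean()
        rs = np.linalg.norm(rc)
        if rs == 0:
            raise ValueError(f"zero-variance reference spectrum for class {code}")
        corr[:, k] = xc @ rc / (xs * rs)
    return np.asarray(codes)[np.argmax(corr, axis=1)]
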