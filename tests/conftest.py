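import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from s2cropmap import synthetic as syn
from s2cropmap.features import build_crop_bank


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def series_arrays(code: int, n: int, seed: int):
    """(doys, reflectance (n,t,8), valid (n,t)) for one class's default params."""
    sl = syn.simulate_series(syn.default_params(code), n, seed=seed)
    return sl[0].doys, np.stack([s.reflectance for s in sl]), np.stack([s.valid for s in sl])


def labeled_crop_bank(n_per_class: int, seed: int):
    """Crop feature matrix + labels over all four default classes."""
    frames, labels = [], []
    for code in range(4):
        doys, refl, valid = series_arrays(code, n_per_class, seed * 10 + code)
        fm = build_crop_bank(doys, refl, valid)
        frames.append(fm)
        labels.append(np.full(len(fm), code))
    return (pd.concat(frames, ignore_index=True), np.concatenate(labels))


@pytest.fixture(scope="session")
def crop_bank_small():
    """Session-cached 4-class crop bank, 120 samples per class."""
    return labeled_crop_bank(120, seed=7)


@pytest.fixture(scope="session")
def default_scene():
    """Session-cached 40x40 synthetic scene with all four classes."""
    return syn.simulate_scene(40, 40, (0.25, 0.30, 0.25, 0.20), seed=3, patch=5)
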