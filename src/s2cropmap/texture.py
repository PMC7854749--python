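"""Gray-level co-occurrence texture statistics.

The co-occurrence matrix is accumulated symmetrically for the four
standard unit offsets (0,1), (1,0), (1,1), (1,-1); the 18 statistics are
computed per offset and averaged. Images are quantized to ``levels`` gray
levels over their own min-max range. Conventions fixed here (natural log,
0*log(0)=0, degenerate-image correlation = 1) are shared with the tests'
brute-force oracle.
"""

from __future__ import annotations

import numpy as np

OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_STATS = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2", "mcc",
    "dissimilarity", "inertia", "cluster_shade", "cluster_prominence",
)


def quantize(image: np.ndarray, levels: int = 32) -> np.ndarray:
    """Linear quantization of an image to integer levels 0..levels-1."""
    img = np.asarray(image, dtype=float)
    lo, hi = np.nanmin(img), np.nanmax(img)
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def cooccurrence(quantized: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one pixel offset."""
    dr, dc = offset
    h, w = quantized.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quantized[r0:r1, c0:c1].ravel()
    b = quantized[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    m = np.zeros((levels, levels), dtype=float)
    np.add.at(m, (a, b), 1.0)
    m += m.T
    total = m.sum()
    if total == 0:
        raise ValueError("image too small for the requested offset")
    return m / total


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_stats(p: np.ndarray) -> dict[str, float]:
    """The 18 texture statistics of one normalized symmetric GLCM."""
    g = p.shape[0]
    i = np.arange(g, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))

    asm = float(np.sum(p * p))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    if var_x * var_y > 0:
        correlation = float(np.sum((ii - mu_x) * (jj - mu_y) * p)
                            / np.sqrt(var_x * var_y))
    else:
        correlation = 1.0
    variance = float(np.sum((ii - mu_x) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))

    k_sum = np.arange(2 * g - 1, dtype=float)
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (np.arange(g)[:, None] + np.arange(g)[None, :]).ravel(), p.ravel())
    sum_average = float(np.sum(k_sum * p_sum))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * p_sum))
    sum_entropy = float(-np.sum(_xlogx(p_sum)))

    entropy = float(-np.sum(_xlogx(p)))

    k_diff = np.arange(g, dtype=float)
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(np.arange(g)[:, None] - np.arange(g)[None, :]).ravel(),
              p.ravel())
    mu_diff = float(np.sum(k_diff * p_diff))
    difference_variance = float(np.sum((k_diff - mu_diff) ** 2 * p_diff))
    difference_entropy = float(-np.sum(_xlogx(p_diff)))

    pxy = px[:, None] * py[None, :]
    hx = float(-np.sum(_xlogx(px)))
    hy = float(-np.sum(_xlogx(py)))
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log(pxy[nz])))
    hxy2 = float(-np.sum(_xlogx(pxy)))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)), restricted to occupied levels
    live = px > 0
    p_l = p[np.ix_(live, live)]
    a = p_l / px[live][:, None]
    b = p_l / py[live][None, :]
    eig = np.sort(np.real(np.linalg.eigvals(a @ b.T)))
    mcc = float(np.sqrt(np.clip(eig[-2], 0.0, 1.0))) if eig.size >= 2 else 1.0

    dissimilarity = float(np.sum(np.abs(ii - jj) * p))
    cluster_shade = float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p))
    cluster_prominence = float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p))

    return {
        "asm": asm, "contrast": contrast, "correlation": correlation,
        "variance": variance, "idm": idm, "sum_average": sum_average,
        "sum_variance": sum_variance, "sum_entropy": sum_entropy,
        "entropy": entropy, "difference_variance": difference_variance,
        "difference_entropy": difference_entropy, "imc1": imc1, "imc2": imc2,
        "mcc": mcc, "dissimilarity": dissimilarity, "inertia": contrast,
        "cluster_shade": cluster_shade, "cluster_prominence": cluster_prominence,
    }


def glcm_textures(image: np.ndarray, levels: int = 32) -> dict[str, float]:
    """Offset-averaged 18-statistic texture vector of one image window."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("texture image must be 2-D and at least 2x2")
    q = quantize(img, levels)
    acc = {k: 0.0 for k in GLCM_STATS}
    for off in OFFSETS:
        stats = glcm_stats(cooccurrence(q, off, levels))
        for k in GLCM_STATS:
            acc[k] += stats[k]
    return {k: v / len(OFFSETS) for k, v in acc.items()}
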