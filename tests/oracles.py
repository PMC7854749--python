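"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops over definitions, deliberately
avoiding the package's vectorized implementation paths.
"""

import math

import numpy as np


def sg_weights(window: int, order: int) -> np.ndarray:
    """Savitzky-Golay weights for the window center via explicit least squares.

    Row of the hat matrix H = X (X'X)^-1 X' belonging to the central point,
    with X the polynomial design on offsets -h..h.
    """
    h = window // 2
    x = np.arange(-h, h + 1, dtype=float)
    design = np.vander(x, order + 1, increasing=True)
    hat = design @ np.linalg.inv(design.T @ design) @ design.T
    return hat[h]


def glcm_pairs(quantized: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by per-pixel enumeration."""
    h, w = quantized.shape
    dr, dc = offset
    m = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = int(quantized[r, c]), int(quantized[r2, c2])
                m[a, b] += 1
                m[b, a] += 1
    return m / m.sum()


def glcm_stats_bruteforce(p: np.ndarray) -> dict:
    """The 18 texture statistics computed with explicit loops.

    Shares the package's stated conventions (natural log, 0 log 0 = 0,
    correlation = 1 for a degenerate matrix) but no code.
    """
    g = p.shape[0]
    px = [sum(p[i][j] for j in range(g)) for i in range(g)]
    py = [sum(p[i][j] for i in range(g)) for j in range(g)]
    mu_x = sum(i * px[i] for i in range(g))
    mu_y = sum(j * py[j] for j in range(g))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(g))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(g))

    def xlogx(v):
        return v * math.log(v) if v > 0 else 0.0

    asm = contrast = idm = entropy = 0.0
    corr_num = variance = dissimilarity = shade = prom = 0.0
    hxy1 = hxy2 = 0.0
    p_sum = [0.0] * (2 * g - 1)
    p_diff = [0.0] * g
    for i in range(g):
        for j in range(g):
            v = p[i][j]
            asm += v * v
            contrast += (i - j) ** 2 * v
            idm += v / (1 + (i - j) ** 2)
            entropy -= xlogx(v)
            corr_num += (i - mu_x) * (j - mu_y) * v
            variance += (i - mu_x) ** 2 * v
            dissimilarity += abs(i - j) * v
            shade += (i + j - mu_x - mu_y) ** 3 * v
            prom += (i + j - mu_x - mu_y) ** 4 * v
            p_sum[i + j] += v
            p_diff[abs(i - j)] += v
            marg = px[i] * py[j]
            if v > 0 and marg > 0:
                hxy1 -= v * math.log(marg)
            hxy2 -= xlogx(marg)
    correlation = corr_num / math.sqrt(var_x * var_y) if var_x * var_y > 0 else 1.0
    sum_average = sum(k * p_sum[k] for k in range(2 * g - 1))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * g - 1))
    sum_entropy = -sum(xlogx(v) for v in p_sum)
    mu_d = sum(k * p_diff[k] for k in range(g))
    difference_variance = sum((k - mu_d) ** 2 * p_diff[k] for k in range(g))
    difference_entropy = -sum(xlogx(v) for v in p_diff)
    hx = -sum(xlogx(v) for v in px)
    hy = -sum(xlogx(v) for v in py)
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    live = [i for i in range(g) if px[i] > 0]
    q = np.zeros((len(live), len(live)))
    for a, i in enumerate(live):
        for b, j in enumerate(live):
            q[a, b] = sum(p[i][k] * p[j][k] / (px[i] * py[k])
                          for k in live if py[k] > 0)
    if len(live) >= 2:
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(min(1.0, max(0.0, eig[-2])))
    else:
        mcc = 1.0

    return {
        "asm": asm, "contrast": contrast, "correlation": correlation,
        "variance": variance, "idm": idm, "sum_average": sum_average,
        "sum_variance": sum_variance, "sum_entropy": sum_entropy,
        "entropy": entropy, "difference_variance": difference_variance,
        "difference_entropy": difference_entropy, "imc1": imc1, "imc2": imc2,
        "mcc": mcc, "dissimilarity": dissimilarity, "inertia": contrast,
        "cluster_shade": shade, "cluster_prominence": prom,
    }


def glcm_textures_bruteforce(image: np.ndarray, levels: int = 32) -> dict:
    """Offset-averaged oracle counterpart of ``texture.glcm_textures``."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        q = np.minimum((np.floor((img - lo) / (hi - lo) * levels)).astype(int),
                       levels - 1)
    else:
        q = np.zeros(img.shape, dtype=int)
    offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
    acc = None
    for off in offsets:
        stats = glcm_stats_bruteforce(glcm_pairs(q, off, levels))
        acc = stats if acc is None else {k: acc[k] + stats[k] for k in stats}
    return {k: v / len(offsets) for k, v in acc.items()}
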