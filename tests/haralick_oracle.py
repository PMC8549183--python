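"""Independent reference implementation of GLCM + the 13 texture statistics.

Written straight from the classical definitions with explicit Python loops
— no shared code with the package implementation.  Used as the oracle in
unit and acceptance tests.
"""

import math

import numpy as np

OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1)]  # 0, 45, 90, 135 degrees


def reference_glcm(levels, mask, scale, n_bins):
    """Brute-force pair enumeration, symmetrised, normalised."""
    h, w = levels.shape
    counts = np.zeros((n_bins, n_bins), dtype=float)
    for dy, dx in OFFSETS:
        oy, ox = dy * scale, dx * scale
        for y in range(h):
            for x in range(w):
                y2, x2 = y + oy, x + ox
                if not (0 <= y2 < h and 0 <= x2 < w):
                    continue
                if not (mask[y, x] and mask[y2, x2]):
                    continue
                a, b = levels[y, x], levels[y2, x2]
                counts[a, b] += 1
                counts[b, a] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pairs")
    return counts / total


def _log2(v):
    return math.log2(v) if v > 0 else 0.0


def reference_haralick(p):
    """The 13 statistics, each summed with explicit loops, log base 2."""
    g = p.shape[0]
    px = [sum(p[i, j] for j in range(g)) for i in range(g)]
    py = [sum(p[i, j] for i in range(g)) for j in range(g)]
    mu_x = sum(i * px[i] for i in range(g))
    mu_y = sum(j * py[j] for j in range(g))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(g))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(g))

    p_sum = [0.0] * (2 * g - 1)
    p_diff = [0.0] * g
    for i in range(g):
        for j in range(g):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    asm = sum(p[i, j] ** 2 for i in range(g) for j in range(g))
    con = sum(k ** 2 * p_diff[k] for k in range(g))
    if var_x > 0 and var_y > 0:
        cor = (sum(i * j * p[i, j] for i in range(g) for j in range(g))
               - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        cor = 0.0
    var = sum((i - mu_x) ** 2 * p[i, j] for i in range(g) for j in range(g))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    sav = sum(k * p_sum[k] for k in range(2 * g - 1))
    sva = sum((k - sav) ** 2 * p_sum[k] for k in range(2 * g - 1))
    sen = -sum(p_sum[k] * _log2(p_sum[k]) for k in range(2 * g - 1))
    ent = -sum(p[i, j] * _log2(p[i, j]) for i in range(g) for j in range(g))
    mu_d = sum(k * p_diff[k] for k in range(g))
    dva = sum((k - mu_d) ** 2 * p_diff[k] for k in range(g))
    den = -sum(p_diff[k] * _log2(p_diff[k]) for k in range(g))

    hx = -sum(px[i] * _log2(px[i]) for i in range(g))
    hy = -sum(py[j] * _log2(py[j]) for j in range(g))
    hxy1 = -sum(p[i, j] * _log2(px[i] * py[j])
                for i in range(g) for j in range(g))
    hxy2 = -sum(px[i] * py[j] * _log2(px[i] * py[j])
                for i in range(g) for j in range(g))
    denom = max(hx, hy)
    f12 = (ent - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - ent))
    f13 = math.sqrt(arg) if arg > 0 else 0.0

    return dict(asm=asm, con=con, cor=cor, var=var, idm=idm, sav=sav,
                sva=sva, sen=sen, ent=ent, dva=dva, den=den, f12=f12, f13=f13)
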