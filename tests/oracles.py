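"""Independent literal-formula oracles used by the unit and acceptance tests.

Every function here re-derives an expected value from first principles —
explicit loops, direct formula transcription, brute-force enumeration —
deliberately avoiding the package's own vectorized code paths.
"""

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Blur
# ---------------------------------------------------------------------------

def brute_force_line_kernel(L: int, angle_deg: float) -> np.ndarray:
    """Anti-aliased line PSF: L unit-spaced taps, bilinear splat, unit sum.

    Returns a dict-free dense array with odd shape centered on the zero tap.
    """
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    if abs(c) < 1e-12:
        c = 0.0
    if abs(s) < 1e-12:
        s = 0.0
    cells = {}
    for j in range(L):
        t = j - (L - 1) // 2
        x, y = t * c, -t * s
        x0, y0 = math.floor(x), math.floor(y)
        fx, fy = x - x0, y - y0
        for (rr, cc), w in [
            ((y0, x0), (1 - fy) * (1 - fx)),
            ((y0, x0 + 1), (1 - fy) * fx),
            ((y0 + 1, x0), fy * (1 - fx)),
            ((y0 + 1, x0 + 1), fy * fx),
        ]:
            if w > 0:
                cells[(rr, cc)] = cells.get((rr, cc), 0.0) + w / L
    half_r = max(abs(r) for r, _ in cells)
    half_c = max(abs(cl) for _, cl in cells)
    grid = np.zeros((2 * half_r + 1, 2 * half_c + 1))
    for (r, cl), w in cells.items():
        grid[half_r + r, half_c + cl] = w
    return grid / grid.sum()


def direct_motion_sum(img: np.ndarray, L: int) -> np.ndarray:
    """Direct horizontal motion-blur sum with centered support.

    g(r, c) = (1/L) * sum_{j=0}^{L-1} f[r, c + j - (L-1)//2], valid at
    interior pixels only (no padding applied).
    """
    h, w = img.shape
    out = np.full((h, w), np.nan)
    off = (L - 1) // 2
    for r in range(h):
        for c in range(off, w - (L - 1 - off)):
            out[r, c] = sum(img[r, c + j - off] for j in range(L)) / L
    return out


# ---------------------------------------------------------------------------
# Features: literal per-pixel/per-block transcriptions
# ---------------------------------------------------------------------------

def scharr_center(img5: np.ndarray) -> float:
    """Scharr gradient magnitude at the center of a 5x5 patch, by stencil."""
    kx = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0
    ky = kx.T
    patch = img5[1:4, 1:4]
    gx = float((patch * kx).sum())
    gy = float((patch * ky).sum())
    return math.hypot(gx, gy)


def similarity_scalar(a: float, b: float, c: float) -> float:
    return (2.0 * a * b + c) / (a * a + b * b + c)


def lsf_oracle(pc_r, pc_d, gm_r, gm_d, a_pc, a1, alpha, beta) -> float:
    """Pixel-by-pixel transcription of the PC/GM similarity with PC pooling."""
    h, w = pc_r.shape
    num = den = 0.0
    for i in range(h):
        for j in range(w):
            s_pc = similarity_scalar(pc_r[i, j], pc_d[i, j], a_pc)
            s_gm = similarity_scalar(gm_r[i, j], gm_d[i, j], a1)
            f_l = s_pc ** alpha * s_gm ** beta
            wgt = max(pc_r[i, j], pc_d[i, j])
            num += f_l * wgt
            den += wgt
    return num / den if den > 0 else num / (h * w)


def vsf_oracle(vs_r, vs_d, gm_r, gm_d, m_r, m_d, n_r, n_d, a1, a2, alpha, beta) -> float:
    """Transcription of the saliency/gradient/chrominance fusion."""
    def pooled(a, b, c):
        vals = [
            similarity_scalar(a[i, j], b[i, j], c)
            for i in range(a.shape[0])
            for j in range(a.shape[1])
        ]
        return sum(vals) / len(vals)

    f_vs = pooled(255.0 * vs_r, 255.0 * vs_d, a2)
    f_gm = pooled(gm_r, gm_d, a1)
    f_c = pooled(m_r, m_d, a2) * pooled(n_r, n_d, a2)
    return f_vs * f_gm ** alpha * f_c ** beta


def log_gabor_filter_oracle(shape, f_rs, bw_ratio, mu0, sigma0) -> np.ndarray:
    """Literal frequency-domain log-Gabor transfer function on the DFT grid."""
    h, w = shape
    filt = np.zeros((h, w))
    fys = np.fft.fftfreq(h)
    fxs = np.fft.fftfreq(w)
    for i in range(h):
        for j in range(w):
            fr = math.hypot(fxs[j], fys[i])
            if fr == 0:
                continue
            ft = math.atan2(-fys[i], fxs[j])
            d = math.atan2(math.sin(ft - mu0), math.cos(ft - mu0))
            radial = math.exp(-(math.log(fr / f_rs)) ** 2 / (2 * math.log(bw_ratio) ** 2))
            angular = math.exp(-(d ** 2) / (2 * sigma0 ** 2))
            filt[i, j] = radial * angular
    return filt


def lgf_oracle(ref, dist, f_rs, bw_ratio, mu0, sigma0, c_stab) -> float:
    """Single-subband amplitude similarity via the literal DFT filter."""
    filt = log_gabor_filter_oracle(ref.shape, f_rs, bw_ratio, mu0, sigma0)
    a_r = np.abs(np.fft.ifft2(np.fft.fft2(ref) * filt))
    a_d = np.abs(np.fft.ifft2(np.fft.fft2(dist) * filt))
    vals = [
        similarity_scalar(a_r[i, j], a_d[i, j], c_stab)
        for i in range(ref.shape[0])
        for j in range(ref.shape[1])
    ]
    return sum(vals) / len(vals)


def local_variance_3x3(img: np.ndarray) -> np.ndarray:
    """3x3 local variance with replicate padding, by explicit loops."""
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(img[ii, jj])
            m = sum(vals) / 9.0
            out[i, j] = sum((v - m) ** 2 for v in vals) / 9.0
    return out


def information_oracle(img: np.ndarray, block: int, noise_var: float) -> float:
    """Literal log-determinant information sum for the scalar model.

    Per block i: (1/2) log2(|s_i^2 + eps I| / |eps I|) with scalar
    determinants, s_i^2 the block-mean of the 3x3 local variance.
    """
    lv = local_variance_3x3(img)
    h, w = img.shape
    total = 0.0
    for bi in range(h // block):
        for bj in range(w // block):
            patch = lv[bi * block : (bi + 1) * block, bj * block : (bj + 1) * block]
            s2 = float(patch.mean())
            total += 0.5 * math.log2((s2 + noise_var) / noise_var)
    return total


def nsf_oracle(gm_r: np.ndarray, gm_d: np.ndarray, block: int, a3: float) -> float:
    """Literal block-contrast statistic on co-located block pairs."""
    h, w = gm_r.shape
    vals = []
    for bi in range(h // block):
        for bj in range(w // block):
            ci, cj = bi * block + block // 2, bj * block + block // 2
            fi, fj = gm_r[ci, cj], gm_d[ci, cj]
            m = max(fi, fj)
            if m == 0:
                vals.append(1.0)
                continue
            R = abs(fi - fj) / m
            K = a3 / m ** 2
            vals.append((2 * (1 - R) + K) / (1 + (1 - R) ** 2 + K))
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# Rank statistics and logistic mapping
# ---------------------------------------------------------------------------

def _rank_with_ties(v) -> list:
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """SROCC as the Pearson correlation of mid-ranks, computed directly."""
    rx, ry = _rank_with_ties(list(x)), _rank_with_ties(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def kendall_tau_b_oracle(x, y) -> float:
    """Tie-corrected Kendall tau by O(n^2) pair enumeration."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif (dx > 0) == (dy > 0):
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v) -> float:
    from collections import Counter

    return sum(c * (c - 1) / 2 for c in Counter(v).values())


def logistic5_oracle(z, b1, b2, b3, b4, b5):
    z = np.asarray(z, float)
    return b1 * (0.5 - 1.0 / (1.0 + np.exp(b2 * (z - b3)))) + b4 * z + b5
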