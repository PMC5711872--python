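"""Naive, loop-based reference implementations used only by the tests.

Each oracle recomputes a quantity directly from its defining formula with
explicit Python loops, independently of the vectorized implementations it
checks.
"""

import math


def oracle_glcm_counts(q, offset):
    """Co-occurrence counts by explicit pixel-pair enumeration."""
    dr, dc = offset
    H = len(q)
    W = len(q[0])
    L = max(max(row) for row in q)
    counts = [[0] * L for _ in range(L)]
    n = 0
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                counts[q[r][c] - 1][q[r2][c2] - 1] += 1
                n += 1
    return counts, n


def _xlogx(p):
    return p * math.log(p) if p > 0 else 0.0


def oracle_glcm_features(P):
    """The 19 co-occurrence features from a probability grid, computed
    with scalar double loops.  Returns a dict keyed by feature name."""
    L = len(P)
    idx = list(range(1, L + 1))
    px = [sum(P[i - 1][j - 1] for j in idx) for i in idx]
    py = [sum(P[i - 1][j - 1] for i in idx) for j in idx]
    mux = sum(i * px[i - 1] for i in idx)
    muy = sum(j * py[j - 1] for j in idx)
    sx = math.sqrt(sum((i - mux) ** 2 * px[i - 1] for i in idx))
    sy = math.sqrt(sum((j - muy) ** 2 * py[j - 1] for j in idx))

    p_sum = {}
    p_diff = {}
    for i in idx:
        for j in idx:
            p_sum[i + j] = p_sum.get(i + j, 0.0) + P[i - 1][j - 1]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i - 1][j - 1]

    out = {}
    out["entropy"] = -sum(_xlogx(P[i - 1][j - 1]) for i in idx for j in idx)
    out["energy"] = sum(P[i - 1][j - 1] ** 2 for i in idx for j in idx)
    if sx * sy > 0:
        out["correlation"] = sum(
            (i - mux) * (j - muy) * P[i - 1][j - 1] for i in idx for j in idx
        ) / (sx * sy)
    else:
        out["correlation"] = 0.0
    out["contrast"] = sum((i - j) ** 2 * P[i - 1][j - 1] for i in idx for j in idx)
    out["variance"] = sum((i - mux) ** 2 * P[i - 1][j - 1] for i in idx for j in idx)
    sa = sum(k * v for k, v in p_sum.items())
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    out["sum_entropy"] = -sum(_xlogx(v) for v in p_sum.values())
    da = sum(k * v for k, v in p_diff.items())
    out["difference_variance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
    out["difference_entropy"] = -sum(_xlogx(v) for v in p_diff.values())
    hx = -sum(_xlogx(v) for v in px)
    hy = -sum(_xlogx(v) for v in py)
    hxy1 = -sum(
        P[i - 1][j - 1] * math.log(px[i - 1] * py[j - 1])
        for i in idx
        for j in idx
        if P[i - 1][j - 1] > 0
    )
    denom = max(hx, hy)
    out["imc1"] = (out["entropy"] - hxy1) / denom if denom > 0 else 0.0
    out["autocorrelation"] = sum(i * j * P[i - 1][j - 1] for i in idx for j in idx)
    out["dissimilarity"] = sum(abs(i - j) * P[i - 1][j - 1] for i in idx for j in idx)
    out["homogeneity"] = sum(
        P[i - 1][j - 1] / (1 + abs(i - j)) for i in idx for j in idx
    )
    out["cluster_prominence"] = sum(
        (i + j - mux - muy) ** 4 * P[i - 1][j - 1] for i in idx for j in idx
    )
    out["cluster_shade"] = sum(
        (i + j - mux - muy) ** 3 * P[i - 1][j - 1] for i in idx for j in idx
    )
    out["max_probability"] = max(P[i - 1][j - 1] for i in idx for j in idx)
    out["idn"] = sum(P[i - 1][j - 1] / (1 + abs(i - j) / L) for i in idx for j in idx)
    out["idmn"] = sum(
        P[i - 1][j - 1] / (1 + (i - j) ** 2 / L**2) for i in idx for j in idx
    )
    return out


def oracle_semivariogram(img, h, direction):
    """gamma(h) along one axis by explicit pair enumeration."""
    H = len(img)
    W = len(img[0])
    total = 0.0
    m = 0
    for r in range(H):
        for c in range(W):
            if direction == "horizontal":
                r2, c2 = r, c + h
            else:
                r2, c2 = r + h, c
            if r2 < H and c2 < W:
                total += (float(img[r][c]) - float(img[r2][c2])) ** 2
                m += 1
    if m == 0:
        raise ValueError("no pairs at this lag")
    return total / (2.0 * m)


def oracle_lbp_code(img, r, c, V=8, R=1.0):
    """LBP code at one pixel: neighbor 0 due east, counter-clockwise,
    bilinear interpolation of the neighbor-minus-center difference,
    bit set when the difference is >= 0."""
    H = len(img)
    W = len(img[0])
    center = float(img[r][c])
    code = 0
    for v in range(V):
        theta = 2.0 * math.pi * v / V
        rr = r - R * math.sin(theta)
        cc = c + R * math.cos(theta)
        if abs(rr - round(rr)) < 1e-9:
            rr = float(round(rr))
        if abs(cc - round(cc)) < 1e-9:
            cc = float(round(cc))
        r0, c0 = int(math.floor(rr)), int(math.floor(cc))
        r1, c1 = min(r0 + 1, H - 1), min(c0 + 1, W - 1)
        tr, tc = rr - r0, cc - c0
        diff = 0.0
        for (ri, wr) in ((r0, 1 - tr), (r1, tr)):
            for (ci, wc) in ((c0, 1 - tc), (c1, tc)):
                diff += wr * wc * (float(img[ri][ci]) - center)
        if diff >= 0:
            code += 2**v
    return code
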