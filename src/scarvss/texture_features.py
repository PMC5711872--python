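"""Texture descriptors for grayscale scar patches.

Three complementary statistics are computed on each 8-bit grayscale patch:

* **GLCM** — the gray-level co-occurrence matrix at a single pixel offset
  (default: one pixel to the right), summarized by 19 Haralick-style
  features.  The patch is first quantized to a small number of gray levels
  (default 8) spanning its own intensity range.
* **Semi-variogram** — the geostatistical statistic
  ``gamma(h) = (1/(2 m(h))) * sum_i [f(x_i) - f(x_i + h)]^2`` over all
  ``m(h)`` pixel pairs at lag ``h`` along one axis.  It captures global
  spatial structure: how quickly similarity decays with distance.  Computed
  on the *unquantized* 0-255 grayscale values, 10 lags in the horizontal and
  vertical directions.
* **LBP** — local binary pattern codes.  Each interior pixel is compared
  against ``V`` neighbors sampled on a circle of radius ``R`` (bilinear
  interpolation at non-integer positions); bit ``v`` is set when the
  neighbor is at least as bright as the center (``b(x) = 1`` for ``x >= 0``,
  so ties count as 1).  The patch descriptor is the normalized histogram of
  the ``2^V`` codes.

Numerical conventions: natural logarithms everywhere, ``0 * ln 0 == 0``,
and degenerate denominators (zero marginal variance, zero marginal entropy)
yield a feature value of 0 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# --------------------------------------------------------------------------
# Gray-level quantization and the co-occurrence matrix


def quantize(img: np.ndarray, num_levels: int = 8) -> np.ndarray:
    """Quantize a grayscale image to levels ``1..num_levels``.

    Equal-width bins span ``[min(img), max(img)]``; the maximum value maps
    to ``num_levels`` and a constant image maps entirely to level 1.
    """
    if num_levels < 2:
        raise ValueError(f"num_levels must be >= 2, got {num_levels}")
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.ones(img.shape, dtype=np.int64)
    q = 1 + np.floor((img - lo) / (hi - lo) * num_levels).astype(np.int64)
    q[q > num_levels] = num_levels
    return q


@dataclass(frozen=True)
class GLCM:
    """Co-occurrence counts and probabilities for one offset.

    ``counts[p-1, q-1]`` is the number of pixel pairs (u, v = u + offset)
    whose quantized values are (p, q); single direction, non-symmetric.
    ``probs`` is ``counts / n_pairs``.
    """

    counts: np.ndarray
    probs: np.ndarray
    offset: tuple[int, int]
    num_levels: int
    n_pairs: int

    def __post_init__(self) -> None:
        if self.counts.shape != (self.num_levels, self.num_levels):
            raise ValueError("counts grid does not match num_levels")
        if self.n_pairs != int(self.counts.sum()):
            raise ValueError("n_pairs does not equal the sum of counts")


def compute_glcm(
    img: np.ndarray,
    offset: tuple[int, int] = (0, 1),
    num_levels: int | None = None,
) -> GLCM:
    """Co-occurrence matrix of a quantized image for one (drow, dcol) offset."""
    q = np.asarray(img)
    if q.ndim != 2:
        raise ValueError("expected a 2-D quantized image")
    if num_levels is None:
        num_levels = int(q.max())
    if q.min() < 1 or q.max() > num_levels:
        raise ValueError("quantized values must lie in 1..num_levels")
    dr, dc = offset
    H, W = q.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty GLCM: no pixel pairs for offset {offset} in shape {(H, W)}")
    first = q[r0:r1, c0:c1]
    second = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.zeros((num_levels, num_levels), dtype=np.int64)
    np.add.at(counts, (first.ravel() - 1, second.ravel() - 1), 1)
    n_pairs = int(counts.sum())
    return GLCM(
        counts=counts,
        probs=counts / n_pairs,
        offset=(int(dr), int(dc)),
        num_levels=int(num_levels),
        n_pairs=n_pairs,
    )


GLCM_FEATURE_NAMES = (
    "entropy",
    "energy",
    "correlation",
    "contrast",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "autocorrelation",
    "dissimilarity",
    "homogeneity",
    "cluster_prominence",
    "cluster_shade",
    "max_probability",
    "idn",
    "idmn",
)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*ln(0) == 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def glcm_features(g: GLCM) -> np.ndarray:
    """The 19 co-occurrence features, in the fixed order of
    :data:`GLCM_FEATURE_NAMES`.

    Level indices i, j run over 1..L.  Marginals p_x(i) = sum_j p(i,j) and
    p_y(j) = sum_i p(i,j); p_{x+y}(k) sums p over cells with i + j = k and
    p_{x-y}(k) over cells with |i - j| = k.
    """
    if g.n_pairs <= 0:
        raise ValueError("GLCM has no pairs")
    L = g.num_levels
    p = g.probs
    levels = np.arange(1, L + 1, dtype=np.float64)
    i = levels[:, None]
    j = levels[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((levels * px).sum())
    mu_y = float((levels * py).sum())
    sigma_x = float(np.sqrt(((levels - mu_x) ** 2 * px).sum()))
    sigma_y = float(np.sqrt(((levels - mu_y) ** 2 * py).sum()))

    # p_{x+y} over k = 2..2L and p_{x-y} over k = 0..L-1
    ks_sum = np.arange(2, 2 * L + 1, dtype=np.float64)
    p_sum = np.zeros(2 * L - 1)
    ks_diff = np.arange(0, L, dtype=np.float64)
    p_diff = np.zeros(L)
    for a in range(L):
        for b in range(L):
            p_sum[a + b] += p[a, b]
            p_diff[abs(a - b)] += p[a, b]

    entropy = _entropy(p.ravel())
    energy = float((p**2).sum())
    if sigma_x * sigma_y > 0:
        correlation = float((((i - mu_x) * (j - mu_y) * p).sum()) / (sigma_x * sigma_y))
    else:
        correlation = 0.0
    contrast = float(((i - j) ** 2 * p).sum())
    variance = float(((i - mu_x) ** 2 * p).sum())
    sum_average = float((ks_sum * p_sum).sum())
    sum_variance = float(((ks_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    diff_average = float((ks_diff * p_diff).sum())
    difference_variance = float(((ks_diff - diff_average) ** 2 * p_diff).sum())
    difference_entropy = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    pxy_outer = px[:, None] * py[None, :]
    mask = p > 0
    hxy1 = float(-(p[mask] * np.log(pxy_outer[mask])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0

    autocorrelation = float((i * j * p).sum())
    dissimilarity = float((np.abs(i - j) * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    cluster = i + j - mu_x - mu_y
    cluster_prominence = float((cluster**4 * p).sum())
    cluster_shade = float((cluster**3 * p).sum())
    max_probability = float(p.max())
    idn = float((p / (1.0 + np.abs(i - j) / L)).sum())
    idmn = float((p / (1.0 + (i - j) ** 2 / L**2)).sum())

    return np.array(
        [
            entropy,
            energy,
            correlation,
            contrast,
            variance,
            sum_average,
            sum_variance,
            sum_entropy,
            difference_variance,
            difference_entropy,
            imc1,
            autocorrelation,
            dissimilarity,
            homogeneity,
            cluster_prominence,
            cluster_shade,
            max_probability,
            idn,
            idmn,
        ]
    )


def glcm_imc2(g: GLCM) -> float:
    """Second information measure of correlation (not part of the default
    19-feature vector): sqrt(1 - exp(-2 (HXY2 - HXY)))."""
    p = g.probs
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    pxy_outer = (px[:, None] * py[None, :]).ravel()
    hxy2 = _entropy(pxy_outer)
    hxy = _entropy(p.ravel())
    return float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))


# --------------------------------------------------------------------------
# Semi-variogram


@dataclass(frozen=True)
class SemivariogramProfile:
    """Empirical semivariance per lag along one axis."""

    lags: np.ndarray
    gamma: np.ndarray
    direction: str
    pair_counts: np.ndarray


def semivariogram(
    img: np.ndarray, n_lags: int = 10, direction: str = "horizontal"
) -> SemivariogramProfile:
    """Directional semi-variogram of an intensity image.

    ``gamma(h)`` is half the mean squared intensity difference over all
    pixel pairs separated by exactly ``h`` pixels along the direction
    (``horizontal``: within a row, ``vertical``: within a column).
    Intensities are used as floating-point values of the unquantized image.
    """
    f = np.asarray(img, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if direction not in ("horizontal", "vertical"):
        raise ValueError(f"unknown direction {direction!r}")
    extent = f.shape[1] if direction == "horizontal" else f.shape[0]
    if n_lags >= extent:
        raise ValueError(
            f"n_lags={n_lags} requires image extent > {n_lags} in the "
            f"{direction} direction, got {extent}"
        )
    gamma = np.empty(n_lags)
    counts = np.empty(n_lags, dtype=np.int64)
    for h in range(1, n_lags + 1):
        if direction == "horizontal":
            diff = f[:, :-h] - f[:, h:]
        else:
            diff = f[:-h, :] - f[h:, :]
        m = diff.size
        gamma[h - 1] = (diff**2).sum() / (2.0 * m)
        counts[h - 1] = m
    return SemivariogramProfile(
        lags=np.arange(1, n_lags + 1),
        gamma=gamma,
        direction=direction,
        pair_counts=counts,
    )


def sv_features(img: np.ndarray, n_lags: int = 10) -> np.ndarray:
    """Concatenated [horizontal gamma(1..n), vertical gamma(1..n)] vector."""
    h = semivariogram(img, n_lags, "horizontal")
    v = semivariogram(img, n_lags, "vertical")
    return np.concatenate([h.gamma, v.gamma])


# --------------------------------------------------------------------------
# Local binary patterns


@dataclass(frozen=True)
class LBPConfig:
    """Circular LBP sampling parameters (V neighbors on radius R)."""

    num_neighbors: int = 8
    radius: float = 1.0
    rotation_invariant: bool = False

    def __post_init__(self) -> None:
        if self.num_neighbors < 1:
            raise ValueError("num_neighbors must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


def _neighbor_offsets(cfg: LBPConfig) -> tuple[np.ndarray, np.ndarray]:
    """(drow, dcol) offsets of the V sampling points.

    Neighbor 0 lies due east at (0, +R); subsequent neighbors proceed
    counter-clockwise (visually upward first, i.e. decreasing row).
    Offsets within 1e-9 of an integer are snapped, so axis-aligned
    neighbors compare exact pixel values.
    """
    V, R = cfg.num_neighbors, cfg.radius
    angles = 2.0 * np.pi * np.arange(V) / V
    drow = -R * np.sin(angles)
    dcol = R * np.cos(angles)
    for arr in (drow, dcol):
        near = np.abs(arr - np.round(arr)) < 1e-9
        arr[near] = np.round(arr[near])
    return drow, dcol


def _bilinear_minus_center(
    f: np.ndarray, rr: np.ndarray, cc: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Bilinearly interpolated ``f`` at fractional (rr, cc), minus the
    center value.

    The center is subtracted from the four corner values *before*
    weighting, so a neighborhood of pixels equal to the center yields a
    difference of exactly 0 regardless of floating-point weight rounding —
    the sign convention b(0) = 1 then holds exactly on constant regions.
    """
    r0 = np.floor(rr).astype(np.int64)
    c0 = np.floor(cc).astype(np.int64)
    r1 = np.minimum(r0 + 1, f.shape[0] - 1)
    c1 = np.minimum(c0 + 1, f.shape[1] - 1)
    tr = rr - r0
    tc = cc - c0
    return (
        (f[r0, c0] - center) * (1 - tr) * (1 - tc)
        + (f[r0, c1] - center) * (1 - tr) * tc
        + (f[r1, c0] - center) * tr * (1 - tc)
        + (f[r1, c1] - center) * tr * tc
    )


def _rotation_min_codes(codes: np.ndarray, V: int) -> np.ndarray:
    table = np.arange(2**V, dtype=np.int64)
    best = table.copy()
    rolled = table.copy()
    for _ in range(V - 1):
        rolled = ((rolled >> 1) | ((rolled & 1) << (V - 1))) & (2**V - 1)
        best = np.minimum(best, rolled)
    return best[codes]


def lbp_codes(img: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """LBP code of every interior pixel (those at least ceil(R) from each
    border), as an integer array."""
    cfg = cfg or LBPConfig()
    f = np.asarray(img, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    margin = int(np.ceil(cfg.radius))
    H, W = f.shape
    if H < 2 * margin + 1 or W < 2 * margin + 1:
        raise ValueError(
            f"image of shape {(H, W)} too small for LBP radius {cfg.radius}"
        )
    rows = np.arange(margin, H - margin)
    cols = np.arange(margin, W - margin)
    rgrid, cgrid = np.meshgrid(rows, cols, indexing="ij")
    center = f[rgrid, cgrid]
    drow, dcol = _neighbor_offsets(cfg)
    codes = np.zeros(center.shape, dtype=np.int64)
    for v in range(cfg.num_neighbors):
        diff = _bilinear_minus_center(f, rgrid + drow[v], cgrid + dcol[v], center)
        codes |= (diff >= 0).astype(np.int64) << v
    if cfg.rotation_invariant:
        codes = _rotation_min_codes(codes, cfg.num_neighbors)
    return codes


def lbp_code(img: np.ndarray, u: tuple[int, int], cfg: LBPConfig | None = None) -> int:
    """LBP code of the single pixel at (row, col) ``u``."""
    cfg = cfg or LBPConfig()
    f = np.asarray(img, dtype=np.float64)
    margin = int(np.ceil(cfg.radius))
    r, c = u
    H, W = f.shape
    if not (margin <= r < H - margin and margin <= c < W - margin):
        raise ValueError(
            f"pixel {u} closer than radius {cfg.radius} to the border of {(H, W)}"
        )
    drow, dcol = _neighbor_offsets(cfg)
    center = f[r, c]
    code = 0
    for v in range(cfg.num_neighbors):
        diff = _bilinear_minus_center(
            f, np.array([r + drow[v]]), np.array([c + dcol[v]]), center
        )[0]
        if diff >= 0:
            code |= 1 << v
    if cfg.rotation_invariant:
        code = int(_rotation_min_codes(np.array([code]), cfg.num_neighbors)[0])
    return int(code)


def lbp_histogram(img: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Normalized histogram of LBP codes over all interior pixels
    (``2^V`` bins summing to 1)."""
    cfg = cfg or LBPConfig()
    codes = lbp_codes(img, cfg)
    hist = np.bincount(codes.ravel(), minlength=2**cfg.num_neighbors).astype(np.float64)
    return hist / hist.sum()
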