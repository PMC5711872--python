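"""Assembly of per-sample feature vectors and dataset-wide standardization.

A feature combination is named with the study's notation, e.g.
``"(LBP+SV)+(RGB+HSV+Lab)"``; parentheses group texture and color blocks
but carry no meaning here — the combination is simply the set of blocks
mentioned.  Blocks are always concatenated in the canonical order
GLCM, SV, LBP, RGB, HSV, LAB regardless of how the name orders them.

Standardization z-scores every column over the whole dataset (sample
standard deviation, divide by N-1).  Doing this before cross-validation
leaks the held-out sample's contribution to the column statistics; the
classifier module offers a fold-wise alternative, but dataset-wide is the
default protocol here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import color_features as cf
from . import texture_features as tf
from .dataset_io import to_grayscale

log = logging.getLogger(__name__)

BLOCK_ORDER = ("GLCM", "SV", "LBP", "RGB", "HSV", "LAB")
BLOCK_SIZES = {"GLCM": 19, "SV": 20, "LBP": 256, "RGB": 12, "HSV": 12, "LAB": 12}

_TOKEN_ALIASES = {
    "GLCM": "GLCM",
    "SV": "SV",
    "LBP": "LBP",
    "RGB": "RGB",
    "HSV": "HSV",
    "LAB": "LAB",
}


def parse_combo(name: str) -> tuple[str, ...]:
    """Resolve a combination name to the ordered tuple of blocks it uses."""
    tokens = [t for t in re.split(r"[()+\s]+", name) if t]
    if not tokens:
        raise ValueError(f"empty feature combination: {name!r}")
    blocks: set[str] = set()
    for tok in tokens:
        key = tok.upper()
        if key not in _TOKEN_ALIASES:
            raise ValueError(f"unknown feature block {tok!r} in combination {name!r}")
        blocks.add(_TOKEN_ALIASES[key])
    return tuple(b for b in BLOCK_ORDER if b in blocks)


def block_feature_names(block: str, lbp_bins: int = 256) -> list[str]:
    if block == "GLCM":
        return [f"glcm_{n}" for n in tf.GLCM_FEATURE_NAMES]
    if block == "SV":
        return [f"sv_h_{h}" for h in range(1, 11)] + [f"sv_v_{h}" for h in range(1, 11)]
    if block == "LBP":
        return [f"lbp_{c:03d}" for c in range(lbp_bins)]
    if block == "RGB":
        return [f"rgb_{ch}_{m}" for ch in "rgb" for m in ("mean", "var", "skew", "kurt")]
    if block == "HSV":
        return [f"hsv_{ch}_bin{b}" for ch in "hsv" for b in range(1, 5)]
    if block == "LAB":
        return [f"lab_{ch}_bin{b}" for ch in "lab" for b in range(1, 5)]
    raise ValueError(f"unknown block {block!r}")


@dataclass
class FeatureMatrix:
    """Samples x named features, with optional standardization state."""

    sample_ids: list[str]
    labels: np.ndarray
    values: np.ndarray
    columns: list[str]
    blocks: tuple[str, ...]
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length does not match values")
        if len(self.columns) != d:
            raise ValueError("column names do not match values width")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def extract_features(
    images: list[np.ndarray],
    combo: str | tuple[str, ...],
    labels: np.ndarray | list[int] | None = None,
    sample_ids: list[str] | None = None,
    *,
    glcm_levels: int = 8,
    glcm_offset: tuple[int, int] = (0, 1),
    sv_lags: int = 10,
    lbp_config: tf.LBPConfig | None = None,
) -> FeatureMatrix:
    """Compute the requested feature blocks for every image.

    Texture blocks are computed on the grayscale conversion of each image;
    color blocks see the original RGB pixels.
    """
    blocks = parse_combo(combo) if isinstance(combo, str) else tuple(combo)
    if not blocks:
        raise ValueError("empty feature combination")
    lbp_cfg = lbp_config or tf.LBPConfig()
    n = len(images)
    if labels is None:
        labels = np.zeros(n, dtype=int)
    labels = np.asarray(labels)
    if sample_ids is None:
        sample_ids = [f"sample_{k:04d}" for k in range(n)]

    rows = []
    for img in images:
        gray = to_grayscale(img) if "GLCM" in blocks or "SV" in blocks or "LBP" in blocks else None
        parts = []
        for block in blocks:
            if block == "GLCM":
                g = tf.compute_glcm(tf.quantize(gray, glcm_levels), glcm_offset)
                parts.append(tf.glcm_features(g))
            elif block == "SV":
                parts.append(tf.sv_features(gray, sv_lags))
            elif block == "LBP":
                parts.append(tf.lbp_histogram(gray, lbp_cfg))
            elif block == "RGB":
                parts.append(cf.rgb_moments(img))
            elif block == "HSV":
                parts.append(cf.hsv_histogram_features(img))
            elif block == "LAB":
                parts.append(cf.lab_histogram_features(img))
        rows.append(np.concatenate(parts))

    columns: list[str] = []
    for block in blocks:
        columns.extend(block_feature_names(block, lbp_bins=2**lbp_cfg.num_neighbors))
    return FeatureMatrix(
        sample_ids=list(sample_ids),
        labels=labels,
        values=np.vstack(rows),
        columns=columns,
        blocks=blocks,
    )


def standardization_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column means, sample SDs (ddof=1) and the zero-variance mask."""
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    zero = sds == 0.0
    return means, sds, zero


def apply_standardization(
    values: np.ndarray, means: np.ndarray, sds: np.ndarray, zero: np.ndarray
) -> np.ndarray:
    safe = np.where(zero, 1.0, sds)
    out = (values - means) / safe
    out[:, zero] = 0.0
    return out


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score every column over the dataset (sample SD, divide by N-1).

    Zero-variance columns are set to all zeros and flagged rather than
    dropped, so column counts stay stable across feature combinations.
    """
    if fm.standardized:
        raise ValueError("feature matrix is already standardized")
    if fm.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    means, sds, zero = standardization_stats(fm.values)
    if zero.any():
        log.info("standardize: %d zero-variance columns zeroed", int(zero.sum()))
    values = apply_standardization(fm.values, means, sds, zero)
    return replace(
        fm,
        values=values,
        standardized=True,
        column_means=means,
        column_sds=sds,
        zero_variance=zero,
    )


def write_feature_table(fm: FeatureMatrix, path) -> None:
    # default float formatting is the shortest exact repr, so the
    # table round-trips to full float64 precision
    fm.to_dataframe().to_csv(path, index=False)


def read_feature_table(path) -> FeatureMatrix:
    df = pd.read_csv(path, float_precision="round_trip")
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"feature table {path} lacks sample_id/label columns")
    columns = [c for c in df.columns if c not in ("sample_id", "label")]
    prefixes = {"glcm": "GLCM", "sv": "SV", "lbp": "LBP", "rgb": "RGB", "hsv": "HSV", "lab": "LAB"}
    blocks = tuple(
        b for b in BLOCK_ORDER
        if any(prefixes.get(c.split("_", 1)[0]) == b for c in columns)
    )
    return FeatureMatrix(
        sample_ids=[str(s) for s in df["sample_id"]],
        labels=df["label"].to_numpy(),
        values=df[columns].to_numpy(dtype=np.float64),
        columns=columns,
        blocks=blocks,
    )
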