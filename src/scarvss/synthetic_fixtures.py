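"""Synthetic class-structured colored textures emulating the study design.

The original scar photograph archive is not redistributable, so this
module synthesizes a dataset with the same label structure: 24 parent
images over the 8 observed VSS totals {0, 1, 2, 4, 5, 7, 8, 9} with
parent counts (3, 9, 2, 1, 1, 5, 1, 2), which subdivide 3 x 3 into the
216 sub-image samples with per-class counts (27, 81, 18, 9, 9, 45, 9, 18).

Each class is a stationary colored random field:

    pixel = base_rgb
          + amplitude * T            (T: unit-variance smoothed noise,
                                      shared across channels)
          + per-channel white noise  (sd = noise_sd)

T is Gaussian white noise smoothed with a Gaussian kernel of width
``texture_scale`` pixels and rescaled to unit variance, so ``amplitude``
is the texture contrast in intensity units and ``texture_scale`` the
spatial correlation length.  Classes differ in two orthogonal ways —
mean color and correlation length — so color-only and texture-only
feature combinations are each informative on their own.  Pixels are
clipped (not wrapped) to [0, 255].

All randomness flows through one seeded generator per call; the same seed
reproduces bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .dataset_io import ScarRecord, write_manifest


@dataclass(frozen=True)
class SyntheticClassSpec:
    label: int
    base_rgb: tuple[float, float, float]
    texture_scale: float
    amplitude: float
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.texture_scale < 0:
            raise ValueError("texture_scale must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Default class specs: widely separated base colors spanning the gamut of
#: scar appearance (pale normal skin through red/purple hypertrophic), with
#: distinct spatial correlation lengths.
DEFAULT_CLASS_SPECS: dict[int, SyntheticClassSpec] = {
    0: SyntheticClassSpec(0, (225.0, 200.0, 185.0), 0.0, 20.0),
    1: SyntheticClassSpec(1, (150.0, 95.0, 80.0), 0.5, 24.0),
    2: SyntheticClassSpec(2, (200.0, 145.0, 120.0), 1.0, 28.0),
    4: SyntheticClassSpec(4, (120.0, 65.0, 60.0), 1.5, 31.0),
    5: SyntheticClassSpec(5, (140.0, 100.0, 160.0), 2.0, 34.0),
    7: SyntheticClassSpec(7, (170.0, 55.0, 80.0), 2.5, 37.0),
    8: SyntheticClassSpec(8, (80.0, 45.0, 50.0), 3.0, 40.0),
    9: SyntheticClassSpec(9, (230.0, 125.0, 155.0), 3.5, 43.0),
}

#: Parent-image counts per VSS total, as in the study.
DEFAULT_CLASS_COUNTS: dict[int, int] = {0: 3, 1: 9, 2: 2, 4: 1, 5: 1, 7: 5, 8: 1, 9: 2}

#: A fixed consistent decomposition of each total into
#: (pigmentation, vascularity, pliability, height) subscores.
SUBSCORE_DECOMPOSITION: dict[int, tuple[int, int, int, int]] = {
    0: (0, 0, 0, 0),
    1: (1, 0, 0, 0),
    2: (1, 1, 0, 0),
    4: (1, 1, 1, 1),
    5: (1, 1, 2, 1),
    7: (2, 2, 2, 1),
    8: (2, 2, 2, 2),
    9: (2, 3, 2, 2),
}

#: Default parent image size: 150 x 150, so 3 x 3 tiles are 50 x 50 —
#: comfortably above the 11-pixel extent a 10-lag semivariogram needs, and
#: enough interior pixels (48 x 48) for stable 256-bin LBP histograms.
DEFAULT_SIZE = (150, 150)


def generate_class_image(
    spec: SyntheticClassSpec, size: tuple[int, int], seed
) -> np.ndarray:
    """One synthetic RGB image drawn from a class's colored-texture model."""
    H, W = size
    if H < 33 or W < 33:
        raise ValueError(f"size {size} too small; need at least 33 x 33")
    rng = np.random.default_rng(seed)
    texture = rng.standard_normal((H, W))
    if spec.texture_scale > 0:
        texture = gaussian_filter(texture, sigma=spec.texture_scale, mode="reflect")
    sd = texture.std()
    if sd > 0:
        texture = texture / sd
    img = np.asarray(spec.base_rgb, dtype=np.float64)[None, None, :]
    img = img + spec.amplitude * texture[:, :, None]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(H, W, 3))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _scaled_specs(
    specs: dict[int, SyntheticClassSpec], separation: float
) -> dict[int, SyntheticClassSpec]:
    """Shrink between-class differences toward the pooled mean.

    ``separation=1`` keeps the defaults; 0 collapses every class onto the
    same color and correlation length (pure chance-level problem).
    """
    base = np.array([s.base_rgb for s in specs.values()])
    center_rgb = base.mean(axis=0)
    center_scale = float(np.mean([s.texture_scale for s in specs.values()]))
    out = {}
    for label, s in specs.items():
        rgb = center_rgb + separation * (np.asarray(s.base_rgb) - center_rgb)
        scale = center_scale + separation * (s.texture_scale - center_scale)
        out[label] = replace(s, base_rgb=tuple(rgb), texture_scale=max(0.0, scale))
    return out


def generate_study_dataset(
    seed,
    *,
    size: tuple[int, int] = DEFAULT_SIZE,
    class_specs: dict[int, SyntheticClassSpec] | None = None,
    class_counts: dict[int, int] | None = None,
    separation: float = 1.0,
) -> tuple[list[np.ndarray], list[ScarRecord]]:
    """The full synthetic study: parent images plus their manifest records.

    Returns 24 parent images by default, with exactly the study's class
    counts; subdividing each 3 x 3 yields the 216 labeled samples.
    """
    specs = dict(class_specs or DEFAULT_CLASS_SPECS)
    counts = dict(class_counts or DEFAULT_CLASS_COUNTS)
    if separation != 1.0:
        specs = _scaled_specs(specs, separation)
    seed_seq = np.random.SeedSequence(seed)
    images: list[np.ndarray] = []
    records: list[ScarRecord] = []
    serial = 0
    for label in sorted(counts):
        spec = specs[label]
        pig, vasc, pli, height = SUBSCORE_DECOMPOSITION[label]
        for k in range(counts[label]):
            child = seed_seq.spawn(1)[0]
            image_id = f"scar_vss{label}_{k:02d}"
            images.append(generate_class_image(spec, size, child))
            records.append(
                ScarRecord(
                    image_id=image_id,
                    path=f"{image_id}.png",
                    pigmentation=pig,
                    vascularity=vasc,
                    pliability=pli,
                    height_score=height,
                    patient_id=f"synthetic_{serial:02d}",
                    site="synthetic",
                )
            )
            serial += 1
    return images, records


def write_dataset(
    images: list[np.ndarray], records: list[ScarRecord], outdir
) -> Path:
    """Write PNGs plus a ``manifest.csv`` compatible with dataset_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for img, rec in zip(images, records):
        Image.fromarray(img, mode="RGB").save(outdir / rec.path)
    manifest = outdir / "manifest.csv"
    write_manifest(records, manifest)
    return manifest
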