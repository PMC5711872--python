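"""Image and manifest I/O for scar patch datasets.

Images are plain :class:`numpy.ndarray` rasters: an RGB image is an
``H x W x 3`` array of ``uint8`` and a grayscale image is ``H x W`` of
``uint8``.  Each cropped scar photograph is divided into a 3 x 3 grid of
equal-sized sub-images that serve as the classification samples, and a CSV
manifest assigns every photograph its Vancouver Scar Scale (VSS) subscores.

Conventions used throughout the package: coordinates are (row, column),
0-based, origin at the top-left corner, traversal row-major.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

log = logging.getLogger(__name__)

#: VSS subscale upper bounds (all lower bounds are 0): pigmentation 0-2,
#: vascularity 0-3, pliability 0-5, height 0-3; maximum total 13.
SUBSCORE_MAX = {
    "pigmentation": 2,
    "vascularity": 3,
    "pliability": 5,
    "height_score": 3,
}
VSS_MAX_TOTAL = sum(SUBSCORE_MAX.values())

MANIFEST_COLUMNS = (
    "image_id",
    "path",
    "pigmentation",
    "vascularity",
    "pliability",
    "height",
    "patient_id",
    "site",
)


@dataclass(frozen=True)
class ScarRecord:
    """One scar photograph with its VSS subscores.

    The total score is always recomputed from the four subscores; a stored
    total in a manifest is cross-checked against the sum, never trusted.
    """

    image_id: str
    path: str
    pigmentation: int
    vascularity: int
    pliability: int
    height_score: int
    patient_id: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        for name, hi in SUBSCORE_MAX.items():
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)):
                raise ValueError(
                    f"record {self.image_id!r}: {name} must be an integer, got {value!r}"
                )
            if not 0 <= value <= hi:
                raise ValueError(
                    f"record {self.image_id!r}: {name}={value} outside [0, {hi}]"
                )

    @property
    def vss_total(self) -> int:
        return (
            self.pigmentation + self.vascularity + self.pliability + self.height_score
        )


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image smaller than 3 x 3: shape {img.shape[:2]}")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("RGB values outside [0, 255]")
        img = img.astype(np.uint8)
    return img


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file as an 8-bit RGB array.

    Grayscale sources are replicated across the three channels; 16-bit
    sources are rescaled to 0-255 by integer division of the full range
    (``value // 257``).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.uint32)
                arr = (arr // 257).astype(np.uint8)
                arr = np.stack([arr] * 3, axis=-1)
            else:
                arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, UnidentifiedImageError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    return _validate_rgb(arr)


#: ITU-R BT.601 luma weights for R, G, B.
_LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale using BT.601 luma weights.

    gray = round(0.2989 R + 0.5870 G + 0.1140 B), rounding half away from
    zero, clipped to [0, 255].
    """
    img = _validate_rgb(img)
    wr, wg, wb = _LUMA_WEIGHTS
    luma = wr * img[..., 0] + wg * img[..., 1] + wb * img[..., 2]
    # values are non-negative, so floor(x + 0.5) is round-half-away-from-zero
    gray = np.floor(luma + 0.5)
    return np.clip(gray, 0, 255).astype(np.uint8)


def subdivide(img: np.ndarray, rows: int = 3, cols: int = 3) -> list[np.ndarray]:
    """Divide an image into a ``rows x cols`` grid of equal-sized tiles.

    Tile size is ``floor(H/rows) x floor(W/cols)``; trailing remainder rows
    and columns at the bottom/right are discarded so every tile has the same
    shape.  Tiles are returned in row-major order.
    """
    img = np.asarray(img)
    H, W = img.shape[:2]
    if H < rows or W < cols:
        raise ValueError(f"image of shape {(H, W)} smaller than {rows} x {cols} grid")
    th, tw = H // rows, W // cols
    tiles = []
    for r in range(rows):
        for c in range(cols):
            tiles.append(img[r * th : (r + 1) * th, c * tw : (c + 1) * tw].copy())
    return tiles


def _parse_score(text: str, column: str, row_num: int) -> int:
    try:
        return int(text)
    except (TypeError, ValueError):
        raise ValueError(
            f"manifest row {row_num}: column {column!r} is not an integer: {text!r}"
        ) from None


def load_manifest(path: str | Path) -> list[ScarRecord]:
    """Read a CSV manifest of scar records.

    Required header columns: ``image_id, path, pigmentation, vascularity,
    pliability, height, patient_id, site``.  An optional ``vss_total`` column
    is cross-checked against the subscore sum.  Unknown extra columns are
    ignored with a warning.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"manifest {path}: empty file")
        missing = [c for c in MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"manifest {path}: missing columns {missing}")
        extra = [
            c
            for c in reader.fieldnames
            if c not in MANIFEST_COLUMNS and c != "vss_total"
        ]
        if extra:
            log.warning("manifest %s: ignoring unknown columns %s", path, extra)

        records: list[ScarRecord] = []
        seen: set[str] = set()
        for row_num, row in enumerate(reader, start=2):
            image_id = (row["image_id"] or "").strip()
            if not image_id:
                raise ValueError(f"manifest row {row_num}: empty image_id")
            if image_id in seen:
                raise ValueError(f"manifest row {row_num}: duplicate image_id {image_id!r}")
            seen.add(image_id)
            try:
                rec = ScarRecord(
                    image_id=image_id,
                    path=(row["path"] or "").strip(),
                    pigmentation=_parse_score(row["pigmentation"], "pigmentation", row_num),
                    vascularity=_parse_score(row["vascularity"], "vascularity", row_num),
                    pliability=_parse_score(row["pliability"], "pliability", row_num),
                    height_score=_parse_score(row["height"], "height", row_num),
                    patient_id=(row["patient_id"] or "").strip(),
                    site=(row["site"] or "").strip(),
                )
            except ValueError as exc:
                raise ValueError(f"manifest row {row_num}: {exc}") from None
            stored_total = (row.get("vss_total") or "").strip()
            if stored_total:
                total = _parse_score(stored_total, "vss_total", row_num)
                if total != rec.vss_total:
                    raise ValueError(
                        f"manifest row {row_num}: stored vss_total {total} does not "
                        f"match subscore sum {rec.vss_total}"
                    )
            records.append(rec)
    return records


def write_manifest(records: list[ScarRecord], path: str | Path) -> None:
    """Write records to a CSV manifest (including the derived vss_total)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(MANIFEST_COLUMNS) + ["vss_total"])
        for rec in records:
            writer.writerow(
                [
                    rec.image_id,
                    rec.path,
                    rec.pigmentation,
                    rec.vascularity,
                    rec.pliability,
                    rec.height_score,
                    rec.patient_id,
                    rec.site,
                    rec.vss_total,
                ]
            )
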