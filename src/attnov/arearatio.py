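"""Area-ratio attention proxy from object masks or bounding boxes.

The area ratio of an image is the fraction of pixels occupied by the target
object; it proxies attention deployment (a large ratio = the object fills the
frame = focused attention, a small ratio = much surrounding context =
divided attention).  Segmentation itself is external to this package: inputs
are binary masks (8-bit PNG, pixel > 127 counts as object) or detector
bounding boxes (CSV).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

from .exceptions import DomainError

__all__ = [
    "MaskAnnotation",
    "area_ratio_from_mask",
    "area_ratio_from_box",
    "validate_against_manual",
    "read_mask_png",
    "write_mask_png",
    "read_boxes_csv",
    "score_masks",
]

_OBJECT_THRESHOLD = 127  # 8-bit PNG pixels above this count as object


@dataclass
class MaskAnnotation:
    """A binary pixel mask or bounding box for one image.

    Exactly one of ``mask`` (boolean array of shape (height, width)) and
    ``box`` ((x, y, w, h), 0-based, origin top-left) should be provided.
    """

    image_id: str
    width: int
    height: int
    mask: np.ndarray | None = None
    box: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise DomainError(f"image {self.image_id!r} has empty dimensions")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != (self.height, self.width):
                raise DomainError(
                    f"mask shape {self.mask.shape} does not match image "
                    f"dimensions ({self.height}, {self.width})"
                )
        if self.box is not None:
            x, y, w, h = self.box
            if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
                raise DomainError(f"box {self.box} exceeds image bounds")


def area_ratio_from_mask(annotation: MaskAnnotation) -> float:
    """Object-pixel fraction of the image, in [0, 1]."""
    if annotation.mask is None:
        raise DomainError(f"annotation {annotation.image_id!r} carries no mask")
    n_pixels = annotation.width * annotation.height
    return float(np.count_nonzero(annotation.mask)) / n_pixels


def area_ratio_from_box(annotation: MaskAnnotation) -> float:
    """Bounding-box area fraction of the image, in (0, 1]."""
    if annotation.box is None:
        raise DomainError(f"annotation {annotation.image_id!r} carries no box")
    _, _, w, h = annotation.box
    if w <= 0 or h <= 0:
        raise DomainError(f"degenerate box of size {w}x{h}")
    return (w * h) / (annotation.width * annotation.height)


def area_ratio(annotation: MaskAnnotation) -> float:
    """Dispatch on whichever variant the annotation carries (mask preferred)."""
    if annotation.mask is not None:
        return area_ratio_from_mask(annotation)
    return area_ratio_from_box(annotation)


def validate_against_manual(
    auto: Sequence[tuple[str, float]] | pd.DataFrame,
    manual: Sequence[tuple[str, float]] | pd.DataFrame,
) -> dict:
    """Pearson correlation between automatic and manual area ratios.

    Ratios are matched on id; at least 3 matched ids are required.  Returns
    ``{"pearson_r": ..., "p_value": ..., "n": ...}``.
    """

    def _as_map(values):
        if isinstance(values, pd.DataFrame):
            return dict(zip(values.iloc[:, 0].astype(str), values.iloc[:, 1]))
        return {str(i): float(r) for i, r in values}

    auto_map, manual_map = _as_map(auto), _as_map(manual)
    common = sorted(set(auto_map) & set(manual_map))
    if len(common) < 3:
        raise DomainError(
            f"need at least 3 matched ids to correlate, got {len(common)}"
        )
    a = np.array([auto_map[i] for i in common])
    m = np.array([manual_map[i] for i in common])
    r, p = stats.pearsonr(a, m)
    return {"pearson_r": float(r), "p_value": float(p), "n": len(common)}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_mask_png(path: str | Path, image_id: str | None = None) -> MaskAnnotation:
    """Read an 8-bit grayscale PNG mask (pixel > 127 = object)."""
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("L"))
    return MaskAnnotation(
        image_id=image_id or path.stem,
        width=arr.shape[1],
        height=arr.shape[0],
        mask=arr > _OBJECT_THRESHOLD,
    )


def write_mask_png(annotation: MaskAnnotation, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (0 background, 255 object)."""
    if annotation.mask is None:
        raise DomainError("only mask annotations can be written as PNG")
    Image.fromarray(annotation.mask.astype(np.uint8) * 255, mode="L").save(path)


def read_boxes_csv(path: str | Path) -> list[MaskAnnotation]:
    """Read box annotations from CSV (image_id,x,y,w,h,width,height)."""
    table = pd.read_csv(path)
    return [
        MaskAnnotation(
            image_id=str(row.image_id),
            width=int(row.width),
            height=int(row.height),
            box=(int(row.x), int(row.y), int(row.w), int(row.h)),
        )
        for row in table.itertuples()
    ]


def score_masks(annotations: Sequence[MaskAnnotation]) -> pd.DataFrame:
    """Area ratio for each annotation; (image_id, area_ratio) frame."""
    rows = [
        {"image_id": a.image_id, "area_ratio": area_ratio(a)} for a in annotations
    ]
    return pd.DataFrame(rows, columns=["image_id", "area_ratio"])
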