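"""Silhouette image and manifest input.

A study is described by a CSV *manifest* with one row per photographed
statolith face and six columns::

    specimen_id,species,family,face,image_path,um_per_px

Images are binary-style silhouettes (by convention a dark statolith on a
white background, the usual presentation for transmitted-light hard-part
photography) in TIFF, PNG or JPEG.  Physical scale comes from the manifest's
``um_per_px`` column rather than from scale-bar detection: scale cancels in
every size-invariant quantity downstream (L:W ratios, normalized Fourier
coefficients), so automated bar detection would add fragility without
affecting any result.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .exceptions import (
    BorderContactError,
    EmptySilhouetteError,
    ManifestFormatError,
    ManifestValidationError,
)

#: The three orthogonal statolith viewing orientations, in canonical order.
#: Proximal = cleavage plane vertical, oral = cleavage down, lateral =
#: cleavage horizontal.
FACES = ("proximal", "oral", "lateral")

MANIFEST_COLUMNS = (
    "specimen_id",
    "species",
    "family",
    "face",
    "image_path",
    "um_per_px",
)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one silhouette image (one face of one specimen)."""

    specimen_id: str
    species: str
    family: str
    face: str
    image_path: str
    um_per_px: float

    def __post_init__(self) -> None:
        if self.face not in FACES:
            raise ManifestValidationError(
                f"unknown face {self.face!r}; expected one of {FACES}"
            )
        if not (self.um_per_px > 0):
            raise ManifestValidationError(
                f"um_per_px must be positive, got {self.um_per_px!r} "
                f"for specimen {self.specimen_id!r}"
            )


@dataclass
class SilhouetteMask:
    """Binary foreground mask with physical scale.

    ``pixels`` is a 2-D boolean array in image (row, col) order, True on the
    statolith.  Guaranteed by :func:`load_silhouette`: exactly one
    8-connected foreground component, interior holes filled, no foreground
    pixel on the image border.
    """

    pixels: np.ndarray
    um_per_px: float
    meta: SampleMeta


def read_manifest(path: str | os.PathLike) -> list[SampleMeta]:
    """Read and validate a sample manifest.

    Raises
    ------
    ManifestFormatError
        If the file cannot be parsed or a required column is missing.
    ManifestValidationError
        On duplicate (specimen_id, face) pairs, unknown face tokens,
        non-positive scales, or a species listed under two families.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ManifestFormatError(f"cannot read manifest {path}: {exc}") from exc

    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(
            f"manifest {path} is missing required columns: {missing}"
        )

    dup = df.duplicated(subset=["specimen_id", "face"])
    if dup.any():
        pairs = df.loc[dup, ["specimen_id", "face"]].to_records(index=False)
        raise ManifestValidationError(
            f"duplicate (specimen_id, face) pairs in manifest: {list(pairs)[:5]}"
        )

    fam_per_species = df.groupby("species")["family"].nunique()
    bad = fam_per_species[fam_per_species > 1]
    if len(bad):
        raise ManifestValidationError(
            f"species mapped to more than one family: {list(bad.index)}"
        )

    records = []
    for row in df.itertuples(index=False):
        try:
            scale = float(row.um_per_px)
        except (TypeError, ValueError) as exc:
            raise ManifestValidationError(
                f"non-numeric um_per_px {row.um_per_px!r} for "
                f"specimen {row.specimen_id!r}"
            ) from exc
        records.append(
            SampleMeta(
                specimen_id=str(row.specimen_id),
                species=str(row.species),
                family=str(row.family),
                face=str(row.face),
                image_path=str(row.image_path),
                um_per_px=scale,
            )
        )
    return records


def _to_grayscale(img: Image.Image) -> np.ndarray:
    """Image -> float array in [0, 1]; RGB converted to luminance."""
    if img.mode not in ("L", "I;16", "F"):
        img = img.convert("L")
    arr = np.asarray(img, dtype=np.float64)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255.0 else 255.0)
    return arr


def mask_from_gray(
    gray: np.ndarray,
    meta: SampleMeta,
    threshold: float = 0.5,
    polarity: str = "dark_foreground",
) -> SilhouetteMask:
    """Binarize a grayscale array and clean it into a silhouette mask.

    Keeps the largest 8-connected foreground component and fills interior
    holes — the programmatic analogue of manually erasing membrane fragments
    and dust from a silhouette photograph.
    """
    if polarity == "dark_foreground":
        fg = gray < threshold
    elif polarity == "light_foreground":
        fg = gray > threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    if not fg.any():
        raise EmptySilhouetteError(
            f"no foreground pixels in {meta.image_path!r} at threshold {threshold}"
        )

    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = labels == int(np.argmax(sizes))
    fg = ndimage.binary_fill_holes(fg)

    if fg[0, :].any() or fg[-1, :].any() or fg[:, 0].any() or fg[:, -1].any():
        raise BorderContactError(
            f"silhouette touches the image border in {meta.image_path!r}; "
            "the outline would be clipped"
        )
    return SilhouetteMask(pixels=fg, um_per_px=meta.um_per_px, meta=meta)


def load_silhouette(
    meta: SampleMeta,
    threshold: float = 0.5,
    polarity: str = "dark_foreground",
) -> SilhouetteMask:
    """Load one silhouette image and return its cleaned binary mask.

    Parameters
    ----------
    meta
        Manifest record; ``meta.image_path`` must be readable.
    threshold
        Binarization threshold as a fraction of full intensity range.
        Inputs are near-binary silhouettes, so a fixed threshold is used
        rather than an adaptive one.
    polarity
        ``"dark_foreground"`` (the silhouette convention) or
        ``"light_foreground"``.
    """
    with Image.open(meta.image_path) as img:
        gray = _to_grayscale(img)
    return mask_from_gray(gray, meta, threshold=threshold, polarity=polarity)
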