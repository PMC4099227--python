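"""Raster image IO, ROI geometry, and manifest handling.

Radiographs digitized to 12-bit gray scale are carried in 16-bit
single-channel containers (TIFF or PNG).  An :class:`ImageGrid` keeps the
pixel array together with its declared bit depth; ROIs are axis-aligned
rectangles in 0-based, half-open pixel coordinates (row-major: y = row,
x = column).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "ImageGrid",
    "ROISpec",
    "ROIRecord",
    "Group",
    "BoneClass",
    "ImageReadError",
    "MissingImageError",
    "MultiChannelImageError",
    "UnsupportedFormatError",
    "ROIBoundsError",
    "ManifestError",
    "read_image",
    "write_image",
    "extract_roi",
    "load_roi_manifest",
    "MANIFEST_COLUMNS",
]


class ImageReadError(Exception):
    """Base class for image input failures."""


class MissingImageError(ImageReadError):
    """The image file does not exist."""


class MultiChannelImageError(ImageReadError):
    """The image is not single-channel grayscale."""


class UnsupportedFormatError(ImageReadError):
    """The file extension is not a supported raster format."""


class ROIBoundsError(ValueError):
    """A ROI rectangle extends past an image edge."""


class ManifestError(ValueError):
    """A ROI manifest is malformed."""


class Group(str, enum.Enum):
    """Pathology group: multiple myeloma or osteolytic metastasis."""

    MM = "MM"
    OL = "OL"


class BoneClass(str, enum.Enum):
    """Histological/anatomical bone stratification."""

    FLAT = "flat"
    NONFLAT = "nonflat"


@dataclass(frozen=True)
class ImageGrid:
    """A 2D grid of non-negative integer gray levels.

    Parameters
    ----------
    pixels
        2D integer array, values in ``[0, 2**bit_depth - 1]``.
    bit_depth
        Declared dynamic range of the gray levels (default 12, i.e. 0-4095).
    """

    pixels: np.ndarray
    bit_depth: int = 12

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("pixels must be an integer array")
        vmax = (1 << self.bit_depth) - 1
        if arr.min() < 0 or arr.max() > vmax:
            raise ValueError(
                f"pixel values must lie in [0, {vmax}] for bit_depth={self.bit_depth}"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def max_value(self) -> int:
        """Largest representable gray level (4095 at 12 bits)."""
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class ROISpec:
    """Rectangle ``[x0, x0+width) x [y0, y0+height)`` in pixel coordinates."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI offsets must be non-negative")


@dataclass(frozen=True)
class ROIRecord:
    """One manifest row: a single ROI drawn on one radiograph."""

    image_path: str
    roi: ROISpec
    group: Group
    bone_class: BoneClass
    case_id: str


MANIFEST_COLUMNS = (
    "image_path",
    "x0",
    "y0",
    "width",
    "height",
    "group",
    "bone_class",
    "case_id",
)

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}


def read_image(path: str | Path) -> ImageGrid:
    """Read a single-channel grayscale TIFF or PNG.

    The bit depth is inferred from the container: a 16-bit container whose
    values all fit in 12 bits is declared ``bit_depth=12`` (the native range
    of the digitized radiographs), otherwise 16; 8-bit containers keep
    ``bit_depth=8``.

    Raises
    ------
    MissingImageError, UnsupportedFormatError, MultiChannelImageError
    """
    p = Path(path)
    if not p.exists():
        raise MissingImageError(f"image file not found: {p}")
    suffix = p.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(p)
    elif suffix in _PNG_SUFFIXES:
        with Image.open(p) as im:
            if im.mode in ("RGB", "RGBA", "P", "LA"):
                raise MultiChannelImageError(
                    f"expected single-channel grayscale, got mode {im.mode!r}: {p}"
                )
            arr = np.asarray(im)
    else:
        raise UnsupportedFormatError(
            f"unsupported image format {suffix!r} (use .tif/.tiff/.png): {p}"
        )
    if arr.ndim != 2:
        raise MultiChannelImageError(
            f"expected a 2D single-channel image, got shape {arr.shape}: {p}"
        )
    arr = arr.astype(np.int64, copy=False)
    if _container_bits(p, suffix) == 8:
        depth = 8
    elif arr.max(initial=0) <= 4095:
        depth = 12
    else:
        depth = 16
    return ImageGrid(pixels=arr.astype(np.uint16), bit_depth=depth)


def _container_bits(p: Path, suffix: str) -> int:
    if suffix in _TIFF_SUFFIXES:
        with tifffile.TiffFile(p) as tf:
            return int(tf.pages[0].bitspersample)
    with Image.open(p) as im:
        return 16 if im.mode.startswith("I") else 8


def write_image(image: ImageGrid, path: str | Path) -> None:
    """Write losslessly to a 16-bit (or 8-bit) single-channel container.

    Values are stored unscaled, so a 12-bit image round-trips bit-exactly
    through a 16-bit container.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    arr = image.pixels
    dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
    arr = arr.astype(dtype)
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(p, arr, photometric="minisblack")
    elif suffix in _PNG_SUFFIXES:
        Image.fromarray(arr).save(p)  # uint8 -> 'L', uint16 -> 'I;16'
    else:
        raise UnsupportedFormatError(
            f"unsupported image format {suffix!r} (use .tif/.tiff/.png): {p}"
        )


def extract_roi(image: ImageGrid, roi: ROISpec) -> ImageGrid:
    """Extract the ROI sub-grid; output pixel (r, c) is input (y0+r, x0+c).

    Raises :class:`ROIBoundsError` naming the offending edge if the
    rectangle is not fully inside the image.
    """
    if roi.x0 + roi.width > image.width:
        raise ROIBoundsError(
            f"ROI exceeds right edge: x0+width={roi.x0 + roi.width} > image width {image.width}"
        )
    if roi.y0 + roi.height > image.height:
        raise ROIBoundsError(
            f"ROI exceeds bottom edge: y0+height={roi.y0 + roi.height} > image height {image.height}"
        )
    sub = image.pixels[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return ImageGrid(pixels=sub.copy(), bit_depth=image.bit_depth)


def load_roi_manifest(path: str | Path) -> list[ROIRecord]:
    """Load a ROI manifest CSV (one record per radiograph).

    Header must be exactly ``image_path,x0,y0,width,height,group,bone_class,
    case_id``.  Group and bone-class labels are validated; malformed rows
    raise :class:`ManifestError` naming the row number (1 = first data row).
    """
    p = Path(path)
    with open(p, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestError(f"empty manifest: {p}") from None
        if tuple(h.strip() for h in header) != MANIFEST_COLUMNS:
            raise ManifestError(
                f"bad manifest header {header!r}; expected {','.join(MANIFEST_COLUMNS)}"
            )
        records: list[ROIRecord] = []
        for i, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(MANIFEST_COLUMNS):
                raise ManifestError(f"row {i}: expected {len(MANIFEST_COLUMNS)} fields, got {len(row)}")
            image_path, x0, y0, w, h, group, bone, case_id = (c.strip() for c in row)
            try:
                roi = ROISpec(x0=int(x0), y0=int(y0), width=int(w), height=int(h))
            except ValueError as exc:
                raise ManifestError(f"row {i}: invalid ROI geometry: {exc}") from None
            try:
                g = Group(group)
            except ValueError:
                raise ManifestError(f"row {i}: unknown group label {group!r}") from None
            try:
                b = BoneClass(bone)
            except ValueError:
                raise ManifestError(f"row {i}: unknown bone_class label {bone!r}") from None
            records.append(ROIRecord(image_path=image_path, roi=roi, group=g, bone_class=b, case_id=case_id))
    return records


def write_roi_manifest(records: Sequence[ROIRecord], path: str | Path) -> None:
    """Write records back to manifest CSV (inverse of :func:`load_roi_manifest`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in records:
            writer.writerow(
                [r.image_path, r.roi.x0, r.roi.y0, r.roi.width, r.roi.height,
                 r.group.value, r.bone_class.value, r.case_id]
            )
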