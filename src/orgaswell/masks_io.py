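"""Image and instance-mask I/O plus per-organoid measurements.

Conventions used throughout the package:

* images are 2-D grayscale arrays; colour inputs are collapsed to the
  unweighted channel mean (bright-field channels are near-identical, so
  no luma weighting is applied);
* instance label masks are integer images in which ``0`` is background
  and every positive value identifies one organoid; labels need not be
  contiguous integers;
* coordinates are 0-based ``(row, col)``; bounding boxes are half-open
  ``[min, max)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage import measure

logger = logging.getLogger("orgaswell")

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}
_MASK_SUFFIXES = {".tif", ".tiff", ".png"}

__all__ = [
    "GrayImage",
    "LabelMask",
    "Instance",
    "InstanceSet",
    "read_image",
    "write_image",
    "read_label_mask",
    "write_label_mask",
    "extract_instances",
    "write_features_table",
    "read_features_table",
    "FormatError",
    "DimensionError",
    "ValidityError",
    "PairingError",
]


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


class DimensionError(ValueError):
    """Zero-sized or otherwise degenerate image dimensions."""


class ValidityError(ValueError):
    """Mask content violates the label-mask contract."""


class PairingError(ValueError):
    """Image and mask (or two masks) do not belong together."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with its source bit depth.

    Parameters
    ----------
    pixels
        2-D float array of intensities (arbitrary units, finite,
        non-negative).
    bit_depth
        8 or 16; the bit depth of the file of origin (or the depth a
        synthetic image is meant to be written at).
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"image must be 2-D and non-empty, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("image intensities must be finite and non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabelMask:
    """Instance label image: 0 = background, positive ints = organoids."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise DimensionError(f"label mask must be 2-D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValidityError(f"label mask must be integer-valued, got dtype {lab.dtype}")
        if lab.size and lab.min() < 0:
            raise ValidityError("label mask contains negative values")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        """Sorted array of distinct positive labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def n_instances(self) -> int:
        return int(self.label_ids().size)


@dataclass(frozen=True)
class Instance:
    """Measurements of one organoid instance.

    ``area`` is the exact pixel count; ``centroid`` is the pixel-coordinate
    mean ``(row, col)``; ``bbox`` is half-open
    ``(row_min, col_min, row_max, col_max)``.
    """

    label_id: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValidityError(f"label_id must be positive, got {self.label_id}")
        if self.area < 1:
            raise ValidityError(f"area must be >= 1 px, got {self.area}")
        r, c = self.centroid
        r0, c0, r1, c1 = self.bbox
        if not (r0 <= r < r1 and c0 <= c < c1):
            raise ValidityError(f"centroid {self.centroid} outside bbox {self.bbox}")


@dataclass
class InstanceSet:
    """All instances measured from one label mask at one timepoint."""

    instances: list[Instance]
    source_image_id: str = ""
    timepoint: float = 0.0  # hours

    def __post_init__(self) -> None:
        ids = [i.label_id for i in self.instances]
        if len(ids) != len(set(ids)):
            raise ValidityError("duplicate label_ids within an InstanceSet")

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def by_label(self) -> dict[int, Instance]:
        return {i.label_id: i for i in self.instances}

    def areas(self) -> dict[int, int]:
        return {i.label_id: i.area for i in self.instances}


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def _infer_bit_depth(arr: np.ndarray) -> int:
    return 16 if arr.dtype.itemsize >= 2 else 8


def read_image(path: str | Path) -> GrayImage:
    """Read a TIFF/PNG/JPEG image as grayscale.

    Colour images are converted by the unweighted channel mean. JPEG is
    accepted (the assay workflow exports JPEG) but lossy compression can
    perturb downstream segmentation, so a warning is logged. Pixel values
    of single-channel inputs are passed through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported image format {path.suffix!r}: {path}")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        logger.warning("reading lossy JPEG %s; compression may perturb segmentation", path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - reraise with the offending path
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0 or arr.ndim not in (2, 3):
        raise DimensionError(f"image {path} has unusable shape {arr.shape}")
    depth = _infer_bit_depth(arr)
    if arr.ndim == 3:
        # drop alpha if present, then unweighted channel mean
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64).mean(axis=2)
    return GrayImage(pixels=arr.astype(np.float64), bit_depth=depth)


def write_image(image: GrayImage, path: str | Path) -> Path:
    """Write a grayscale image as 8- or 16-bit TIFF/PNG (per its bit depth)."""
    path = Path(path)
    lim = 255 if image.bit_depth == 8 else 65535
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = np.clip(np.rint(image.pixels), 0, lim).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    return path


def read_label_mask(path: str | Path, *, image: GrayImage | None = None) -> LabelMask:
    """Read an instance label mask from a single-channel TIFF or PNG.

    Float-valued files are rejected: a mask must be integer-labelled.
    If ``image`` is supplied the shapes are cross-checked.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mask file: {path}")
    if path.suffix.lower() not in _MASK_SUFFIXES:
        raise FormatError(f"label masks must be TIFF or PNG, got {path.suffix!r}: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValidityError(f"mask {path} must be single-channel, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidityError(f"mask {path} is float-valued ({arr.dtype}); labels must be integers")
    mask = LabelMask(labels=arr.astype(np.int64))
    if image is not None and mask.shape != image.shape:
        raise PairingError(
            f"mask {path} shape {mask.shape} does not match image shape {image.shape}"
        )
    return mask


def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as 16-bit TIFF (labels above 65535 are rejected)."""
    path = Path(path)
    if mask.labels.size and mask.labels.max() > 65535:
        raise ValidityError(
            f"label {int(mask.labels.max())} exceeds the 16-bit limit 65535; "
            "relabel before writing"
        )
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def extract_instances(
    mask: LabelMask, timepoint: float = 0.0, source_image_id: str = ""
) -> InstanceSet:
    """Measure area, centroid and bounding box for each labelled organoid.

    Area is the exact pixel count of the label. An empty mask yields an
    empty set.
    """
    instances: list[Instance] = []
    for rp in measure.regionprops(mask.labels):
        r0, c0, r1, c1 = rp.bbox
        instances.append(
            Instance(
                label_id=int(rp.label),
                area=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=(int(r0), int(c0), int(r1), int(c1)),
            )
        )
    instances.sort(key=lambda i: i.label_id)
    return InstanceSet(instances=instances, source_image_id=source_image_id, timepoint=timepoint)


_FEATURE_COLUMNS = [
    "image_id",
    "timepoint_h",
    "label_id",
    "area_px2",
    "centroid_row",
    "centroid_col",
]


def write_features_table(instances: InstanceSet, path: str | Path) -> Path:
    """Write per-instance features as CSV, rows sorted by label_id.

    Floats are formatted to 6 significant digits so identical inputs
    produce byte-identical files.
    """
    path = Path(path)
    rows = []
    for inst in sorted(instances.instances, key=lambda i: i.label_id):
        rows.append(
            {
                "image_id": instances.source_image_id,
                "timepoint_h": f"{instances.timepoint:.6g}",
                "label_id": inst.label_id,
                "area_px2": inst.area,
                "centroid_row": f"{inst.centroid[0]:.6g}",
                "centroid_col": f"{inst.centroid[1]:.6g}",
            }
        )
    df = pd.DataFrame(rows, columns=_FEATURE_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_features_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV produced by :func:`write_features_table`."""
    return pd.read_csv(path)
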