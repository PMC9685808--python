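"""Readers and writers for every on-disk artifact.

Fluorescence frames come in as 16-bit single-channel TIFF pairs (F0, Fm) holding
12-bit digital numbers (DN, 0-4095). Leaf instance labels are PNGs in the CVPPP
dialect: either integer-coded (0 = background, k >= 1 = leaf k) or RGB with one
color per leaf and black background. Generated samples go out as 32-bit float
TIFF (the Fv/Fm ratio in [0, 1], stored losslessly) plus a single-channel PNG
class mask over {0: background, 1: healthy, 2: diseased}. Dataset manifests are
plain CSV.

All arrays are row-major with the origin at the top-left, 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ContractError, FormatError

#: Upper bound of the 12-bit sensor dynamic range.
MAX_DN = 4095

#: Class codes of a 3-class annotation mask.
BACKGROUND, HEALTHY, DISEASED = 0, 1, 2
CLASS_CODES = (BACKGROUND, HEALTHY, DISEASED)

#: Column order of a dataset manifest CSV.
MANIFEST_COLUMNS = [
    "sample_id",
    "image",
    "mask",
    "severity_pct",
    "plant_size_pct",
    "seed",
    "source_label",
]


@dataclass
class RawFluorPair:
    """A dark-adapted fluorescence frame pair: minimum (F0) and maximum (Fm).

    Parameters
    ----------
    f0, fm
        2-D integer arrays of digital numbers, identical shape.
    acquisition_day
        Day index (>= 0) after emergence; 0 if unknown.
    """

    f0: np.ndarray
    fm: np.ndarray
    acquisition_day: int = 0

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0)
        self.fm = np.asarray(self.fm)
        if self.f0.ndim != 2 or self.fm.ndim != 2:
            raise FormatError("fluorescence frames must be 2-D single-channel arrays")
        if self.f0.shape != self.fm.shape:
            raise FormatError(
                f"F0/Fm shape mismatch: {self.f0.shape} vs {self.fm.shape}"
            )
        if self.f0.min() < 0 or self.fm.min() < 0:
            raise FormatError("digital numbers must be non-negative")
        if self.f0.max() > MAX_DN or self.fm.max() > MAX_DN:
            warnings.warn(
                f"frame values exceed the 12-bit range (> {MAX_DN} DN)",
                stacklevel=3,
            )
        if self.acquisition_day < 0:
            raise ContractError("acquisition_day must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.f0.shape


@dataclass
class LeafLabelImage:
    """Integer-coded leaf instance mask: 0 = background, k >= 1 = leaf k."""

    labels: np.ndarray
    source: str = "cvppp"  # {"cvppp", "procedural"}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label image must be 2-D")
        if self.labels.min() < 0:
            raise ContractError("leaf labels must be non-negative integers")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ContractError("leaf labels must have an integer dtype")
        if self.source not in ("cvppp", "procedural"):
            raise ContractError(f"unknown label source {self.source!r}")

    @property
    def leaf_codes(self) -> np.ndarray:
        """Sorted distinct nonzero label codes."""
        codes = np.unique(self.labels)
        return codes[codes > 0]

    @property
    def n_leaves(self) -> int:
        return int(self.leaf_codes.size)

    @property
    def usable(self) -> bool:
        """A plant is usable if it has at least one labelled pixel."""
        return self.n_leaves > 0


def read_fluor_pair(path_f0, path_fm, acquisition_day: int = 0) -> RawFluorPair:
    """Load an F0/Fm TIFF pair losslessly as integers.

    Raises :class:`FormatError` on shape mismatch or non-2-D frames; values
    outside the 12-bit range only raise a warning.
    """
    f0 = tifffile.imread(str(path_f0))
    fm = tifffile.imread(str(path_fm))
    return RawFluorPair(f0=f0, fm=fm, acquisition_day=acquisition_day)


def write_fluor_pair(pair: RawFluorPair, path_f0, path_fm) -> None:
    """Write an F0/Fm pair as 16-bit single-channel TIFFs (lossless inverse of
    :func:`read_fluor_pair`)."""
    tifffile.imwrite(str(path_f0), pair.f0.astype(np.uint16))
    tifffile.imwrite(str(path_fm), pair.fm.astype(np.uint16))


def _rgb_to_codes(arr: np.ndarray) -> np.ndarray:
    # Enumerate distinct non-background colors in first-occurrence, row-major
    # order; (0,0,0) is the background and maps to 0.
    packed = (
        arr[..., 0].astype(np.uint32) << 16
        | arr[..., 1].astype(np.uint32) << 8
        | arr[..., 2].astype(np.uint32)
    )
    flat = packed.ravel()
    _, first_idx = np.unique(flat, return_index=True)
    ordered = flat[np.sort(first_idx)]
    ordered = ordered[ordered != 0]
    if ordered.size > 255:
        raise FormatError(f"{ordered.size} distinct leaf colors; at most 255 supported")
    labels = np.zeros(packed.shape, dtype=np.uint8)
    for code, color in enumerate(ordered, start=1):
        labels[packed == color] = code
    return labels


def read_label_image(path) -> LeafLabelImage:
    """Read a CVPPP-dialect leaf label PNG (integer-coded or RGB color-coded)."""
    try:
        img = Image.open(str(path))
    except OSError as exc:  # unreadable / not an image
        raise FormatError(f"cannot read label image {path}: {exc}") from exc
    if img.mode in ("RGB", "RGBA"):
        arr = np.asarray(img.convert("RGB"))
        labels = _rgb_to_codes(arr)
    else:
        labels = np.asarray(img.convert("I")).astype(np.int32)
    out = LeafLabelImage(labels=labels, source="cvppp")
    if not out.usable:
        warnings.warn(f"label image {path} contains no leaves", stacklevel=2)
    return out


def write_label_image(label: LeafLabelImage, path) -> None:
    """Write an integer-coded label PNG (codes must fit in 8 bits)."""
    if label.labels.max() > 255:
        raise FormatError("more than 255 leaves; cannot encode as 8-bit PNG")
    Image.fromarray(label.labels.astype(np.uint8), mode="L").save(str(path))


def validate_class_mask(mask: np.ndarray) -> np.ndarray:
    """Check a 3-class annotation mask: 2-D, values in {0, 1, 2}."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ContractError("class mask must be 2-D")
    if not np.isin(mask, CLASS_CODES).all():
        bad = sorted(set(np.unique(mask)) - set(CLASS_CODES))
        raise ContractError(f"class mask contains invalid codes {bad}")
    return mask.astype(np.uint8)


def one_hot(mask: np.ndarray) -> np.ndarray:
    """Expand a class mask to an (H, W, 3) one-hot array (channels sum to 1)."""
    mask = validate_class_mask(mask)
    return np.stack([(mask == c) for c in CLASS_CODES], axis=-1).astype(np.float64)


def write_class_mask(mask: np.ndarray, path) -> None:
    mask = validate_class_mask(mask)
    Image.fromarray(mask, mode="L").save(str(path))


def read_class_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return validate_class_mask(arr)


def write_sample(sample, image_path, mask_path) -> None:
    """Write a synthetic sample: Fv/Fm image (32-bit float TIFF, values in
    [0, 1]) plus its class-mask PNG. Bit-exact under a read round trip.

    ``sample`` is anything with ``image`` and ``mask`` attributes (usually a
    :class:`~fluorosynth.synthesis.SyntheticSample`).
    """
    image = np.asarray(sample.image, dtype=np.float32)
    if image.min() < 0 or image.max() > 1:
        raise ContractError("Fv/Fm image values must lie in [0, 1]")
    mask = validate_class_mask(sample.mask)
    if image.shape != mask.shape:
        raise ContractError("image and mask shapes differ")
    tifffile.imwrite(str(image_path), image)
    write_class_mask(mask, mask_path)


def read_sample(image_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_sample`; returns ``(image, mask)``."""
    image = tifffile.imread(str(image_path))
    mask = read_class_mask(mask_path)
    if image.shape != mask.shape:
        raise FormatError("image and mask shapes differ on disk")
    return image, mask


def write_manifest(manifest: pd.DataFrame, path) -> None:
    """Write a dataset manifest CSV with the canonical column order."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ContractError(f"manifest missing columns {missing}")
    if manifest["sample_id"].duplicated().any():
        raise ContractError("manifest sample_ids must be unique")
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(str(path), index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(str(path))
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns {missing}")
    return df
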