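"""Dataset preprocessing: severity/plant-size accounting, quadrant splitting,
severity filtering, geometric augmentation, and the train/validation split.

Severity S and plant size P are image-level percentages:

    S = 100 * d / (H * W)      d = diseased pixels
    P = 100 * p / (H * W)      p = plant pixels (healthy + diseased)

Both are exact pixel-count ratios, hence invariant under flips and 90-degree
rotations — the augmentation transforms used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import io_formats
from .errors import ContractError
from .io_formats import DISEASED, HEALTHY, validate_class_mask

TRANSFORMS = ("hflip", "vflip", "rot90")


@dataclass(frozen=True)
class SeverityReport:
    """Exact pixel accounting of one class mask."""

    severity_pct: float
    plant_size_pct: float
    diseased_px: int
    plant_px: int
    height: int
    width: int


@dataclass
class AugmentationPlan:
    """Selection fraction, transform set and seed of one augmentation pass."""

    fraction: float = 0.7
    transforms: tuple[str, ...] = TRANSFORMS
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ContractError("fraction must lie in [0, 1]")
        bad = [t for t in self.transforms if t not in TRANSFORMS]
        if bad:
            raise ContractError(f"unknown transforms {bad}")
        if not self.transforms:
            raise ContractError("transform set is empty")


def severity(mask: np.ndarray) -> SeverityReport:
    """Severity and plant size of a 3-class mask, as exact percentages."""
    mask = validate_class_mask(mask)
    h, w = mask.shape
    d = int((mask == DISEASED).sum())
    p = d + int((mask == HEALTHY).sum())
    return SeverityReport(
        severity_pct=100.0 * d / (h * w),
        plant_size_pct=100.0 * p / (h * w),
        diseased_px=d,
        plant_px=p,
        height=h,
        width=w,
    )


def split_quadrants(
    image: np.ndarray, mask: np.ndarray, out_size: int = 128
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a multi-plant frame into its four quadrants and resize each.

    Quadrants come out in top-left, top-right, bottom-left, bottom-right
    order. Images are resized with bilinear interpolation; masks with
    nearest-neighbor so class codes stay in {0, 1, 2}.
    """
    image = np.asarray(image)
    mask = validate_class_mask(mask)
    if image.shape != mask.shape:
        raise ContractError("image and mask shapes differ")
    h, w = image.shape
    if h % 2 or w % 2:
        raise ContractError(f"dimensions must be even to split quadrants, got {h}x{w}")
    hh, hw = h // 2, w // 2
    out = []
    for r0 in (0, hh):
        for c0 in (0, hw):
            img_q = image[r0 : r0 + hh, c0 : c0 + hw]
            msk_q = mask[r0 : r0 + hh, c0 : c0 + hw]
            img_r = resize(
                img_q.astype(np.float64),
                (out_size, out_size),
                order=1,
                preserve_range=True,
                anti_aliasing=True,
            )
            msk_r = resize(
                msk_q,
                (out_size, out_size),
                order=0,
                preserve_range=True,
                anti_aliasing=False,
            ).astype(np.uint8)
            out.append((img_r, validate_class_mask(msk_r)))
    return out


def filter_by_severity(manifest: pd.DataFrame, threshold_pct: float) -> pd.DataFrame:
    """Eliminate records with severity <= threshold (strict keep of S > t),
    preserving record order. Idempotent."""
    return manifest[manifest["severity_pct"] > threshold_pct].reset_index(drop=True)


def apply_transform(arr: np.ndarray, name: str) -> np.ndarray:
    """Apply one named geometric transform (same call for image and mask)."""
    if name == "hflip":
        return np.fliplr(arr).copy()
    if name == "vflip":
        return np.flipud(arr).copy()
    if name == "rot90":
        return np.rot90(arr).copy()
    raise ContractError(f"unknown transform {name!r}")


def plan_augmentation(n_samples: int, plan: AugmentationPlan) -> list[tuple[int, str]]:
    """Pure manifest arithmetic of an augmentation pass.

    A seeded shuffle selects floor(fraction * n) distinct sample indices; each
    gets exactly one transform drawn uniformly from the plan's set. The
    resulting dataset size is therefore n + floor(fraction * n).
    """
    rng = np.random.default_rng(plan.seed)
    k = math.floor(plan.fraction * n_samples)
    chosen = rng.permutation(n_samples)[:k]
    transforms = rng.choice(plan.transforms, size=k)
    return [(int(i), str(t)) for i, t in zip(chosen, transforms)]


def augment(
    manifest: pd.DataFrame,
    plan: AugmentationPlan,
    data_root: str | Path | None = None,
) -> pd.DataFrame:
    """Append one transformed copy per selected sample (originals retained).

    With ``data_root`` given, each selected sample's image and mask are read,
    transformed identically, and written next to the originals with a
    ``-<transform>`` suffix; severity is recomputed from the transformed mask
    (it always matches the source — geometric invariance). Without
    ``data_root`` only the manifest records are planned, for count accounting
    on manifests whose files are not materialized.
    """
    chosen = plan_augmentation(len(manifest), plan)
    new_records = []
    for idx, tname in chosen:
        rec = manifest.iloc[idx].to_dict()
        rec["sample_id"] = f"{rec['sample_id']}-{tname}"
        if data_root is not None:
            root = Path(data_root)
            image, mask = io_formats.read_sample(
                root / rec["image"], root / rec["mask"]
            )
            image_t = apply_transform(image, tname)
            mask_t = apply_transform(mask, tname)
            img_path = _suffixed(rec["image"], tname)
            msk_path = _suffixed(rec["mask"], tname)
            io_formats.write_sample(
                _Sample(image_t, mask_t), root / img_path, root / msk_path
            )
            rep = severity(mask_t)
            rec.update(
                image=img_path,
                mask=msk_path,
                severity_pct=rep.severity_pct,
                plant_size_pct=rep.plant_size_pct,
            )
        new_records.append(rec)
    out = pd.concat([manifest, pd.DataFrame(new_records)], ignore_index=True)
    return out


@dataclass
class _Sample:
    image: np.ndarray
    mask: np.ndarray


def _suffixed(path_str: str, tag: str) -> str:
    p = Path(path_str)
    return str(p.with_name(f"{p.stem}-{tag}{p.suffix}"))


def train_val_split(
    manifest: pd.DataFrame, val_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle split into train and validation manifests."""
    if not 0 <= val_fraction <= 1:
        raise ContractError("val_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(manifest))
    n_val = math.floor(val_fraction * len(manifest))
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    return (
        manifest.iloc[train_idx].reset_index(drop=True),
        manifest.iloc[val_idx].reset_index(drop=True),
    )
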