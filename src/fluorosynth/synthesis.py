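"""The synthesis core: fluorescent diseased plants with exact annotation.

A synthetic Fv/Fm map is assembled leaf by leaf. For each leaf we

1. draw a speckle lesion mask inside the leaf (the healthy part is its
   complement);
2. simulate a healthy ratio field  x(h) = 1 - N(muF0, sigmaF0^2) / N(muFm,
   sigmaFm^2)  from a healthy parameter row and cut the healthy part from it;
3. sample diseased parameters by shifting the healthy ones with deltas drawn
   from their empirical ranges, simulate the diseased field x(d) the same way,
   and cut the lesions from it;
4. assemble the two parts into one leaf (they partition the leaf exactly);
5. paint the leaf onto the plant canvas (later leaves overwrite earlier ones)
   and copy its lesion mask into the disease annotation.

Because the annotation is the very mask that placed the lesions, it is exact
by construction — zero annotation noise.

The raw ratio 1 - a/b is unbounded (b can come arbitrarily close to 0, and
a can exceed b). Two numerical guards keep the field physical: denominator
draws below ``b_floor_frac * muFm`` are redrawn, and the assembled field is
clipped to [0, 1], the physical range of Fv/Fm.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .errors import ContractError
from .fluostats import (
    DeltaRanges,
    FluorParams,
    load_delta_ranges,
    load_healthy_table,
    sample_diseased_params,
)
from .io_formats import BACKGROUND, DISEASED, HEALTHY, LeafLabelImage
from .lesionfield import SpeckleSpec, generate_lesion_mask
from .plantshapes import split_leaves
from .preprocess import severity


@dataclass
class NoiseField:
    """A simulated Fv/Fm ratio field for one tissue class."""

    values: np.ndarray
    tissue: str  # {"healthy", "diseased"}
    params_used: FluorParams


@dataclass
class SyntheticSample:
    """One generated Fv/Fm image with its 3-class annotation and metadata."""

    image: np.ndarray
    mask: np.ndarray
    severity_pct: float
    plant_size_pct: float
    provenance: dict = dc_field(default_factory=dict)


@dataclass
class SynthesisConfig:
    """Every knob of the generator, with defaults bound to the packaged
    parameter tables.

    healthy_sampling
        "per_leaf": each leaf draws its own healthy day row (default);
        "per_plant": one row shared by all leaves of a plant.
    fixed_day
        Pin the healthy row to one acquisition day instead of drawing it.
    b_floor_frac
        Fm draws below this fraction of muFm are redrawn (division guard).
    """

    healthy_table: pd.DataFrame = dc_field(default_factory=load_healthy_table)
    delta_ranges: DeltaRanges = dc_field(default_factory=load_delta_ranges)
    speckle: SpeckleSpec = dc_field(default_factory=SpeckleSpec)
    healthy_sampling: str = "per_leaf"
    fixed_day: int | None = None
    delta_distribution: str = "uniform"
    b_floor_frac: float = 0.05
    clip: bool = True
    n_per_label: int = 7

    def __post_init__(self) -> None:
        if self.healthy_sampling not in ("per_leaf", "per_plant"):
            raise ContractError("healthy_sampling must be per_leaf or per_plant")
        if not 0 < self.b_floor_frac < 1:
            raise ContractError("b_floor_frac must lie in (0, 1)")
        if self.n_per_label < 1:
            raise ContractError("n_per_label must be >= 1")

    def healthy_row(self, rng: np.random.Generator) -> FluorParams:
        df = self.healthy_table
        if self.fixed_day is not None:
            sub = df[df["day"] == self.fixed_day]
            if sub.empty:
                raise ContractError(f"no healthy row for day {self.fixed_day}")
            r = sub.iloc[0]
        else:
            r = df.iloc[int(rng.integers(len(df)))]
        return FluorParams(r.mu_f0, r.sigma_f0, r.mu_fm, r.sigma_fm)


def simulate_field(
    shape: tuple[int, int],
    params: FluorParams,
    rng: np.random.Generator,
    tissue: str = "healthy",
    b_floor_frac: float = 0.05,
    clip: bool = True,
) -> NoiseField:
    """Simulate a per-pixel Fv/Fm ratio field 1 - a/b with a ~ N(muF0,
    sigmaF0^2) and b ~ N(muFm, sigmaFm^2) drawn independently per pixel.

    Denominator draws below ``b_floor_frac * muFm`` are redrawn; the final
    field is clipped to [0, 1] unless ``clip`` is disabled. With zero sigmas
    the field is the constant 1 - muF0/muFm (noiseless limit).
    """
    a = rng.normal(params.mu_f0, params.sigma_f0, size=shape)
    b = rng.normal(params.mu_fm, params.sigma_fm, size=shape)
    floor = b_floor_frac * params.mu_fm
    bad = b < floor
    while bad.any():
        b[bad] = rng.normal(params.mu_fm, params.sigma_fm, size=int(bad.sum()))
        bad = b < floor
    values = 1.0 - a / b
    if clip:
        values = np.clip(values, 0.0, 1.0)
    return NoiseField(values=values, tissue=tissue, params_used=params)


@dataclass
class LeafRender:
    """Output of one per-leaf synthesis pass."""

    image: np.ndarray  # full-canvas field, meaningful only inside the leaf
    lesion_mask: np.ndarray
    healthy_params: FluorParams
    diseased_params: FluorParams


def synthesize_leaf(
    leaf_mask: np.ndarray,
    healthy_params: FluorParams,
    ranges: DeltaRanges,
    speckle: SpeckleSpec,
    rng: np.random.Generator,
    b_floor_frac: float = 0.05,
    clip: bool = True,
    delta_distribution: str = "uniform",
) -> LeafRender:
    """Synthesize one fluorescent diseased leaf (steps 1-4 of the assembly)."""
    leaf_mask = np.asarray(leaf_mask, dtype=bool)
    if not leaf_mask.any():
        raise ContractError("leaf mask is empty")
    lesions = generate_lesion_mask(leaf_mask, speckle, rng)
    healthy = simulate_field(
        leaf_mask.shape, healthy_params, rng, "healthy", b_floor_frac, clip
    )
    diseased_params = sample_diseased_params(
        healthy_params, ranges, rng, delta_distribution
    )
    diseased = simulate_field(
        leaf_mask.shape, diseased_params, rng, "diseased", b_floor_frac, clip
    )
    image = np.zeros(leaf_mask.shape, dtype=np.float64)
    healthy_part = leaf_mask & ~lesions
    image[healthy_part] = healthy.values[healthy_part]
    image[lesions] = diseased.values[lesions]
    return LeafRender(
        image=image,
        lesion_mask=lesions,
        healthy_params=healthy_params,
        diseased_params=diseased_params,
    )


def synthesize_plant(
    label: LeafLabelImage,
    config: SynthesisConfig | None = None,
    rng: np.random.Generator | None = None,
    source_label: str = "",
    seed: int | None = None,
    keep_leaf_masks: bool = False,
) -> SyntheticSample:
    """Assemble a whole synthetic plant by iterating the leaves in label order.

    Later leaves overwrite earlier ones where they overlap — both the image
    values and the lesion annotation, so the diseased class of the final mask
    is exactly the union of the *effective* (post-overwrite) per-leaf lesion
    masks. Background pixels are 0 (non-fluorescing).
    """
    config = config or SynthesisConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    mask_set = split_leaves(label)

    image = np.zeros(mask_set.canvas_shape, dtype=np.float64)
    disease = np.zeros(mask_set.canvas_shape, dtype=bool)
    plant_healthy = (
        config.healthy_row(rng) if config.healthy_sampling == "per_plant" else None
    )
    leaf_params: list[dict] = []
    for leaf_mask, code in zip(mask_set.leaves, mask_set.codes):
        healthy_params = (
            plant_healthy if plant_healthy is not None else config.healthy_row(rng)
        )
        render = synthesize_leaf(
            leaf_mask,
            healthy_params,
            config.delta_ranges,
            config.speckle,
            rng,
            config.b_floor_frac,
            config.clip,
            config.delta_distribution,
        )
        image[leaf_mask] = render.image[leaf_mask]
        disease[leaf_mask] = render.lesion_mask[leaf_mask]
        entry = {
            "leaf": code,
            "healthy": healthy_params.as_tuple(),
            "diseased": render.diseased_params.as_tuple(),
        }
        if keep_leaf_masks:
            entry["leaf_mask"] = leaf_mask.copy()
            entry["lesion_mask"] = render.lesion_mask.copy()
        leaf_params.append(entry)

    plant = mask_set.plant_mask
    mask = np.full(mask_set.canvas_shape, BACKGROUND, dtype=np.uint8)
    mask[plant] = HEALTHY
    mask[disease] = DISEASED
    rep = severity(mask)
    return SyntheticSample(
        image=image,
        mask=mask,
        severity_pct=rep.severity_pct,
        plant_size_pct=rep.plant_size_pct,
        provenance={
            "source_label": source_label,
            "seed": seed,
            "leaf_params": leaf_params,
        },
    )


def derive_sample_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-sample integer seeds derived deterministically from a master seed
    (recorded in the manifest so any sample can be regenerated alone)."""
    return np.random.default_rng(master_seed).integers(2**31, size=n)


def plan_dataset(
    n_labels: int, n_per_label: int, master_seed: int
) -> pd.DataFrame:
    """Manifest skeleton of a build: one row per (label, replicate) with its
    derived seed; |labels| x n_per_label rows in total."""
    if n_per_label < 1:
        raise ContractError("n_per_label must be >= 1")
    seeds = derive_sample_seeds(master_seed, n_labels * n_per_label)
    rows = []
    i = 0
    for li in range(n_labels):
        for rep in range(n_per_label):
            rows.append(
                {
                    "sample_id": f"s{li:04d}_{rep:02d}",
                    "image": f"images/s{li:04d}_{rep:02d}.tif",
                    "mask": f"masks/s{li:04d}_{rep:02d}.png",
                    "severity_pct": np.nan,
                    "plant_size_pct": np.nan,
                    "seed": int(seeds[i]),
                    "source_label": f"label{li:04d}",
                }
            )
            i += 1
    return pd.DataFrame(rows, columns=io_formats.MANIFEST_COLUMNS)


def build_dataset(
    labels: list[LeafLabelImage],
    n_per_label: int,
    config: SynthesisConfig,
    master_seed: int,
    out_dir: str | Path,
    verify: bool = False,
) -> pd.DataFrame:
    """Generate |labels| x n_per_label samples to ``out_dir`` and return the
    manifest. Fully deterministic under a fixed master seed (bit-exact files).

    With ``verify`` the written files are re-read and the severity columns
    recomputed from the masks on disk.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = plan_dataset(len(labels), n_per_label, master_seed)

    i = 0
    for li, label in enumerate(labels):
        for _rep in range(n_per_label):
            rec = manifest.iloc[i]
            sample = synthesize_plant(
                label,
                config,
                source_label=rec["source_label"],
                seed=int(rec["seed"]),
            )
            io_formats.write_sample(
                sample, out_dir / rec["image"], out_dir / rec["mask"]
            )
            manifest.loc[i, "severity_pct"] = sample.severity_pct
            manifest.loc[i, "plant_size_pct"] = sample.plant_size_pct
            i += 1

    if verify:
        manifest = verify_manifest(manifest, out_dir)
    io_formats.write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def verify_manifest(manifest: pd.DataFrame, data_root: str | Path) -> pd.DataFrame:
    """Recompute severity and plant size from the masks on disk; raises if a
    stored value disagrees with its mask."""
    root = Path(data_root)
    out = manifest.copy()
    for i, rec in manifest.iterrows():
        _, mask = io_formats.read_sample(root / rec["image"], root / rec["mask"])
        rep = severity(mask)
        stored = rec["severity_pct"]
        if np.isfinite(stored) and not np.isclose(stored, rep.severity_pct):
            raise ContractError(
                f"{rec['sample_id']}: stored severity {stored} != mask {rep.severity_pct}"
            )
        out.loc[i, "severity_pct"] = rep.severity_pct
        out.loc[i, "plant_size_pct"] = rep.plant_size_pct
    return out
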