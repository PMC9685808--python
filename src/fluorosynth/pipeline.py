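"""End-to-end pipeline: labels -> synthetic dataset -> augmentation, with a
structured run log so that a config file plus its log fully determine every
output byte."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import io_formats
from .config import RunConfig
from .errors import FluorosynthError
from .plantshapes import generate_rosette, sample_rosette_spec
from .preprocess import AugmentationPlan, augment
from .synthesis import build_dataset

logger = logging.getLogger("fluorosynth")


def _load_labels(config: RunConfig, rng: np.random.Generator):
    if config.labels_dir is not None:
        paths = sorted(Path(config.labels_dir).glob("*.png"))
        if not paths:
            raise FluorosynthError(f"no label PNGs found in {config.labels_dir}")
        return [io_formats.read_label_image(p) for p in paths]
    return [
        generate_rosette(sample_rosette_spec(rng, config.canvas_size))
        for _ in range(config.n_rosettes)
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run labels -> build -> augment; returns paths and counts per stage.

    Any stage failure is re-raised annotated with the stage name.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.master_seed)
    log: dict = {"config": "config.yaml", "stages": {}}

    stage = "labels"
    try:
        t0 = time.perf_counter()
        labels = _load_labels(config, rng)
        log["stages"][stage] = {
            "n_labels": len(labels),
            "source": "dir" if config.labels_dir else "procedural",
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s: %d label images", stage, len(labels))

        stage = "build"
        t0 = time.perf_counter()
        manifest = build_dataset(
            labels,
            config.n_per_label,
            config.synthesis_config(),
            config.master_seed,
            out_dir,
            verify=True,
        )
        log["stages"][stage] = {
            "n_samples": len(manifest),
            "master_seed": config.master_seed,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s: %d samples", stage, len(manifest))

        stage = "augment"
        t0 = time.perf_counter()
        plan = AugmentationPlan(
            fraction=config.augment_fraction, seed=config.augmentation_seed
        )
        augmented = augment(manifest, plan, data_root=out_dir)
        io_formats.write_manifest(augmented, out_dir / "manifest_augmented.csv")
        log["stages"][stage] = {
            "n_samples": len(augmented),
            "seed": config.augmentation_seed,
            "fraction": config.augment_fraction,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s: %d samples after augmentation", stage, len(augmented))
    except FluorosynthError as exc:
        raise FluorosynthError(f"stage {stage!r} failed: {exc}") from exc

    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "runlog.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    return {
        "out_dir": str(out_dir),
        "manifest": str(out_dir / "manifest.csv"),
        "manifest_augmented": str(out_dir / "manifest_augmented.csv"),
        "n_samples": len(manifest),
        "n_augmented": len(augmented),
    }
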