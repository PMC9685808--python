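"""Leaf geometry: splitting label images into per-leaf masks and generating
procedural rosettes.

The procedural generator is a download-free stand-in for hand-labelled rosette
imagery: ovate leaf lobes placed around a common center at phyllotaxis-spaced
angles (golden angle ~137.5 deg) with jittered size and orientation. It only
needs to supply plausible blob-like plant silhouettes — the fluorescence
texture is synthesized independently of leaf shape — so no venation, serration
or growth model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .io_formats import LeafLabelImage


@dataclass
class LeafMaskSet:
    """Ordered per-leaf binary masks partitioning the plant region."""

    leaves: list[np.ndarray]
    codes: list[int]
    canvas_shape: tuple[int, int]

    def __post_init__(self) -> None:
        for m, code in zip(self.leaves, self.codes):
            if m.shape != tuple(self.canvas_shape):
                raise ContractError(f"leaf {code}: mask shape differs from canvas")
            if not m.any():
                raise ContractError(f"leaf {code}: empty mask")

    def __len__(self) -> int:
        return len(self.leaves)

    @property
    def plant_mask(self) -> np.ndarray:
        out = np.zeros(self.canvas_shape, dtype=bool)
        for m in self.leaves:
            out |= m
        return out


@dataclass
class RosetteSpec:
    """Parameters of one procedural rosette.

    Leaf lengths are drawn uniformly from ``leaf_length_frac`` (as fractions of
    the canvas side); widths as ``leaf_aspect`` times the length. Later-drawn
    leaves overwrite earlier ones where they overlap, mimicking occlusion in
    top-view imagery.
    """

    n_leaves: int = 8
    canvas_size: int = 128
    leaf_length_frac: tuple[float, float] = (0.18, 0.42)
    leaf_aspect: tuple[float, float] = (0.35, 0.60)
    phyllotaxis_deg: float = 137.5
    angle_jitter_deg: float = 12.0
    center_jitter_frac: float = 0.04
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ContractError("n_leaves must be >= 1")
        if self.canvas_size < 8:
            raise ContractError("canvas too small for any leaf")
        max_len = self.leaf_length_frac[1] * self.canvas_size
        if max_len < 2:
            raise ContractError("canvas too small: longest leaf under 2 px")
        if max_len > 0.5 * self.canvas_size:
            raise ContractError("leaves too long to fit a centered rosette")


def split_leaves(label: LeafLabelImage) -> LeafMaskSet:
    """One binary mask per distinct nonzero label, ordered by label code.

    Masks are pairwise disjoint by construction (labels partition the plant);
    painting code k wherever mask k is true reproduces the input exactly.
    """
    codes = label.leaf_codes
    if codes.size == 0:
        raise ContractError("label image contains no leaves")
    return LeafMaskSet(
        leaves=[label.labels == c for c in codes],
        codes=[int(c) for c in codes],
        canvas_shape=label.labels.shape,
    )


def paint_labels(mask_set: LeafMaskSet) -> LeafLabelImage:
    """Inverse of :func:`split_leaves`: paint each mask with its label code."""
    labels = np.zeros(mask_set.canvas_shape, dtype=np.int32)
    for mask, code in zip(mask_set.leaves, mask_set.codes):
        labels[mask] = code
    return LeafLabelImage(labels=labels, source="procedural")


# Ovate half-width profile along the leaf axis t in (0, 1): narrow at the
# petiole (t=0), widest at t ~ 0.62, rounded tip. Normalized to peak 1.
_PROFILE_P, _PROFILE_Q = 0.5, 0.3
_PROFILE_PEAK = (
    (_PROFILE_P / (_PROFILE_P + _PROFILE_Q)) ** _PROFILE_P
    * (_PROFILE_Q / (_PROFILE_P + _PROFILE_Q)) ** _PROFILE_Q
)


def _leaf_halfwidth(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return (t**_PROFILE_P) * ((1 - t) ** _PROFILE_Q) / _PROFILE_PEAK


def generate_rosette(
    spec: RosetteSpec, rng: np.random.Generator | None = None
) -> LeafLabelImage:
    """Generate a procedural rosette label image.

    Deterministic given ``spec.seed`` (or an explicit ``rng``). Leaves whose
    pixels are fully overwritten by later leaves vanish, so the surviving leaf
    count may be below ``spec.n_leaves``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    size = spec.canvas_size
    labels = np.zeros((size, size), dtype=np.int32)
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    jit = spec.center_jitter_frac * size
    cy, cx = size / 2 + rng.uniform(-jit, jit, size=2)

    for k in range(1, spec.n_leaves + 1):
        angle = np.deg2rad(
            (k - 1) * spec.phyllotaxis_deg
            + rng.uniform(-spec.angle_jitter_deg, spec.angle_jitter_deg)
        )
        length = size * rng.uniform(*spec.leaf_length_frac)
        width = length * rng.uniform(*spec.leaf_aspect)
        dy, dx = np.sin(angle), np.cos(angle)
        u = (rr - cy) * dy + (cc - cx) * dx  # along the axis, petiole at 0
        v = -(rr - cy) * dx + (cc - cx) * dy  # across the axis
        t = u / length
        inside = (t > 0) & (t < 1)
        half = np.zeros_like(u)
        half[inside] = 0.5 * width * _leaf_halfwidth(t[inside])
        labels[inside & (np.abs(v) <= half)] = k

    out = LeafLabelImage(labels=labels, source="procedural")
    if not out.usable:
        raise ContractError("rosette generation produced no leaf pixels")
    return out


def sample_rosette_spec(
    rng: np.random.Generator, canvas_size: int = 128
) -> RosetteSpec:
    """Draw a randomized rosette spec spanning small seedlings to large
    rosettes (plant sizes from under 2 % to over 40 % of the canvas, the
    range observed in top-view rosette imagery)."""
    n_leaves = int(rng.integers(2, 17))
    scale = rng.uniform(0.38, 1.12)
    base_lo, base_hi = 0.18, 0.42
    return RosetteSpec(
        n_leaves=n_leaves,
        canvas_size=canvas_size,
        leaf_length_frac=(base_lo * scale, min(base_hi * scale, 0.49)),
        leaf_aspect=(0.40, 0.70),
        seed=int(rng.integers(2**31)),
    )
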