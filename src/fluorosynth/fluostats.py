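"""Fluorescence statistics: per-tissue parameter estimation and disease shifts.

The generator is parameterized by per-tissue Gaussian statistics of the two
dark-adapted fluorescence frames: (muF0, sigmaF0, muFm, sigmaFm) in digital
numbers. Disease shifts those statistics in a characteristic direction —
F0 rises, Fm falls — which is captured by four dimensionless relative deltas:

    d_mu_f0    = (muF0(d) - muF0(h)) / muF0(h)
    d_sigma_f0 = (sigmaF0(d) - sigmaF0(h)) / sigmaF0(h)
    d_mu_fm    = (muFm(h) - muFm(d)) / muFm(h)
    d_sigma_fm = (sigmaFm(h) - sigmaFm(d)) / sigmaFm(h)

(all four are positive for symptomatic tissue; the pre-symptomatic day 0 shows
negative values). Diseased parameters are then re-synthesized from healthy ones
by drawing each delta from its empirical [min, max] range:

    muF0(r)    = muF0    * (1 + d_mu_f0)
    sigmaF0(r) = sigmaF0 * (1 + d_sigma_f0)
    muFm(r)    = muFm    * (1 - d_mu_fm)
    sigmaFm(r) = sigmaFm * (1 - d_sigma_fm)

The packaged tables carry the published estimates: per-day healthy statistics
(``table1_healthy.csv``), per-day healthy/diseased statistics from infected
dishes (``table2_diseased.csv``), and the delta ranges used for sampling
(``table3_ranges.csv``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd

from .errors import ContractError, InsufficientDataError
from .io_formats import DISEASED, HEALTHY, RawFluorPair, validate_class_mask

DELTA_NAMES = ("d_mu_f0", "d_sigma_f0", "d_mu_fm", "d_sigma_fm")

_TISSUE_CODES = {"healthy": HEALTHY, "diseased": DISEASED}


@dataclass(frozen=True)
class FluorParams:
    """Gaussian statistics of one tissue class's F0 and Fm frames (in DN).

    ``degenerate`` flags a zero standard deviation (e.g. estimated from a
    constant image); such parameters are valid for noiseless simulation but
    cannot serve as a delta denominator.
    """

    mu_f0: float
    sigma_f0: float
    mu_fm: float
    sigma_fm: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mu_f0 <= 0 or self.mu_fm <= 0:
            raise ContractError("fluorescence means must be strictly positive")
        if self.sigma_f0 < 0 or self.sigma_fm < 0:
            raise ContractError("standard deviations must be non-negative")
        if self.sigma_f0 == 0 or self.sigma_fm == 0:
            object.__setattr__(self, "degenerate", True)
        if self.mu_f0 >= self.mu_fm:
            warnings.warn(
                "mu_f0 >= mu_fm: inconsistent with dark-adapted fluorescence "
                "(F0 is always below Fm in real tissue)",
                stacklevel=3,
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mu_f0, self.sigma_f0, self.mu_fm, self.sigma_fm)


@dataclass(frozen=True)
class DeltaSet:
    """The four disease-induced relative shifts (dimensionless, may be < 0)."""

    d_mu_f0: float
    d_sigma_f0: float
    d_mu_fm: float
    d_sigma_fm: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.as_array())):
            raise ContractError("deltas must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.d_mu_f0, self.d_sigma_f0, self.d_mu_fm, self.d_sigma_fm]
        )


@dataclass(frozen=True)
class DeltaRanges:
    """[min, max] interval for each of the four deltas."""

    d_mu_f0: tuple[float, float]
    d_sigma_f0: tuple[float, float]
    d_mu_fm: tuple[float, float]
    d_sigma_fm: tuple[float, float]

    def __post_init__(self) -> None:
        for name in DELTA_NAMES:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ContractError(f"{name}: min {lo} exceeds max {hi}")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lows = np.array([getattr(self, n)[0] for n in DELTA_NAMES])
        highs = np.array([getattr(self, n)[1] for n in DELTA_NAMES])
        return lows, highs


# ---------------------------------------------------------------------------
# Packaged parameter tables


def load_healthy_table() -> pd.DataFrame:
    """Per-day healthy statistics (columns day, mu_f0, sigma_f0, mu_fm, sigma_fm)."""
    return pd.read_csv(files("fluorosynth.data") / "table1_healthy.csv")


def load_diseased_table() -> pd.DataFrame:
    """Per-day healthy/diseased statistics from infected dishes."""
    return pd.read_csv(files("fluorosynth.data") / "table2_diseased.csv")


def load_delta_ranges() -> DeltaRanges:
    """Published delta ranges used to sample diseased parameters."""
    df = pd.read_csv(files("fluorosynth.data") / "table3_ranges.csv").set_index("delta")
    return DeltaRanges(
        **{n: (float(df.loc[n, "min"]), float(df.loc[n, "max"])) for n in DELTA_NAMES}
    )


def healthy_params_by_day(day: int | None = None) -> FluorParams | list[FluorParams]:
    """Healthy parameters for one day, or for every day when ``day`` is None."""
    df = load_healthy_table()
    if day is not None:
        row = df[df["day"] == day]
        if row.empty:
            raise KeyError(f"no healthy statistics for day {day}")
        r = row.iloc[0]
        return FluorParams(r.mu_f0, r.sigma_f0, r.mu_fm, r.sigma_fm)
    return [
        FluorParams(r.mu_f0, r.sigma_f0, r.mu_fm, r.sigma_fm)
        for r in df.itertuples()
    ]


def diseased_table_deltas(days: list[int] | None = None) -> list[DeltaSet]:
    """Deltas computed from the packaged infected-dish table, one per day.

    By default the pre-symptomatic day 0 is excluded (its deltas are negative,
    whereas the published sampling ranges are non-negative).
    """
    df = load_diseased_table()
    if days is None:
        days = [d for d in df["day"] if d != 0]
    out = []
    for day in days:
        row = df[df["day"] == day]
        if row.empty:
            raise KeyError(f"no diseased statistics for day {day}")
        r = row.iloc[0]
        healthy = FluorParams(r.mu_f0_h, r.sigma_f0_h, r.mu_fm_h, r.sigma_fm_h)
        diseased = FluorParams(r.mu_f0_d, r.sigma_f0_d, r.mu_fm_d, r.sigma_fm_d)
        out.append(compute_deltas(healthy, diseased))
    return out


# ---------------------------------------------------------------------------
# Estimation


def compute_fvfm(pair: RawFluorPair, return_zero_count: bool = False):
    """Per-pixel maximum quantum efficiency Fv/Fm = (Fm - F0) / Fm.

    Pixels with Fm = 0 (no fluorescence, typically background) are assigned 0;
    their count is available via ``return_zero_count``.
    """
    f0 = pair.f0.astype(np.float64)
    fm = pair.fm.astype(np.float64)
    nonzero = fm > 0
    out = np.zeros_like(fm)
    out[nonzero] = (fm[nonzero] - f0[nonzero]) / fm[nonzero]
    if return_zero_count:
        return out, int((~nonzero).sum())
    return out


def estimate_class_stats(
    pair: RawFluorPair, mask: np.ndarray, tissue: str
) -> FluorParams:
    """Sample mean and standard deviation (ddof=1) of F0 and Fm over one
    tissue class of an annotated frame pair.

    Raises :class:`InsufficientDataError` below 2 class pixels. A constant
    class yields sigma = 0, returned with the ``degenerate`` flag set.
    """
    mask = validate_class_mask(mask)
    if mask.shape != pair.shape:
        raise ContractError("mask and frame shapes differ")
    if tissue not in _TISSUE_CODES:
        raise ContractError(f"tissue must be one of {sorted(_TISSUE_CODES)}")
    sel = mask == _TISSUE_CODES[tissue]
    n = int(sel.sum())
    if n < 2:
        raise InsufficientDataError(
            f"{n} {tissue} pixel(s); need at least 2 for a standard deviation"
        )
    f0 = pair.f0[sel].astype(np.float64)
    fm = pair.fm[sel].astype(np.float64)
    return FluorParams(
        mu_f0=float(f0.mean()),
        sigma_f0=float(f0.std(ddof=1)),
        mu_fm=float(fm.mean()),
        sigma_fm=float(fm.std(ddof=1)),
    )


def compute_deltas(healthy: FluorParams, diseased: FluorParams) -> DeltaSet:
    """Relative disease shifts of the four parameters (F0 as increases, Fm as
    decreases, so symptomatic tissue yields positive values for all four)."""
    if healthy.sigma_f0 == 0 or healthy.sigma_fm == 0:
        raise ZeroDivisionError("healthy standard deviation is zero")
    return DeltaSet(
        d_mu_f0=(diseased.mu_f0 - healthy.mu_f0) / healthy.mu_f0,
        d_sigma_f0=(diseased.sigma_f0 - healthy.sigma_f0) / healthy.sigma_f0,
        d_mu_fm=(healthy.mu_fm - diseased.mu_fm) / healthy.mu_fm,
        d_sigma_fm=(healthy.sigma_fm - diseased.sigma_fm) / healthy.sigma_fm,
    )


def apply_deltas(healthy: FluorParams, deltas: DeltaSet) -> FluorParams:
    """Diseased parameters implied by healthy ones and a fixed delta set
    (exact inverse of :func:`compute_deltas`)."""
    return FluorParams(
        mu_f0=healthy.mu_f0 * (1 + deltas.d_mu_f0),
        sigma_f0=healthy.sigma_f0 * (1 + deltas.d_sigma_f0),
        mu_fm=healthy.mu_fm * (1 - deltas.d_mu_fm),
        sigma_fm=healthy.sigma_fm * (1 - deltas.d_sigma_fm),
    )


def estimate_delta_ranges(deltas: list[DeltaSet]) -> DeltaRanges:
    """Componentwise [min, max] envelope over a list of per-day delta sets."""
    if not deltas:
        raise InsufficientDataError("need at least one DeltaSet")
    arr = np.stack([d.as_array() for d in deltas])
    lows, highs = arr.min(axis=0), arr.max(axis=0)
    return DeltaRanges(
        **{n: (float(lows[i]), float(highs[i])) for i, n in enumerate(DELTA_NAMES)}
    )


def sample_delta_set(
    ranges: DeltaRanges, rng: np.random.Generator, distribution: str = "uniform"
) -> DeltaSet:
    """Draw each delta independently from its range (uniform by default)."""
    lows, highs = ranges.as_arrays()
    if distribution == "uniform":
        vals = rng.uniform(lows, highs)
    elif distribution == "midpoint":  # deterministic, for diagnostics
        vals = (lows + highs) / 2
    else:
        raise ContractError(f"unknown delta distribution {distribution!r}")
    return DeltaSet(*[float(v) for v in vals])


def sample_diseased_params(
    healthy: FluorParams,
    ranges: DeltaRanges,
    rng: np.random.Generator,
    distribution: str = "uniform",
) -> FluorParams:
    """Draw diseased parameters from healthy ones: each delta uniform on its
    [min, max] range, then applied multiplicatively (F0 up, Fm down)."""
    return apply_deltas(healthy, sample_delta_set(ranges, rng, distribution))
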