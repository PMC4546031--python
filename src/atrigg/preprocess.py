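"""Spectral pre-processing chain.

Stage order (each stage applied per replicate before averaging):

1. Savitzky–Golay smoothing or derivative (window 9, polynomial order 2,
   mirror-padded edges so output length equals input length);
2. normalization — standard normal variate (SNV) or unit vector norm —
   applied to the full-span spectrum;
3. region selection, default 3700–2600 and 1800–1300 cm^-1 (the strongest
   protein absorptions; this also drops the noisy 2200–1900 diamond band);
4. per-wavenumber Dixon Q-test replicate screen: a replicate flagged as the
   outlying value (95% confidence) at more than 50% of the retained points
   is excluded whole;
5. arithmetic averaging of the surviving replicates.

The module is fully deterministic; it contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra_io import WavenumberGrid

__all__ = [
    "PreprocessSpec",
    "OutlierReport",
    "PipelineResult",
    "DIXON_Q_CRITICAL",
    "savgol_smooth",
    "savgol_derivative",
    "snv",
    "vector_normalize",
    "select_regions",
    "region_mask",
    "dixon_q",
    "flag_outlier_replicates",
    "average_replicates",
    "apply_pipeline",
]

DEFAULT_REGIONS = ((3700.0, 2600.0), (1800.0, 1300.0))

# Dixon r10 ("gap over range") two-tailed critical values for n = 3..7
# (Rorabacher 1991); the n=5 / 95% entry is 0.710
DIXON_Q_CRITICAL = {
    0.90: {3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507},
    0.95: {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568},
    0.99: {3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680},
}

_SMOOTHING = ("none", "savitzky_golay")
_DERIVATIVES = ("none", "first", "second")
_NORMALIZATIONS = ("none", "snv", "vector")


@dataclass(frozen=True)
class PreprocessSpec:
    """Declarative description of one pre-processing variant."""

    smoothing: str = "none"
    derivative: str = "none"
    window: int = 9
    polyorder: int = 2
    normalization: str = "none"
    regions: tuple[tuple[float, float], ...] = DEFAULT_REGIONS
    outlier_confidence: float = 0.95
    outlier_point_fraction_threshold: float = 0.50

    def __post_init__(self) -> None:
        if self.smoothing not in _SMOOTHING:
            raise ValueError(f"unknown smoothing {self.smoothing!r}")
        if self.derivative not in _DERIVATIVES:
            raise ValueError(f"unknown derivative {self.derivative!r}")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.smoothing != "none" and self.derivative != "none":
            raise ValueError("smoothing and derivative are alternatives, not a stack")
        if self.window % 2 == 0 or self.window < self.polyorder + 2:
            raise ValueError("window must be odd and >= polyorder + 2")
        if self.derivative == "second" and self.polyorder < 2:
            raise ValueError("second derivative needs polyorder >= 2")
        regs = tuple((float(h), float(l)) for h, l in self.regions)
        for h, l in regs:
            if not h > l:
                raise ValueError("each region must be (high, low) with high > low")
        for (h1, l1), (h2, l2) in zip(regs, regs[1:]):
            if l1 <= h2:
                raise ValueError("regions must be non-overlapping and ordered high to low")
        object.__setattr__(self, "regions", regs)
        if not 0.0 < self.outlier_confidence < 1.0:
            raise ValueError("outlier_confidence must be in (0, 1)")
        if not 0.0 <= self.outlier_point_fraction_threshold <= 1.0:
            raise ValueError("outlier_point_fraction_threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "smoothing": self.smoothing,
            "derivative": self.derivative,
            "window": self.window,
            "polyorder": self.polyorder,
            "normalization": self.normalization,
            "regions": [list(r) for r in self.regions],
            "outlier_confidence": self.outlier_confidence,
            "outlier_point_fraction_threshold": self.outlier_point_fraction_threshold,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PreprocessSpec":
        data = dict(data)
        if "regions" in data:
            data["regions"] = tuple(tuple(r) for r in data["regions"])
        return cls(**data)


@dataclass(frozen=True)
class OutlierReport:
    """Outcome of the per-wavenumber Dixon screen on one replicate group."""

    flagged_fraction: np.ndarray          # per replicate, fraction of points flagged
    excluded: np.ndarray                  # per replicate, bool
    n_points: int
    q_low: np.ndarray = field(repr=False, default=None)    # per point
    q_high: np.ndarray = field(repr=False, default=None)   # per point
    flagged_replicate: np.ndarray = field(repr=False, default=None)  # per point, -1 = none

    @property
    def n_survivors(self) -> int:
        return int((~self.excluded).sum())

    def to_frame(self, sample_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": sample_id,
                "replicate_id": np.arange(1, self.flagged_fraction.size + 1),
                "flagged_fraction": self.flagged_fraction,
                "excluded": self.excluded,
            }
        )


# ---------------------------------------------------------------------------
# Filters and normalizations
# ---------------------------------------------------------------------------

def savgol_smooth(values: np.ndarray, window: int = 9, polyorder: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothing (local least-squares polynomial fit).

    Mirror padding at the ends keeps the output the same length as the
    input; interior points reproduce any polynomial of degree <= polyorder
    exactly.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if values.shape[-1] < window:
        raise ValueError("window larger than spectrum")
    return savgol_filter(values, window, polyorder, mode="mirror")


def savgol_derivative(
    values: np.ndarray,
    order: int,
    window: int = 9,
    spacing: float = 1.0,
    polyorder: int = 2,
) -> np.ndarray:
    """Savitzky–Golay derivative with respect to *increasing* wavenumber.

    The canonical storage order is descending wavenumber, so the index-space
    derivative is sign-flipped once per derivative order; the second
    derivative is therefore unaffected.  Units: AU·cm for order 1,
    AU·cm^2 for order 2.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if order > polyorder:
        raise ValueError("derivative order cannot exceed polyorder")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    values = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if values.shape[-1] < window:
        raise ValueError("window larger than spectrum")
    d = savgol_filter(values, window, polyorder, deriv=order, delta=spacing, mode="mirror")
    return d * ((-1.0) ** order)


def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering to mean 0, scaling to
    sample (n-1) standard deviation 1."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = values.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum")
    return (values - values.mean(axis=-1, keepdims=True)) / sd


def vector_normalize(values: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm, preserving direction."""
    values = np.asarray(values, dtype=float)
    norm = np.linalg.norm(values, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("cannot normalize a zero vector")
    return values / norm


# ---------------------------------------------------------------------------
# Region selection
# ---------------------------------------------------------------------------

def region_mask(grid: WavenumberGrid, regions: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean mask of grid points inside any closed [low, high] interval."""
    nu = grid.values
    mask = np.zeros(nu.size, dtype=bool)
    for high, low in regions:
        mask |= (nu <= high) & (nu >= low)
    return mask


def select_regions(
    grid: WavenumberGrid,
    values: np.ndarray,
    regions: Sequence[tuple[float, float]] = DEFAULT_REGIONS,
) -> tuple[WavenumberGrid, np.ndarray]:
    """Keep only the points inside the given (high, low) intervals.

    Order is preserved (descending), with the higher-wavenumber region
    first.  Works on a single spectrum or a stack (last axis = wavenumber).
    """
    mask = region_mask(grid, regions)
    if not mask.any():
        raise ValueError("regions do not intersect the grid")
    values = np.asarray(values, dtype=float)
    return WavenumberGrid(grid.values[mask], spacing=grid.spacing), values[..., mask]


# ---------------------------------------------------------------------------
# Dixon Q replicate screen
# ---------------------------------------------------------------------------

def dixon_q(values: Sequence[float], confidence: float = 0.95):
    """Two-sided Dixon r10 test on 3–7 replicate values.

    Returns ``(q_low, q_high, outlier_index)`` where q_low tests the
    smallest value and q_high the largest; the larger statistic is compared
    to the tabulated critical value and at most one index is flagged.
    A zero range yields ``(nan, nan, None)``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if not 3 <= n <= 7:
        raise ValueError("Dixon r10 table covers n = 3..7")
    try:
        crit = DIXON_Q_CRITICAL[round(confidence, 2)][n]
    except KeyError:
        raise ValueError(
            f"unsupported confidence {confidence}; table has {sorted(DIXON_Q_CRITICAL)}"
        ) from None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    spread = xs[-1] - xs[0]
    if spread == 0:
        return float("nan"), float("nan"), None
    q_low = (xs[1] - xs[0]) / spread
    q_high = (xs[-1] - xs[-2]) / spread
    idx = None
    if q_high >= q_low:  # tie goes to the high end (deterministic convention)
        if q_high > crit:
            idx = int(order[-1])
    elif q_low > crit:
        idx = int(order[0])
    return float(q_low), float(q_high), idx


def flag_outlier_replicates(
    replicates: np.ndarray,
    spec: PreprocessSpec = PreprocessSpec(),
) -> OutlierReport:
    """Apply the Dixon screen independently at every wavenumber point.

    ``replicates`` is an (n_replicates, n_points) matrix of aligned,
    already-preprocessed spectra.  A replicate flagged at a fraction of
    points strictly greater than the threshold (default 0.50) is excluded;
    at least two replicates must survive.
    """
    X = np.asarray(replicates, dtype=float)
    if X.ndim != 2:
        raise ValueError("replicates must be a 2-D (replicate, point) matrix")
    r, p = X.shape
    if not 3 <= r <= 7:
        raise ValueError("the replicate screen needs 3..7 replicates")
    try:
        crit = DIXON_Q_CRITICAL[round(spec.outlier_confidence, 2)][r]
    except KeyError:
        raise ValueError(f"unsupported confidence {spec.outlier_confidence}") from None

    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    spread = xs[-1] - xs[0]
    valid = spread > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        q_low = np.where(valid, (xs[1] - xs[0]) / spread, np.nan)
        q_high = np.where(valid, (xs[-1] - xs[-2]) / spread, np.nan)

    flagged = np.full(p, -1, dtype=int)
    high_side = valid & (q_high >= q_low) & (q_high > crit)
    low_side = valid & (q_low > q_high) & (q_low > crit)
    flagged[high_side] = order[-1, high_side]
    flagged[low_side] = order[0, low_side]

    counts = np.bincount(flagged[flagged >= 0], minlength=r)
    fractions = counts / p
    excluded = fractions > spec.outlier_point_fraction_threshold
    if (~excluded).sum() < 2:
        raise ValueError("fewer than 2 replicates survive the outlier screen")
    return OutlierReport(
        flagged_fraction=fractions,
        excluded=excluded,
        n_points=p,
        q_low=q_low,
        q_high=q_high,
        flagged_replicate=flagged,
    )


def average_replicates(replicates: np.ndarray, report: OutlierReport | None = None) -> np.ndarray:
    """Pointwise mean over the non-excluded replicates."""
    X = np.asarray(replicates, dtype=float)
    if report is not None:
        keep = ~report.excluded
        if keep.sum() < 2:
            raise ValueError("fewer than 2 replicates to average")
        X = X[keep]
    return X.mean(axis=0)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineResult:
    """Averaged, preprocessed spectrum of one sample plus its audit trail."""

    values: np.ndarray
    grid: WavenumberGrid
    report: OutlierReport
    replicates: np.ndarray = field(repr=False, default=None)  # surviving, preprocessed


def preprocess_replicates(
    replicates: np.ndarray, grid: WavenumberGrid, spec: PreprocessSpec
) -> tuple[np.ndarray, WavenumberGrid]:
    """Stages 1–3 (filter, normalize, region-select) on a replicate stack."""
    X = np.asarray(replicates, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(grid):
        raise ValueError("replicate length does not match grid")
    if spec.smoothing == "savitzky_golay":
        X = savgol_smooth(X, spec.window, spec.polyorder)
    elif spec.derivative != "none":
        order = 1 if spec.derivative == "first" else 2
        spacing = grid.spacing if grid.spacing is not None else abs(
            float(np.median(np.diff(grid.values)))
        )
        X = savgol_derivative(X, order, spec.window, spacing, spec.polyorder)
    if spec.normalization == "snv":
        X = snv(X)
    elif spec.normalization == "vector":
        X = vector_normalize(X)
    subgrid, X = select_regions(grid, X, spec.regions)
    return X, subgrid


def apply_pipeline(
    replicates: np.ndarray, grid: WavenumberGrid, spec: PreprocessSpec
) -> PipelineResult:
    """Run the full per-sample chain and return the averaged spectrum.

    The Dixon screen runs on the same preprocessed, region-selected points
    the calibration model will see, in a single pass (no re-screening after
    an exclusion).
    """
    X, subgrid = preprocess_replicates(replicates, grid, spec)
    report = flag_outlier_replicates(X, spec)
    mean = average_replicates(X, report)
    return PipelineResult(values=mean, grid=subgrid, report=report, replicates=X[~report.excluded])
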