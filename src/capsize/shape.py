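"""Sphericity statistic, shape classification and condition-grid aggregation.

The sphericity factor of a capsule is

    SF = (D_max − D_min) / (D_max + D_min)

which is 0 for a perfect sphere and approaches 1 for a needle.  A capsule is
classed *spherical* when SF < 0.07 (strict), *deformed* otherwise.  Grid
aggregation averages per-condition SF (or diameter) over one viscosity axis
to expose how capsule shape responds to the other axis, skipping conditions
where no capsule formed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import CapsuleBatch, ConditionGrid, ValidationError

logger = logging.getLogger("capsize")

#: Default sphericity threshold separating spherical from deformed capsules.
SF_SPHERICAL_THRESHOLD = 0.07


class ShapeClass(str, Enum):
    SPHERICAL = "spherical"
    DEFORMED = "deformed"


@dataclass(frozen=True)
class ShapeResult:
    """Per-capsule shape summary: SF, class, and diameter D (= d_min)."""

    sf: float
    shape_class: ShapeClass
    d: float


@dataclass(frozen=True)
class BatchSummary:
    """Mean/SD of SF and diameter over one capsule batch (sample SD, n−1)."""

    mean_sf: float
    sd_sf: float | None
    mean_d: float
    sd_d: float | None
    n: int


@dataclass(frozen=True)
class AggregateCurve:
    """A mean ± SD curve against viscosity (or surface tension).

    ``n[i]`` is the number of non-missing grid cells behind point i.
    """

    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        for name in ("x", "mean", "sd", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "n", self.n.astype(int))


class GridAxis(str, Enum):
    """Which grid axis is averaged *over* (collapsed)."""

    OVER_CORE_VISCOSITY = "over_core_viscosity"   # collapse rows → curve vs bath viscosity
    OVER_BATH_VISCOSITY = "over_bath_viscosity"   # collapse columns → curve vs core viscosity


def sphericity_factor(d_max: float, d_min: float) -> float:
    """SF = (d_max − d_min)/(d_max + d_min); both diameters in mm.

    Scale invariant and zero iff the two diameters coincide.
    """
    if not (d_min > 0):
        raise ValidationError(f"d_min must be > 0, got {d_min}")
    if d_max < d_min:
        raise ValidationError(f"d_max ({d_max}) < d_min ({d_min})")
    return (d_max - d_min) / (d_max + d_min)


def classify(sf: float, threshold: float = SF_SPHERICAL_THRESHOLD) -> ShapeClass:
    """Spherical iff sf < threshold, strictly; a tie at the threshold is deformed."""
    if sf < 0:
        raise ValidationError(f"sf must be ≥ 0, got {sf}")
    return ShapeClass.SPHERICAL if sf < threshold else ShapeClass.DEFORMED


def shape_result(d_max: float, d_min: float,
                 threshold: float = SF_SPHERICAL_THRESHOLD) -> ShapeResult:
    sf = sphericity_factor(d_max, d_min)
    return ShapeResult(sf=sf, shape_class=classify(sf, threshold), d=d_min)


def batch_summary(batch: CapsuleBatch) -> BatchSummary:
    """Mean and sample SD (n−1) of SF and diameter over a batch.

    SD is reported as None for a single-capsule batch.
    """
    sfs = np.array([sphericity_factor(c.d_max, c.d_min) for c in batch.capsules])
    ds = np.array([c.d_min for c in batch.capsules])
    n = len(batch)
    return BatchSummary(
        mean_sf=float(sfs.mean()),
        sd_sf=float(sfs.std(ddof=1)) if n > 1 else None,
        mean_d=float(ds.mean()),
        sd_d=float(ds.std(ddof=1)) if n > 1 else None,
        n=n,
    )


def grid_average(grid: ConditionGrid, axis: GridAxis | str) -> AggregateCurve:
    """Average a condition grid along one viscosity axis.

    Missing cells ("no capsule formed") are skipped and the effective count
    per point is reported; an x whose cells are all missing is dropped with
    a warning rather than reported as zero.
    """
    axis = GridAxis(axis)
    if axis is GridAxis.OVER_CORE_VISCOSITY:
        x = grid.bath_viscosities
        cells = grid.values          # columns indexed by x → average down rows
    else:
        x = grid.core_viscosities
        cells = grid.values.T
    xs, means, sds, ns = [], [], [], []
    for xi, col in zip(x, cells.T):
        good = col[~np.isnan(col)]
        if good.size == 0:
            logger.warning("grid point x=%g has no formed capsules; dropped", xi)
            continue
        xs.append(float(xi))
        means.append(float(good.mean()))
        sds.append(float(good.std(ddof=1)) if good.size > 1 else math.nan)
        ns.append(good.size)
    if not xs:
        raise ValidationError("grid has no non-missing cells")
    return AggregateCurve(x=np.array(xs), mean=np.array(means),
                          sd=np.array(sds), n=np.array(ns))


def threshold_crossing(curve: AggregateCurve,
                       level: float = SF_SPHERICAL_THRESHOLD) -> float | None:
    """x where the mean curve first crosses ``level``, by linear interpolation.

    A point exactly at the level counts as a crossing at that x.  Returns
    None when the curve never reaches the level; with several crossings the
    first is returned and the count logged.
    """
    if curve.x.size < 2:
        raise ValidationError("need at least 2 curve points")
    y = curve.mean
    crossings: list[float] = []
    for i in range(y.size):
        if y[i] == level:
            crossings.append(float(curve.x[i]))
        elif i + 1 < y.size and (y[i] - level) * (y[i + 1] - level) < 0:
            t = (level - y[i]) / (y[i + 1] - y[i])
            crossings.append(float(curve.x[i] + t * (curve.x[i + 1] - curve.x[i])))
    if not crossings:
        return None
    if len(crossings) > 1:
        logger.info("curve crosses level %g %d times; reporting the first",
                    level, len(crossings))
    return crossings[0]


def percent_change(first: float, last: float) -> float:
    """Percent decrease from ``first`` to ``last``: (first − last)/first × 100."""
    if not (first > 0):
        raise ValidationError(f"first value must be > 0, got {first}")
    return (first - last) / first * 100.0


__all__ = [
    "SF_SPHERICAL_THRESHOLD",
    "ShapeClass",
    "ShapeResult",
    "BatchSummary",
    "AggregateCurve",
    "GridAxis",
    "sphericity_factor",
    "classify",
    "shape_result",
    "batch_summary",
    "grid_average",
    "threshold_crossing",
    "percent_change",
]
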