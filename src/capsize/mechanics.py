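"""Shell mechanics from parallel-plate compression curves.

For small flattening of a thin-walled liquid-filled sphere the force is
linear in displacement (Reissner point-load response of a shallow shell):

    F = 4·E_s·h·d_D / (r·√(3·(1 − ν_s²)))

where E_s is the surface Young's modulus (N/m), h the membrane thickness,
r the capsule radius, ν_s the surface Poisson ratio and d_D the plate
displacement.  Fitting the initial slope of a force–displacement record
over a small-deformation window (default 0–1 mm) and inverting this
relation gives E_s.  With ν_s = 1/2 the geometric factor √(3(1−ν_s²)) is
exactly 3/2.

A rupture ("crushing point") shows up as a sharp force drop after a force
maximum; spherical capsules crush at much higher force and displacement
than deformed ones, deformed capsules may show no crushing point at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ForceCurve, ValidationError

logger = logging.getLogger("capsize")


@dataclass(frozen=True)
class ModulusEstimate:
    """Surface Young's modulus from the small-deformation window.

    ``slope`` is the fitted F-vs-d_D slope in N/mm; ``e_s`` in N/m.
    """

    e_s: float
    slope: float
    fit_window: tuple[float, float]
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.e_s < 0:
            raise ValidationError(f"e_s must be ≥ 0, got {self.e_s}")
        if not (0 <= self.r_squared <= 1):
            raise ValidationError(f"r_squared must lie in [0, 1], got {self.r_squared}")


@dataclass(frozen=True)
class CrushingEvent:
    """Rupture point of a compression curve; absent for monotone curves."""

    present: bool
    force: float | None = None          # N
    displacement: float | None = None   # mm
    n_drops: int = 0


@dataclass(frozen=True)
class RatioRange:
    """Min/max of pairwise spherical/deformed ratios for one quantity."""

    min_ratio: float
    max_ratio: float
    n_pairs: int
    n_skipped: int = 0


def geometric_factor(poisson_ratio: float) -> float:
    """√(3·(1 − ν_s²)) — exactly 1.5 at ν_s = 1/2."""
    if not (0 <= poisson_ratio < 1):
        raise ValidationError("poisson_ratio must lie in [0, 1)")
    return math.sqrt(3.0 * (1.0 - poisson_ratio**2))


def fit_surface_modulus(
    curve: ForceCurve,
    window: tuple[float, float] = (0.0, 1.0),
    through_origin: bool = True,
) -> ModulusEstimate:
    """Estimate E_s from the linear small-deformation response.

    Least-squares slope of force vs displacement on ``window`` (mm),
    through the origin by default (zero force at zero displacement), then

        E_s = slope · r · √(3(1 − ν_s²)) / (4·h)

    with slope converted to N/m.  A negative fitted slope yields E_s = 0
    with a warning.
    """
    lo, hi = window
    mask = (curve.displacement >= lo) & (curve.displacement <= hi)
    x = curve.displacement[mask]
    y = curve.force[mask]
    if x.size < 3:
        raise ValidationError(
            f"need ≥ 3 points in fit window [{lo}, {hi}] mm, found {x.size}"
        )
    if through_origin:
        denom = float(np.dot(x, x))
        slope = float(np.dot(x, y)) / denom
        resid = y - slope * x
        ss_tot = float(np.dot(y, y))  # uncentered total SS for a no-intercept fit
    else:
        slope, intercept = np.polyfit(x, y, 1)
        slope = float(slope)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.dot(resid, resid)) / ss_tot)
    if slope < 0:
        logger.warning("negative fitted slope %.3g N/mm; reporting E_s = 0", slope)
        e_s = 0.0
    else:
        slope_si = slope * 1000.0  # N/mm → N/m
        e_s = (
            slope_si
            * curve.radius
            * geometric_factor(curve.poisson_ratio)
            / (4.0 * curve.membrane_thickness)
        )
    return ModulusEstimate(
        e_s=e_s, slope=slope, fit_window=(lo, hi), r_squared=r2, n_points=int(x.size)
    )


def detect_crushing(
    curve: ForceCurve, drop_fraction: float = 0.2, lookahead: int = 3
) -> CrushingEvent:
    """Locate the crushing point as the force maximum preceding the first
    sharp relative force drop.

    A drop qualifies when some sample within ``lookahead`` points falls below
    (1 − drop_fraction) times the current force.  Monotone non-decreasing
    curves never fire.  The total number of qualifying drops is reported.
    """
    if len(curve) < 5:
        raise ValidationError("need at least 5 points to detect crushing")
    f = curve.force
    events: list[int] = []  # indices of rupture peaks
    peak_idx = 0
    for j in range(1, f.size):
        if f[j] > f[peak_idx]:
            peak_idx = j
            continue
        if (
            f[peak_idx] > 0
            and j - peak_idx <= lookahead
            and f[j] <= (1.0 - drop_fraction) * f[peak_idx]
        ):
            events.append(peak_idx)
            peak_idx = j  # restart the running maximum after the rupture
    if not events:
        return CrushingEvent(present=False)
    first = events[0]
    return CrushingEvent(
        present=True,
        force=float(f[first]),
        displacement=float(curve.displacement[first]),
        n_drops=len(events),
    )


def _value(item) -> float:
    if isinstance(item, ModulusEstimate):
        return item.e_s
    if isinstance(item, CrushingEvent):
        if not item.present:
            raise ValidationError("cannot take a ratio against an absent crushing event")
        return item.force
    return float(item)


def ratio_range(spherical: Sequence, deformed: Sequence) -> RatioRange:
    """Min and max of all pairwise spherical/deformed ratios.

    Items may be numbers, :class:`ModulusEstimate` (uses e_s) or
    :class:`CrushingEvent` (uses force).  Pairs with a zero denominator are
    skipped with a warning.
    """
    if not spherical or not deformed:
        raise ValidationError("both classes must be non-empty")
    ratios = []
    skipped = 0
    for s in spherical:
        for d in deformed:
            dv = _value(d)
            if dv == 0:
                skipped += 1
                continue
            ratios.append(_value(s) / dv)
    if skipped:
        logger.warning("skipped %d ratio pair(s) with zero denominator", skipped)
    if not ratios:
        raise ValidationError("no ratio pairs with non-zero denominator")
    return RatioRange(
        min_ratio=min(ratios), max_ratio=max(ratios),
        n_pairs=len(ratios), n_skipped=skipped,
    )


def compare_groups(
    spherical_moduli: Sequence | None = None,
    deformed_moduli: Sequence | None = None,
    spherical_crushing: Sequence | None = None,
    deformed_crushing: Sequence | None = None,
) -> dict[str, RatioRange]:
    """Ratio table contrasting spherical vs deformed capsules.

    Returns min/max pairwise ratios for whichever of surface modulus and
    crushing force both classes were supplied.
    """
    table: dict[str, RatioRange] = {}
    if spherical_moduli is not None and deformed_moduli is not None:
        table["e_s"] = ratio_range(spherical_moduli, deformed_moduli)
    if spherical_crushing is not None and deformed_crushing is not None:
        table["crushing_force"] = ratio_range(spherical_crushing, deformed_crushing)
    if not table:
        raise ValidationError("supply both classes for at least one quantity")
    return table


__all__ = [
    "ModulusEstimate",
    "CrushingEvent",
    "RatioRange",
    "geometric_factor",
    "fit_surface_modulus",
    "detect_crushing",
    "ratio_range",
    "compare_groups",
]
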