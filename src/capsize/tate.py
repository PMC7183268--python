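"""Modified Tate's-law capsule diameter prediction and AAD/MAD validation.

Classical Tate's law balances the weight of a pendant drop against the
surface-tension force holding it at the nozzle tip, m·g = π·d_t·γ, giving a
detached-drop diameter (6·d_t·γ/(ρ·g))^(1/3).  Two empirical corrections
adapt this to extrusion-dripped alginate capsules:

* ``K_LF = 0.98 − 0.04·d_t`` (d_t in mm) — residual liquid left at the
  nozzle on detachment shrinks the drop diameter by this factor;
* ``K_SF = D/d_d`` — the diameter change of the drop during ionotropic
  gelation (shrinkage or swelling), measured as the ratio of the final
  capsule diameter to the detached-drop diameter.

The overall correction is multiplicative, K = K_LF·K_SF, and the predicted
capsule diameter is

    d_p = K · (6·d_t·γ / (ρ·g))^(1/3).

Model quality is summarized by the average and maximum absolute percentage
deviation (AAD/MAD) between predicted and observed diameters, with the
predicted diameter as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    DropletMeasurement,
    NozzleSpec,
    ValidationError,
    _sphere_diameter_mm,
)

#: K_LF goes non-positive at this nozzle diameter (mm); larger nozzles are
#: outside the correlation's domain.
_KLF_MAX_DT = 0.98 / 0.04


@dataclass(frozen=True)
class CorrectionFactors:
    """Size-correction factors of the modified Tate model, K = K_LF·K_SF."""

    k_lf: float
    k_sf: float

    def __post_init__(self):
        if not (0 < self.k_lf <= 0.98):
            raise ValidationError(f"k_lf must lie in (0, 0.98], got {self.k_lf}")
        if not (self.k_sf > 0):
            raise ValidationError(f"k_sf must be > 0, got {self.k_sf}")

    @property
    def k(self) -> float:
        return self.k_lf * self.k_sf


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted capsule diameter with the inputs that produced it."""

    d_p: float                       # mm
    d_obs: float | None = None       # mm
    nozzle: NozzleSpec | None = None
    surface_tension: float | None = None   # mN/m
    density: float | None = None           # kg/m³
    factors: CorrectionFactors | None = None

    def __post_init__(self):
        if not (self.d_p > 0):
            raise ValidationError(f"predicted diameter must be > 0, got {self.d_p}")


@dataclass(frozen=True)
class ValidationReport:
    """AAD and MAD, both in %, over n prediction/observation pairs."""

    aad: float
    mad: float
    n: int

    def __post_init__(self):
        if not (0 <= self.aad <= self.mad):
            raise ValidationError(
                f"need 0 ≤ aad ≤ mad, got aad={self.aad}, mad={self.mad}"
            )
        if self.n < 1:
            raise ValidationError("n must be ≥ 1")


def _dt_mm(nozzle: NozzleSpec | float) -> float:
    return nozzle.outer_diameter if isinstance(nozzle, NozzleSpec) else float(nozzle)


def correction_factor_lf(nozzle: NozzleSpec | float) -> float:
    """Residual-liquid correction K_LF = 0.98 − 0.04·d_t (d_t in mm)."""
    d_t = _dt_mm(nozzle)
    if not (0 < d_t < _KLF_MAX_DT):
        raise ValidationError(
            f"nozzle diameter {d_t} mm outside (0, {_KLF_MAX_DT}) mm; "
            "K_LF would be non-positive"
        )
    return 0.98 - 0.04 * d_t


def droplet_diameter(mass: float, density: float) -> float:
    """Equivalent sphere diameter d_d (mm) of a droplet of ``mass`` kg and
    ``density`` kg/m³: d_d = (6·m/(π·ρ))^(1/3)."""
    if not (mass > 0 and density > 0):
        raise ValidationError("mass and density must be > 0")
    return _sphere_diameter_mm(mass, density)


def correction_factor_sf(d_obs: float, d_d: float) -> float:
    """Gelation size-change factor K_SF = D/d_d (both mm)."""
    if not (d_obs > 0 and d_d > 0):
        raise ValidationError("diameters must be > 0")
    return d_obs / d_d


def calibrate(
    pairs: Sequence[tuple[float, DropletMeasurement | float]],
    nozzle: NozzleSpec | float,
) -> CorrectionFactors:
    """Pool a single K_SF over (observed diameter, droplet) pairs.

    Each pair is (d_obs in mm, droplet) where the droplet is either a
    :class:`DropletMeasurement` or a pre-computed d_d in mm.  K_SF is the
    arithmetic mean of the per-pair ratios d_obs/d_d; K_LF comes from the
    nozzle correlation.
    """
    if len(pairs) == 0:
        raise ValidationError("calibration needs at least one pair")
    ratios = []
    for d_obs, drop in pairs:
        d_d = drop.diameter if isinstance(drop, DropletMeasurement) else float(drop)
        ratios.append(correction_factor_sf(d_obs, d_d))
    return CorrectionFactors(
        k_lf=correction_factor_lf(nozzle), k_sf=float(np.mean(ratios))
    )


def per_condition_factors(
    pairs: Sequence[tuple[float, DropletMeasurement | float]],
    nozzle: NozzleSpec | float,
) -> list[CorrectionFactors]:
    """Per-pair correction factors (no pooling), for per-condition checks."""
    k_lf = correction_factor_lf(nozzle)
    out = []
    for d_obs, drop in pairs:
        d_d = drop.diameter if isinstance(drop, DropletMeasurement) else float(drop)
        out.append(CorrectionFactors(k_lf=k_lf, k_sf=correction_factor_sf(d_obs, d_d)))
    return out


def predict_diameter(
    nozzle: NozzleSpec | float,
    surface_tension: float,
    density: float,
    factors: CorrectionFactors | float,
) -> float:
    """Predicted capsule diameter d_p = K·(6·d_t·γ/(ρ·g))^(1/3), in mm.

    Inputs are bench-unit: d_t in mm, γ in mN/m, ρ in kg/m³; the cube root
    is evaluated in SI and converted back.
    """
    d_t = _dt_mm(nozzle)
    g = (
        nozzle.gravitational_acceleration
        if isinstance(nozzle, NozzleSpec)
        else NozzleSpec(d_t).gravitational_acceleration
    )
    if not (d_t > 0 and surface_tension > 0 and density > 0):
        raise ValidationError("nozzle diameter, surface tension and density must be > 0")
    k = factors.k if isinstance(factors, CorrectionFactors) else float(factors)
    d_t_m = d_t / 1000.0
    gamma_nm = surface_tension / 1000.0
    d_p_m = k * (6.0 * d_t_m * gamma_nm / (density * g)) ** (1.0 / 3.0)
    return d_p_m * 1000.0


def validate(pairs: Iterable[tuple[float, float]]) -> ValidationReport:
    """AAD/MAD of (predicted, observed) diameter pairs, in %.

    AAD = mean of |d_p − d_obs|/d_p × 100 over pairs; MAD is the maximum of
    the same per-pair percentages.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("validation needs at least one pair")
    devs = []
    for d_p, d_obs in pairs:
        if not (d_p > 0):
            raise ValidationError(f"predicted diameter must be > 0, got {d_p}")
        devs.append(abs(d_p - d_obs) / d_p * 100.0)
    devs = np.asarray(devs)
    return ValidationReport(aad=float(devs.mean()), mad=float(devs.max()), n=len(devs))


__all__ = [
    "CorrectionFactors",
    "PredictionRecord",
    "ValidationReport",
    "correction_factor_lf",
    "droplet_diameter",
    "correction_factor_sf",
    "calibrate",
    "per_condition_factors",
    "predict_diameter",
    "validate",
]
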