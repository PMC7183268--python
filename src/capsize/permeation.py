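"""Glucose-uptake kinetics through the capsule membrane.

Absorbance readings from the DNS (dinitrosalicylic acid) reducing-sugar
assay are converted to concentration via a linear standard curve.  The
bulk-depletion time series — glucose diffusing from a well-mixed bath into
many identical hollow capsules — is fitted with a single-exponential
approach to equilibrium:

    C(t) = c_eq + (c0 − c_eq) · exp(−k·t)

the solution of first-order membrane-limited exchange between two
well-mixed compartments.  The rate constant k (1/s) sets the half-time
t½ = ln2/k, and the initial uptake rate is −k·(c0 − c_eq).  Deformed
capsules (SF ≥ 0.07) have locally thin walls and show a faster initial
permeation rate and shorter equilibration than spherical ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import UptakeSeries, ValidationError

logger = logging.getLogger("capsize")


@dataclass(frozen=True)
class StandardCurve:
    """Linear DNS standard: concentration = slope·A540 + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not (self.slope > 0):
            raise ValidationError(
                f"a valid DNS standard has positive slope, got {self.slope}"
            )

    def concentration(self, absorbance: float) -> float:
        return self.slope * absorbance + self.intercept

    def absorbance(self, concentration: float) -> float:
        return (concentration - self.intercept) / self.slope


@dataclass(frozen=True)
class UptakeFit:
    """First-order depletion fit: c0, c_eq (mg/mL), k (1/s), t½ = ln2/k."""

    c0: float
    c_eq: float
    k: float

    def __post_init__(self):
        if self.k < 0:
            raise ValidationError(f"rate constant must be ≥ 0, got {self.k}")
        if not (self.c0 >= self.c_eq >= 0):
            raise ValidationError(
                f"depletion needs c0 ≥ c_eq ≥ 0, got c0={self.c0}, c_eq={self.c_eq}"
            )

    @property
    def half_time(self) -> float:
        """Time to cover half the distance to equilibrium, s (inf if k = 0)."""
        return math.log(2.0) / self.k if self.k > 0 else math.inf

    @property
    def initial_rate(self) -> float:
        """Model slope at t = 0: −k·(c0 − c_eq), mg/mL per s (≤ 0)."""
        return -self.k * (self.c0 - self.c_eq)

    def concentration(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c_eq + (self.c0 - self.c_eq) * np.exp(-self.k * t)


@dataclass(frozen=True)
class PermeationComparison:
    """Mean kinetics per shape class and which class permeates faster."""

    mean_rate_spherical: float
    mean_rate_deformed: float
    mean_half_time_spherical: float
    mean_half_time_deformed: float
    ordering: str  # "deformed faster" | "spherical faster" | "tie"


def dns_calibrate(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares line through (absorbance, concentration) standards."""
    if len(standards) < 2:
        raise ValidationError("need at least 2 standards")
    a = np.array([s[0] for s in standards], dtype=float)
    c = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(a) == 0:
        raise ValidationError("degenerate standards: all absorbances identical")
    if len(standards) == 2:
        slope = (c[1] - c[0]) / (a[1] - a[0])
        return StandardCurve(slope=float(slope),
                             intercept=float(c[0] - slope * a[0]), r_squared=1.0)
    res = stats.linregress(a, c)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def _model(t, c0, c_eq, k):
    return c_eq + (c0 - c_eq) * np.exp(-k * t)


def fit_uptake(series: UptakeSeries) -> UptakeFit:
    """Nonlinear least-squares fit of the first-order depletion model.

    Initial guesses: c0 from the first sample, c_eq from the last, k from a
    log-linear regression of (C − c_eq_guess).  A constant series is the
    k = 0 degenerate case and returns c_eq = c0 directly.
    """
    if len(series) < 4:
        raise ValidationError("need at least 4 time points")
    t = series.time
    c = series.concentration
    if np.ptp(c) == 0:
        return UptakeFit(c0=float(c[0]), c_eq=float(c[0]), k=0.0)
    c0_g = float(c[0])
    ceq_g = float(c[-1])
    # log-linear k guess on the decaying excess; guard the log
    excess = c - ceq_g + 1e-3 * max(c0_g - ceq_g, 1e-12)
    good = excess > 0
    if good.sum() >= 2:
        k_g = max(1e-12, -float(np.polyfit(t[good], np.log(excess[good]), 1)[0]))
    else:
        k_g = 1.0 / max(t[-1], 1e-12)
    try:
        popt, _ = optimize.curve_fit(
            _model, t, c, p0=[c0_g, ceq_g, k_g],
            bounds=([0, 0, 0], [np.inf, np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise ValidationError(
            f"uptake fit did not converge (initial guess c0={c0_g:.4g}, "
            f"c_eq={ceq_g:.4g}, k={k_g:.4g}): {exc}"
        ) from None
    c0, c_eq, k = (float(v) for v in popt)
    if c_eq > c0:  # fitter found growth; clamp to the depletion contract
        c0, c_eq = max(c0, c_eq), min(c0, c_eq)
    return UptakeFit(c0=c0, c_eq=c_eq, k=k)


def initial_rate(series: UptakeSeries, window: int = 3) -> float:
    """Least-squares slope over the first ``window`` samples, mg/mL per s.

    Negative for depletion; the two-point case reduces to a difference
    quotient.
    """
    if window < 2:
        raise ValidationError("window must be ≥ 2 points")
    if window > len(series):
        raise ValidationError(
            f"window {window} exceeds series length {len(series)}"
        )
    t = series.time[:window]
    c = series.concentration[:window]
    if window == 2:
        return float((c[1] - c[0]) / (t[1] - t[0]))
    return float(stats.linregress(t, c).slope)


def compare_permeation(
    spherical: Sequence[UptakeFit], deformed: Sequence[UptakeFit]
) -> PermeationComparison:
    """Contrast mean initial rate and half-time between shape classes.

    "Faster" means larger initial uptake-rate magnitude; equal magnitudes
    (to 1 part in 10⁹) are a tie.
    """
    if not spherical or not deformed:
        raise ValidationError("both classes must be non-empty")
    rate_s = float(np.mean([f.initial_rate for f in spherical]))
    rate_d = float(np.mean([f.initial_rate for f in deformed]))
    ht_s = float(np.mean([f.half_time for f in spherical]))
    ht_d = float(np.mean([f.half_time for f in deformed]))
    ms, md = abs(rate_s), abs(rate_d)
    if math.isclose(ms, md, rel_tol=1e-9, abs_tol=1e-15):
        ordering = "tie"
    elif md > ms:
        ordering = "deformed faster"
    else:
        ordering = "spherical faster"
    return PermeationComparison(
        mean_rate_spherical=rate_s,
        mean_rate_deformed=rate_d,
        mean_half_time_spherical=ht_s,
        mean_half_time_deformed=ht_d,
        ordering=ordering,
    )


__all__ = [
    "StandardCurve",
    "UptakeFit",
    "PermeationComparison",
    "dns_calibrate",
    "fit_uptake",
    "initial_rate",
    "compare_permeation",
]
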