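"""Synthetic study generator: every input the pipeline consumes.

The generator emulates the statistical structure of a dripping-extrusion
capsule study so that every stage is testable end to end without lab data:

* solution viscosity rises exponentially with concentration, anchored so
  the printed endpoints are hit exactly (SA: 16.2 mPa·s at 0.25 wt.% to
  516.0 at 1.25; CaCl₂/CMC: 20.0 at 0.5 wt.% to 917.5 at 1.5);
* surface tension falls with surfactant dose — piecewise log-linear with a
  critical-micelle plateau at 37 mN/m for Tween 80, a smooth exponential
  decay without a sharp CMC for poloxamer 407;
* droplet masses follow the Tate detachment balance.  K_LF corrects the
  *diameter* of the detached drop, so the detached mass is
  K_LF³·π·d_t·γ/g, with multiplicative noise (default 1%);
* per-capsule diameters scatter multiplicatively around the condition mean
  (default SD 2% of the mean, matching the 1–4% batch dispersion of the
  measured grids), with the sphericity factor inverted exactly so that a
  noiseless batch reproduces its target SF;
* compression curves follow the Reissner linear response in the 0–1 mm
  window, stiffen smoothly to an optional rupture point, then drop 50%;
* uptake series follow the first-order depletion model.

All randomness flows from one ``numpy.random.Generator``; the same seed and
design give byte-identical output files.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import datasets
from .core import (
    CapsuleBatch,
    CapsuleMeasurement,
    DropletMeasurement,
    ForceCurve,
    NozzleSpec,
    SolutionProperties,
    SolutionRole,
    UptakeSeries,
    ValidationError,
    write_capsule_table,
    write_force_curve,
    write_solution_table,
    write_uptake_series,
)
from .tate import correction_factor_lf

# Exponential viscosity anchors (concentration wt.%, viscosity mPa·s) and
# densities (kg/m³) of the two solution families.
_SOLUTION_ANCHORS = {
    "SA": {
        "anchors": ((0.25, 16.2), (1.25, 516.0)),
        "density": 1055.0,
        "surface_tension": 47.01,
        "role": SolutionRole.BATH,
    },
    "CaCl2_CMC": {
        "anchors": ((0.5, 20.0), (1.5, 917.5)),
        "density": 1065.0,
        "surface_tension": 63.41,
        "role": SolutionRole.CORE,
    },
}

# Tween 80 tension anchors: dose g/L → mN/m; log-linear between the measured
# points, plateau at the apparent critical micelle dose.
_TWEEN_ZERO_DOSE_TENSION = 63.41
_TWEEN_ANCHOR_LO = (0.015, 49.01)
_TWEEN_ANCHOR_HI = (0.075, 37.0)

# Poloxamer 407: smooth decay from the bare-SA tension toward a plateau,
# anchored at (0.1 wt.%, 41.71 mN/m); no sharp CMC.
_POLOXAMER_ZERO_DOSE_TENSION = 47.01
_POLOXAMER_PLATEAU = 37.0
_POLOXAMER_ANCHOR = (0.1, 41.71)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_solution_series(kind: str, concentrations) -> list[SolutionProperties]:
    """Solution-property table for a concentration series.

    ``kind`` is ``"SA"`` (gelation bath) or ``"CaCl2_CMC"`` (drop core).
    Viscosity follows a·exp(b·c) through the two anchor points, so both
    printed endpoints are reproduced exactly; concentrations outside the
    anchored range extrapolate with a warning.
    """
    if kind not in _SOLUTION_ANCHORS:
        raise ValidationError(f"unknown solution kind {kind!r}")
    spec = _SOLUTION_ANCHORS[kind]
    (c1, v1), (c2, v2) = spec["anchors"]
    b = math.log(v2 / v1) / (c2 - c1)
    a = v1 / math.exp(b * c1)
    out = []
    for c in concentrations:
        if not (c1 <= c <= c2):
            warnings.warn(
                f"{kind} concentration {c} wt.% outside the anchored range "
                f"[{c1}, {c2}]; viscosity is an extrapolation",
                stacklevel=2,
            )
        out.append(
            SolutionProperties(
                solute_concentration=float(c),
                viscosity=a * math.exp(b * float(c)),
                surface_tension=spec["surface_tension"],
                density=spec["density"],
                role=spec["role"],
            )
        )
    return out


def gen_surface_tension(surfactant: str, dose: float) -> float:
    """Surface tension (mN/m) of a solution at the given surfactant dose.

    ``tween80`` (dose in g/L): log-linear decay through the measured points,
    flat at 37 mN/m above 0.075 g/L — the plateau above the critical micelle
    concentration.  ``poloxamer407`` (dose in wt.%): smooth exponential
    decay toward 37 mN/m with no sharp break, anchored at (0.1, 41.71).
    """
    if dose < 0:
        raise ValidationError(f"dose must be ≥ 0, got {dose}")
    if surfactant == "tween80":
        if dose == 0:
            return _TWEEN_ZERO_DOSE_TENSION
        (d_lo, g_lo), (d_hi, g_hi) = _TWEEN_ANCHOR_LO, _TWEEN_ANCHOR_HI
        if dose >= d_hi:
            return g_hi
        slope = (g_hi - g_lo) / (math.log(d_hi) - math.log(d_lo))
        g = g_lo + slope * (math.log(dose) - math.log(d_lo))
        return min(g, _TWEEN_ZERO_DOSE_TENSION)
    if surfactant == "poloxamer407":
        g0, g_inf = _POLOXAMER_ZERO_DOSE_TENSION, _POLOXAMER_PLATEAU
        d_a, g_a = _POLOXAMER_ANCHOR
        tau = -d_a / math.log((g_a - g_inf) / (g0 - g_inf))
        return g_inf + (g0 - g_inf) * math.exp(-dose / tau)
    raise ValidationError(f"unknown surfactant {surfactant!r}")


def tate_detachment_mass(nozzle: NozzleSpec, surface_tension: float) -> float:
    """Mean detached-drop mass (kg) from the Tate balance with residual-liquid
    correction: K_LF³·π·d_t·γ/g (γ in mN/m, d_t in mm).

    K_LF rescales the drop *diameter*, hence the cube on the mass.
    """
    k_lf = correction_factor_lf(nozzle)
    d_t_m = nozzle.outer_diameter / 1000.0
    gamma_nm = surface_tension / 1000.0
    return k_lf**3 * math.pi * d_t_m * gamma_nm / nozzle.gravitational_acceleration


def gen_droplets(
    nozzle: NozzleSpec,
    surface_tension: float,
    density: float,
    n: int,
    sigma: float = 0.01,
    rng=None,
) -> list[DropletMeasurement]:
    """n weighed droplets with multiplicative mass noise of SD ``sigma``."""
    if n < 1:
        raise ValidationError("n must be ≥ 1")
    rng = _rng(rng)
    m0 = tate_detachment_mass(nozzle, surface_tension)
    eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    return [DropletMeasurement(mass=m0 * (1.0 + e), density=density) for e in eps]


def gen_capsule_batch(
    true_d: float,
    true_sf: float,
    n: int = 15,
    sigma: float = 0.02,
    rng=None,
    batch_id: str = "synthetic",
) -> CapsuleBatch:
    """A capsule batch with target diameter and sphericity factor.

    d_min = true_d·(1+ε₁); the SF is jittered multiplicatively and inverted
    exactly, d_max = d_min·(1+s)/(1−s) with s = true_sf·(1+ε₂), so a
    noiseless batch has SF = true_sf for every capsule.
    """
    if not (0 <= true_sf < 1):
        raise ValidationError(f"true_sf must lie in [0, 1), got {true_sf}")
    if not (true_d > 0):
        raise ValidationError(f"true_d must be > 0, got {true_d}")
    rng = _rng(rng)
    caps = []
    for _ in range(n):
        e1, e2 = (rng.normal(0.0, sigma, size=2) if sigma > 0 else (0.0, 0.0))
        d_min = true_d * (1.0 + e1)
        s = min(max(true_sf * (1.0 + e2), 0.0), 0.999)
        d_max = d_min * (1.0 + s) / (1.0 - s)
        caps.append(CapsuleMeasurement(d_max=d_max, d_min=d_min, batch_id=batch_id))
    return CapsuleBatch(capsules=tuple(caps), batch_id=batch_id)


def gen_force_curve(
    e_s: float,
    h: float = 0.20,
    r: float = 2.0,
    poisson_ratio: float = 0.5,
    rupture: tuple[float, float] | None = None,
    sigma: float = 0.0,
    rng=None,
    step: float = 0.03,
    max_displacement: float = 3.0,
) -> ForceCurve:
    """A compression curve with the given true surface modulus.

    Linear Reissner response up to 1 mm, then a smooth quadratic stiffening
    toward ``rupture`` = (force N, displacement mm) if given, followed by a
    50% force drop; multiplicative force noise of SD ``sigma``.
    """
    if not (e_s >= 0 and h > 0 and r > 0):
        raise ValidationError("e_s must be ≥ 0; h and r must be > 0")
    factor = math.sqrt(3.0 * (1.0 - poisson_ratio**2))
    slope = 4.0 * e_s * h / (r * factor) / 1000.0  # N per mm
    lin_end = 1.0
    if rupture is not None:
        f_r, d_r = rupture
        if d_r <= lin_end:
            raise ValidationError(
                f"rupture displacement {d_r} mm must exceed the linear "
                f"window end {lin_end} mm"
            )
        f1 = slope * lin_end
        if f_r < f1 + slope * (d_r - lin_end):
            raise ValidationError(
                "rupture force below the extrapolated linear response; "
                "the stiffening segment would not be monotone"
            )
        curvature = (f_r - f1 - slope * (d_r - lin_end)) / (d_r - lin_end) ** 2
        d_end = d_r + 0.3
    else:
        d_end = max_displacement
    disp = np.arange(0.0, d_end + step / 2, step)
    force = np.empty_like(disp)
    for i, d in enumerate(disp):
        if d <= lin_end or rupture is None:
            force[i] = slope * d
        elif d <= d_r:
            force[i] = slope * lin_end + slope * (d - lin_end) + curvature * (d - lin_end) ** 2
        else:
            force[i] = 0.5 * f_r * math.exp(-(d - d_r))  # post-rupture collapse
    if sigma > 0:
        force = force * (1.0 + _rng(rng).normal(0.0, sigma, size=force.size))
    return ForceCurve(
        displacement=disp, force=force,
        membrane_thickness=h, radius=r, poisson_ratio=poisson_ratio,
    )


def gen_uptake_series(
    c0: float,
    c_eq: float,
    k: float,
    times,
    sigma: float = 0.0,
    rng=None,
) -> UptakeSeries:
    """First-order bulk-depletion series C(t) = c_eq + (c0−c_eq)e^(−kt)
    with multiplicative noise of SD ``sigma`` (clipped at 0)."""
    if not (c0 >= c_eq >= 0):
        raise ValidationError(f"need c0 ≥ c_eq ≥ 0, got c0={c0}, c_eq={c_eq}")
    if k < 0:
        raise ValidationError(f"k must be ≥ 0, got {k}")
    t = np.asarray(times, dtype=float)
    c = c_eq + (c0 - c_eq) * np.exp(-k * t)
    if sigma > 0:
        c = np.clip(c * (1.0 + _rng(rng).normal(0.0, sigma, size=c.size)), 0.0, None)
    return UptakeSeries(time=t, concentration=c)


# ---------------------------------------------------------------------------
# prediction study (droplet → capsule pairs for calibrate/predict/validate)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionStudy:
    """Synthetic (observed capsule, droplet) pairs across surface tensions.

    ``pairs[i]`` = (d_obs mm, DropletMeasurement); ``surface_tensions[i]``
    is the condition's γ in mN/m.  ``k_sf_true`` is the gelation factor the
    observations were built with.
    """

    pairs: tuple[tuple[float, DropletMeasurement], ...]
    surface_tensions: np.ndarray
    density: float
    nozzle: NozzleSpec
    k_sf_true: float


def gen_prediction_study(
    n: int = 500,
    seed=0,
    gamma_range: tuple[float, float] = (36.0, 64.0),
    density: float = 1065.0,
    nozzle: NozzleSpec = NozzleSpec(1.06),
    k_sf_true: float = 1.3,
    sigma_mass: float = 0.01,
    sigma_d: float = 0.02,
) -> PredictionStudy:
    """Draw n capsule-condition pairs for end-to-end model validation.

    Each condition draws a surface tension uniformly from ``gamma_range``
    (the span surfactant dosing can reach), a droplet mass from the Tate
    balance with ``sigma_mass`` noise, and an observed capsule diameter
    d_obs = k_sf_true·d_d·(1 + ε) with multiplicative ``sigma_d`` noise.
    """
    rng = _rng(seed)
    gammas = rng.uniform(*gamma_range, size=n)
    pairs = []
    for g in gammas:
        m0 = tate_detachment_mass(nozzle, float(g))
        eps_m = rng.normal(0.0, sigma_mass) if sigma_mass > 0 else 0.0
        drop = DropletMeasurement(mass=m0 * (1.0 + eps_m), density=density)
        eps_d = rng.normal(0.0, sigma_d) if sigma_d > 0 else 0.0
        d_obs = k_sf_true * drop.diameter * (1.0 + eps_d)
        pairs.append((float(d_obs), drop))
    return PredictionStudy(
        pairs=tuple(pairs),
        surface_tensions=gammas,
        density=density,
        nozzle=nozzle,
        k_sf_true=k_sf_true,
    )


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Conditions and noise levels of a full synthetic study.

    Defaults reproduce the measured study layout: 5×5 viscosity grid with
    the 20.0 mPa·s core row unformed, 15 capsules per condition, 2%
    multiplicative diameter noise, 1% droplet-mass noise.
    """

    sa_concentrations: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0, 1.25)
    cmc_concentrations: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    n_capsules: int = 15
    sigma_diameter: float = 0.02
    sigma_mass: float = 0.01
    sigma_force: float = 0.02
    sigma_uptake: float = 0.01
    n_droplet_conditions: int = 20
    gamma_range: tuple[float, float] = (36.0, 64.0)
    k_sf_true: float = 1.3
    nozzle: NozzleSpec = field(default_factory=lambda: NozzleSpec(1.06))
    # mechanics truths: spherical vs deformed surface moduli (N/m) and the
    # spherical-class rupture point (N, mm); deformed capsules rupture early
    # and erratically, so their synthetic curve gets no crushing event.
    e_s_spherical: tuple[float, ...] = (146.1, 139.4)
    e_s_deformed: tuple[float, ...] = (50.1,)
    rupture_spherical: tuple[float, float] = (18.1, 3.96)
    # uptake truths: 20 mg/mL bulk start, equilibrium from the bulk/capsule
    # volume balance, deformed membranes leak ~3× faster
    c0: float = 20.0
    c_eq: float = 16.8
    k_spherical: float = 5.0e-4
    k_deformed: float = 1.5e-3
    uptake_times: tuple[float, ...] = tuple(float(t) for t in range(0, 7501, 300))
    seed: int = 0


def gen_study(design: StudyDesign, out_dir) -> dict:
    """Write the full synthetic file set and a manifest of true parameters.

    Produces solutions.csv, capsules.csv, droplets.csv, per-class force
    curves and uptake series, plus manifest.json recording every true
    parameter for recovery tests.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(design.seed)

    # solutions ------------------------------------------------------------
    sa = gen_solution_series("SA", design.sa_concentrations)
    cmc = gen_solution_series("CaCl2_CMC", design.cmc_concentrations)
    write_solution_table(sa + cmc, out / "solutions.csv")

    # capsule batches on the measured condition grid -----------------------
    sf_grid = datasets.sphericity_grid()
    d_grid = datasets.diameter_grid()
    batches = []
    conditions = []
    for i, core_v in enumerate(sf_grid.core_viscosities):
        for j, bath_v in enumerate(sf_grid.bath_viscosities):
            true_sf = float(sf_grid.values[i, j])
            true_d = float(d_grid.values[i, j])
            if math.isnan(true_sf) or math.isnan(true_d):
                continue
            bid = f"core{core_v:g}_bath{bath_v:g}"
            batches.append(
                gen_capsule_batch(
                    true_d=true_d, true_sf=true_sf, n=design.n_capsules,
                    sigma=design.sigma_diameter, rng=rng, batch_id=bid,
                )
            )
            conditions.append(
                {"batch_id": bid, "core_viscosity_mpas": float(core_v),
                 "bath_viscosity_mpas": float(bath_v),
                 "true_sf": true_sf, "true_d_mm": true_d}
            )
    write_capsule_table(batches, out / "capsules.csv")

    # droplet/observation pairs for Tate-model validation ------------------
    study = gen_prediction_study(
        n=design.n_droplet_conditions,
        seed=rng,
        gamma_range=design.gamma_range,
        nozzle=design.nozzle,
        k_sf_true=design.k_sf_true,
        sigma_mass=design.sigma_mass,
        sigma_d=design.sigma_diameter,
    )
    with open(out / "droplets.csv", "w") as fh:
        fh.write("condition_id,surface_tension_mnm,density_kgm3,mass_kg,d_obs_mm\n")
        for i, ((d_obs, drop), g) in enumerate(
            zip(study.pairs, study.surface_tensions)
        ):
            fh.write(
                f"c{i},{repr(float(g))},{repr(float(drop.density))},"
                f"{repr(float(drop.mass))},{repr(float(d_obs))}\n"
            )

    # force curves ---------------------------------------------------------
    force_files = {"spherical": [], "deformed": []}
    for cls, moduli, rupture in (
        ("spherical", design.e_s_spherical, design.rupture_spherical),
        ("deformed", design.e_s_deformed, None),
    ):
        for idx, e_s in enumerate(moduli):
            curve = gen_force_curve(
                e_s=e_s, rupture=rupture,
                sigma=design.sigma_force, rng=rng,
            )
            name = f"force_{cls}_{idx}.csv"
            write_force_curve(curve, out / name)
            force_files[cls].append(name)

    # uptake series --------------------------------------------------------
    for cls, k in (("spherical", design.k_spherical),
                   ("deformed", design.k_deformed)):
        series = gen_uptake_series(
            design.c0, design.c_eq, k, design.uptake_times,
            sigma=design.sigma_uptake, rng=rng,
        )
        write_uptake_series(series, out / f"uptake_{cls}.csv")

    manifest = {
        "seed": design.seed,
        "n_capsules_per_condition": design.n_capsules,
        "sigma_diameter": design.sigma_diameter,
        "sigma_mass": design.sigma_mass,
        "sigma_force": design.sigma_force,
        "sigma_uptake": design.sigma_uptake,
        "nozzle_od_mm": design.nozzle.outer_diameter,
        "k_lf_true": correction_factor_lf(design.nozzle),
        "k_sf_true": design.k_sf_true,
        "conditions": conditions,
        "e_s_true": {"spherical": list(design.e_s_spherical),
                     "deformed": list(design.e_s_deformed)},
        "rupture_spherical": list(design.rupture_spherical),
        "uptake_true": {"c0": design.c0, "c_eq": design.c_eq,
                        "k_spherical": design.k_spherical,
                        "k_deformed": design.k_deformed},
        "files": {
            "solutions": "solutions.csv",
            "capsules": "capsules.csv",
            "droplets": "droplets.csv",
            "force_curves": force_files,
            "uptake": {"spherical": "uptake_spherical.csv",
                       "deformed": "uptake_deformed.csv"},
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


__all__ = [
    "StudyDesign",
    "PredictionStudy",
    "gen_solution_series",
    "gen_surface_tension",
    "tate_detachment_mass",
    "gen_droplets",
    "gen_capsule_batch",
    "gen_force_curve",
    "gen_uptake_series",
    "gen_prediction_study",
    "gen_study",
]
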