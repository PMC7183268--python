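"""Shared domain types, unit conventions and CSV I/O.

The public API speaks bench units throughout: lengths in mm, forces in N,
surface tension in mN/m, viscosity in mPa·s, density in kg/m³, glucose
concentration in mg/mL and solute concentration in wt.% (or g/L for
surfactant doses).  Physics routines convert to SI internally and convert
back before returning.

CSV layouts accepted by the readers:

* capsules        — ``batch_id,d_max_mm,d_min_mm``
* solutions       — ``role,concentration,viscosity_mpas,surface_tension_mnm,density_kgm3``
* force curve     — ``displacement_mm,force_n``
* uptake          — ``time_s,concentration_mgml``
* condition grid  — first column ``core_viscosity_mpas``; remaining column
  headers are bath viscosities in mPa·s; cells numeric or empty (a capsule
  batch that never formed is an *empty* cell, never 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("capsize")

#: Standard gravitational acceleration used by the droplet force balance, m/s².
STANDARD_GRAVITY = 9.81

MM_PER_M = 1000.0


class ValidationError(ValueError):
    """An input violates a domain-type invariant.

    Reader errors carry ``row`` (1-based data-row index) so a bad cell in a
    long table can be located without re-parsing.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round with ties away from zero, matching how bench tables are printed.

    Python's built-in ``round`` is banker's rounding; printed capsule tables
    use half-up (3.2125 mm → 3.213 mm).
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _sphere_diameter_mm(mass_kg: float, density_kgm3: float) -> float:
    """Diameter (mm) of a sphere of the given mass and density."""
    volume = mass_kg / density_kgm3
    return (6.0 * volume / math.pi) ** (1.0 / 3.0) * MM_PER_M


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CapsuleMeasurement:
    """One capsule's caliper measurement.

    ``d_max`` is the longest diameter and ``d_min`` the shortest diameter
    perpendicular to it, both in mm.  By convention the capsule *diameter* D
    is ``d_min``.
    """

    d_max: float
    d_min: float
    batch_id: str = ""

    def __post_init__(self):
        if not (self.d_min > 0):
            raise ValidationError(f"d_min must be > 0, got {self.d_min}")
        if self.d_max < self.d_min:
            raise ValidationError(
                f"d_max ({self.d_max}) < d_min ({self.d_min})"
            )

    @property
    def d(self) -> float:
        """Capsule diameter D ≡ d_min, mm."""
        return self.d_min


class SolutionRole(str, Enum):
    """Which side of the gelation interface a solution sits on."""

    BATH = "bath"   # sodium-alginate gelation bath (outer phase)
    CORE = "core"   # CaCl₂/CMC drop solution (inner phase)


@dataclass(frozen=True)
class SolutionProperties:
    """Bulk properties of one SA or CaCl₂/CMC solution.

    concentration in wt.% (g/L for surfactant doses), viscosity in mPa·s,
    surface tension in mN/m, density in kg/m³.
    """

    solute_concentration: float
    viscosity: float
    surface_tension: float
    density: float
    role: SolutionRole = SolutionRole.CORE

    def __post_init__(self):
        for name in ("solute_concentration", "viscosity", "surface_tension", "density"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValidationError(f"{name} must be > 0, got {v}")
        if not (900.0 <= self.density <= 1300.0):
            raise ValidationError(
                f"density {self.density} kg/m³ outside the plausible aqueous "
                "range [900, 1300]"
            )


@dataclass(frozen=True)
class CapsuleBatch:
    """Capsules produced under one (bath, core) solution condition."""

    capsules: tuple[CapsuleMeasurement, ...]
    batch_id: str = ""
    condition: tuple[SolutionProperties, SolutionProperties] | None = None

    def __post_init__(self):
        if len(self.capsules) == 0:
            raise ValidationError(f"batch {self.batch_id!r} is empty")
        object.__setattr__(self, "capsules", tuple(self.capsules))

    def __len__(self) -> int:
        return len(self.capsules)


@dataclass(frozen=True)
class NozzleSpec:
    """Dripping-nozzle geometry.  ``outer_diameter`` (d_t) in mm."""

    outer_diameter: float
    gravitational_acceleration: float = STANDARD_GRAVITY

    def __post_init__(self):
        if not (self.outer_diameter > 0):
            raise ValidationError(
                f"nozzle outer_diameter must be > 0, got {self.outer_diameter}"
            )


@dataclass(frozen=True)
class DropletMeasurement:
    """A weighed detached droplet; diameter follows from the sphere assumption."""

    mass: float      # kg
    density: float   # kg/m³

    def __post_init__(self):
        if not (self.mass > 0 and self.density > 0):
            raise ValidationError("droplet mass and density must be > 0")

    @property
    def volume(self) -> float:
        """Droplet volume, m³."""
        return self.mass / self.density

    @property
    def diameter(self) -> float:
        """Equivalent sphere diameter d_d, mm."""
        return _sphere_diameter_mm(self.mass, self.density)


@dataclass(frozen=True)
class ForceCurve:
    """A parallel-plate compression record for one capsule.

    displacement in mm (strictly increasing from ≥ 0), force in N.
    ``membrane_thickness`` h and ``radius`` r in mm; ``poisson_ratio`` is the
    surface Poisson ratio ν_s of the membrane (1/2 for alginate hydrogel).
    """

    displacement: np.ndarray
    force: np.ndarray
    membrane_thickness: float = 0.20
    radius: float = 2.0
    poisson_ratio: float = 0.5

    def __post_init__(self):
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if d.shape != f.shape or d.ndim != 1:
            raise ValidationError("displacement and force must be 1-D and equal length")
        if d.size and d[0] < 0:
            raise ValidationError("displacement must start at ≥ 0")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("displacement must be strictly increasing")
        if not (self.membrane_thickness > 0 and self.radius > 0):
            raise ValidationError("membrane thickness and radius must be > 0")
        if not (0 <= self.poisson_ratio < 1):
            raise ValidationError("poisson_ratio must lie in [0, 1)")
        if np.any(f < 0):
            logger.warning(
                "force curve contains %d negative force value(s); keeping them "
                "(post-rupture load-cell artifacts)",
                int(np.sum(f < 0)),
            )

    def __len__(self) -> int:
        return int(self.displacement.size)


@dataclass(frozen=True)
class UptakeSeries:
    """Bulk glucose concentration vs time during uptake through the membrane."""

    time: np.ndarray            # s, strictly increasing
    concentration: np.ndarray   # mg/mL

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "concentration", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValidationError("time and concentration must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("concentrations must be ≥ 0")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class ConditionGrid:
    """A (core viscosity × bath viscosity) grid of per-condition values.

    ``values[i, j]`` is the quantity measured at core viscosity
    ``core_viscosities[i]`` and bath viscosity ``bath_viscosities[j]``;
    NaN marks a condition where no capsule formed.
    """

    core_viscosities: np.ndarray   # mPa·s, rows
    bath_viscosities: np.ndarray   # mPa·s, columns
    values: np.ndarray             # 2-D, NaN = missing

    def __post_init__(self):
        rows = np.asarray(self.core_viscosities, dtype=float)
        cols = np.asarray(self.bath_viscosities, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "core_viscosities", rows)
        object.__setattr__(self, "bath_viscosities", cols)
        object.__setattr__(self, "values", vals)
        if vals.shape != (rows.size, cols.size):
            raise ValidationError(
                f"grid shape {vals.shape} does not match "
                f"{rows.size} rows × {cols.size} columns"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.core_viscosities, columns=self.bath_viscosities
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CAPSULE_COLS = ["batch_id", "d_max_mm", "d_min_mm"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(f"{path}: non-numeric value in column {c!r}", row=row)
        df[c] = pd.to_numeric(df[c])


def read_capsule_table(path) -> list[CapsuleBatch]:
    """Read a per-capsule caliper table, grouped into batches.

    Batches keep the order in which their ids first appear in the file.
    Rows violating d_max ≥ d_min > 0 raise :class:`ValidationError` naming
    the offending 1-based data row.
    """
    df = pd.read_csv(path, dtype={"batch_id": str}, float_precision="round_trip")
    _require_columns(df, _CAPSULE_COLS, path)
    _numeric(df, ["d_max_mm", "d_min_mm"], path)
    batches: dict[str, list[CapsuleMeasurement]] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            m = CapsuleMeasurement(
                d_max=float(rec.d_max_mm), d_min=float(rec.d_min_mm),
                batch_id=str(rec.batch_id),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}", row=i) from None
        batches.setdefault(m.batch_id, []).append(m)
    return [
        CapsuleBatch(capsules=tuple(caps), batch_id=bid)
        for bid, caps in batches.items()
    ]


def write_capsule_table(batches: Sequence[CapsuleBatch], path) -> None:
    rows = [
        {"batch_id": b.batch_id, "d_max_mm": repr(float(c.d_max)), "d_min_mm": repr(float(c.d_min))}
        for b in batches
        for c in b.capsules
    ]
    pd.DataFrame(rows, columns=_CAPSULE_COLS).to_csv(path, index=False)


def read_solution_table(path) -> list[SolutionProperties]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = ["role", "concentration", "viscosity_mpas", "surface_tension_mnm", "density_kgm3"]
    _require_columns(df, cols, path)
    _numeric(df, cols[1:], path)
    out = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                SolutionProperties(
                    solute_concentration=float(rec.concentration),
                    viscosity=float(rec.viscosity_mpas),
                    surface_tension=float(rec.surface_tension_mnm),
                    density=float(rec.density_kgm3),
                    role=SolutionRole(str(rec.role)),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: {exc}", row=i) from None
    return out


def write_solution_table(solutions: Sequence[SolutionProperties], path) -> None:
    rows = [
        {
            "role": s.role.value,
            "concentration": repr(float(s.solute_concentration)),
            "viscosity_mpas": repr(float(s.viscosity)),
            "surface_tension_mnm": repr(float(s.surface_tension)),
            "density_kgm3": repr(float(s.density)),
        }
        for s in solutions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_force_curve(
    path,
    membrane_thickness: float = 0.20,
    radius: float = 2.0,
    poisson_ratio: float = 0.5,
) -> ForceCurve:
    """Read a displacement/force compression record and attach shell geometry."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["displacement_mm", "force_n"], path)
    _numeric(df, ["displacement_mm", "force_n"], path)
    try:
        return ForceCurve(
            displacement=df["displacement_mm"].to_numpy(),
            force=df["force_n"].to_numpy(),
            membrane_thickness=membrane_thickness,
            radius=radius,
            poisson_ratio=poisson_ratio,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_force_curve(curve: ForceCurve, path) -> None:
    pd.DataFrame(
        {
            "displacement_mm": [repr(float(v)) for v in curve.displacement],
            "force_n": [repr(float(v)) for v in curve.force],
        }
    ).to_csv(path, index=False)


def read_uptake_series(path) -> UptakeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "concentration_mgml"], path)
    _numeric(df, ["time_s", "concentration_mgml"], path)
    try:
        return UptakeSeries(
            time=df["time_s"].to_numpy(),
            concentration=df["concentration_mgml"].to_numpy(),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_uptake_series(series: UptakeSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": [repr(float(v)) for v in series.time],
            "concentration_mgml": [repr(float(v)) for v in series.concentration],
        }
    ).to_csv(path, index=False)


def read_condition_grid(path) -> ConditionGrid:
    """Read a condition grid; empty cells mean "no capsule formed" (NaN)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "core_viscosity_mpas":
        raise ValidationError(
            f"{path}: first column must be 'core_viscosity_mpas', "
            f"got {df.columns[0]!r}"
        )
    try:
        cols = np.array([float(c) for c in df.columns[1:]])
    except ValueError:
        raise ValidationError(
            f"{path}: grid column headers must be numeric bath viscosities"
        ) from None
    rows = df["core_viscosity_mpas"].to_numpy(dtype=float)
    values = df.iloc[:, 1:].to_numpy(dtype=float)  # empty cells → NaN
    return ConditionGrid(core_viscosities=rows, bath_viscosities=cols, values=values)


def write_condition_grid(grid: ConditionGrid, path) -> None:
    df = pd.DataFrame(
        grid.values,
        columns=[repr(float(c)) for c in grid.bath_viscosities],
    )
    df = df.map(lambda v: "" if np.isnan(v) else repr(float(v)))
    df.insert(0, "core_viscosity_mpas", [repr(float(r)) for r in grid.core_viscosities])
    df.to_csv(path, index=False)


__all__ = [
    "STANDARD_GRAVITY",
    "ValidationError",
    "round_half_up",
    "CapsuleMeasurement",
    "CapsuleBatch",
    "SolutionProperties",
    "SolutionRole",
    "NozzleSpec",
    "DropletMeasurement",
    "ForceCurve",
    "UptakeSeries",
    "ConditionGrid",
    "read_capsule_table",
    "write_capsule_table",
    "read_solution_table",
    "write_solution_table",
    "read_force_curve",
    "write_force_curve",
    "read_uptake_series",
    "write_uptake_series",
    "read_condition_grid",
    "write_condition_grid",
]
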