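"""Bundled measured condition grids for worked examples and cross-checks.

Per-condition batch means (n = 15 capsules each) from an extrusion-dripping
study of millimeter-scale calcium-alginate capsules, on a 4 (formed core
viscosities) × 5 (bath viscosities) grid.  At core viscosity 20.0 mPa·s no
capsules formed at any bath viscosity — the drop deformed too severely on
impact — so that row is entirely missing (NaN).
"""

from __future__ import annotations

import numpy as np

from .core import ConditionGrid

#: Sodium-alginate bath viscosities, mPa·s (grid columns).
BATH_VISCOSITIES = (16.2, 33.6, 72.0, 148.5, 265.5)

#: CaCl₂/CMC core viscosities, mPa·s (grid rows).
CORE_VISCOSITIES = (20.0, 56.7, 168.5, 372.0, 917.5)

_NAN = float("nan")

_SF_MEAN = [
    [_NAN, _NAN, _NAN, _NAN, _NAN],
    [0.067, 0.086, 0.258, 0.394, 0.371],
    [0.032, 0.018, 0.153, 0.289, 0.323],
    [0.009, 0.006, 0.026, 0.230, 0.242],
    [0.009, 0.008, 0.002, 0.136, 0.219],
]

_SF_SD = [
    [_NAN, _NAN, _NAN, _NAN, _NAN],
    [0.026, 0.029, 0.011, 0.016, 0.024],
    [0.019, 0.011, 0.035, 0.012, 0.007],
    [0.006, 0.004, 0.022, 0.014, 0.011],
    [0.006, 0.008, 0.002, 0.009, 0.009],
]

_D_MEAN = [
    [_NAN, _NAN, _NAN, _NAN, _NAN],
    [4.769, 4.757, 3.951, 2.940, 3.131],
    [4.355, 4.243, 3.847, 3.336, 3.239],
    [4.271, 4.221, 4.323, 3.208, 3.167],
    [4.278, 4.170, 4.076, 3.597, 3.313],
]

_D_SD = [
    [_NAN, _NAN, _NAN, _NAN, _NAN],
    [0.137, 0.129, 0.087, 0.087, 0.150],
    [0.176, 0.109, 0.115, 0.074, 0.042],
    [0.071, 0.037, 0.176, 0.067, 0.065],
    [0.081, 0.072, 0.027, 0.054, 0.091],
]


def _grid(values) -> ConditionGrid:
    return ConditionGrid(
        core_viscosities=np.array(CORE_VISCOSITIES),
        bath_viscosities=np.array(BATH_VISCOSITIES),
        values=np.array(values, dtype=float),
    )


def sphericity_grid() -> ConditionGrid:
    """Batch-mean sphericity factor per (core, bath) viscosity condition."""
    return _grid(_SF_MEAN)


def sphericity_sd_grid() -> ConditionGrid:
    """Batch SD of the sphericity factor per condition."""
    return _grid(_SF_SD)


def diameter_grid() -> ConditionGrid:
    """Batch-mean capsule diameter D (mm) per condition."""
    return _grid(_D_MEAN)


def diameter_sd_grid() -> ConditionGrid:
    """Batch SD of the capsule diameter (mm) per condition."""
    return _grid(_D_SD)


__all__ = [
    "BATH_VISCOSITIES",
    "CORE_VISCOSITIES",
    "sphericity_grid",
    "sphericity_sd_grid",
    "diameter_grid",
    "diameter_sd_grid",
]
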