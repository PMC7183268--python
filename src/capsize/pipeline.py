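"""End-to-end pipeline: run every analysis stage on one file set.

A :class:`RunConfig` names the input files (typically a ``gen_study``
output directory) and the analysis thresholds; :func:`run_pipeline`
produces per-stage reports plus one combined JSON.  Reports carry the
package version and a hash of the effective config so a result can always
be traced to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, mechanics, permeation, shape, tate
from .core import (
    DropletMeasurement,
    NozzleSpec,
    ValidationError,
    read_capsule_table,
    read_force_curve,
    read_uptake_series,
)

logger = logging.getLogger("capsize")


@dataclass(frozen=True)
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Paths are interpreted relative to ``input_dir``; the default file names
    match what ``gen_study`` writes.
    """

    input_dir: str = "."
    output_dir: str = "reports"
    capsules: str = "capsules.csv"
    droplets: str = "droplets.csv"
    manifest: str = "manifest.json"
    sf_threshold: float = 0.07
    fit_window: tuple[float, float] = (0.0, 1.0)
    drop_fraction: float = 0.2
    membrane_thickness: float = 0.20
    nozzle_od: float = 1.06
    initial_rate_window: int = 3
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self):
        if not (0 < self.sf_threshold < 1):
            raise ValidationError("sf_threshold must lie in (0, 1)")
        if not (0 < self.drop_fraction < 1):
            raise ValidationError("drop_fraction must lie in (0, 1)")
        lo, hi = self.fit_window
        if not (0 <= lo < hi):
            raise ValidationError("fit_window must satisfy 0 ≤ lo < hi")
        object.__setattr__(self, "fit_window", (float(lo), float(hi)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "fit_window" in raw:
            raw["fit_window"] = tuple(raw["fit_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit_window"] = list(d["fit_window"])
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (paths excluded, so the
        same analysis run from two directories hashes identically)."""
        d = self.to_dict()
        for key in ("input_dir", "output_dir"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"version": __version__, "config_hash": config.config_hash()}


def run_pipeline(config: RunConfig) -> dict:
    """Run shape, prediction, mechanics and permeation stages; write reports.

    Returns the combined report dict (also written as ``combined.json``).
    Raises :class:`FileNotFoundError` / :class:`ValidationError` with the
    offending stage and path in the message.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    combined: dict = {"provenance": _provenance(config), "seed": config.seed}

    # --- shape stage ------------------------------------------------------
    capsules_path = in_dir / config.capsules
    if not capsules_path.exists():
        raise FileNotFoundError(f"shape stage: missing input {capsules_path}")
    batches = read_capsule_table(capsules_path)
    rows = []
    for b in batches:
        s = shape.batch_summary(b)
        rows.append(
            {
                "batch_id": b.batch_id,
                "n": s.n,
                "mean_sf": s.mean_sf,
                "sd_sf": s.sd_sf,
                "mean_d_mm": s.mean_d,
                "sd_d_mm": s.sd_d,
                "shape_class": shape.classify(s.mean_sf, config.sf_threshold).value,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "shape_summary.csv", index=False)
    n_spherical = sum(r["shape_class"] == "spherical" for r in rows)
    combined["shape"] = {
        "n_batches": len(rows),
        "n_spherical": n_spherical,
        "n_deformed": len(rows) - n_spherical,
        "sf_threshold": config.sf_threshold,
    }

    # --- Tate prediction stage -------------------------------------------
    droplets_path = in_dir / config.droplets
    if not droplets_path.exists():
        raise FileNotFoundError(f"predict stage: missing input {droplets_path}")
    df = pd.read_csv(droplets_path)
    nozzle = NozzleSpec(config.nozzle_od)
    pairs = [
        (float(r.d_obs_mm), DropletMeasurement(mass=float(r.mass_kg),
                                               density=float(r.density_kgm3)))
        for r in df.itertuples(index=False)
    ]
    factors = tate.calibrate(pairs, nozzle)
    preds = [
        (
            tate.predict_diameter(nozzle, float(r.surface_tension_mnm),
                                  float(r.density_kgm3), factors),
            float(r.d_obs_mm),
        )
        for r in df.itertuples(index=False)
    ]
    report = tate.validate(preds)
    tate_report = {
        "k_lf": factors.k_lf,
        "k_sf": factors.k_sf,
        "k": factors.k,
        "aad_percent": report.aad,
        "mad_percent": report.mad,
        "n": report.n,
    }
    (out_dir / "prediction_report.json").write_text(
        json.dumps({**_provenance(config), **tate_report}, indent=1, sort_keys=True)
    )
    combined["tate"] = tate_report

    # --- mechanics stage --------------------------------------------------
    manifest_path = in_dir / config.manifest
    mech_report: dict = {"curves": {}}
    force_files: dict[str, list[str]] = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        force_files = manifest.get("files", {}).get("force_curves", {})
    else:
        logger.warning("no manifest at %s; skipping mechanics stage", manifest_path)
    moduli: dict[str, list] = {}
    for cls, names in force_files.items():
        moduli[cls] = []
        for name in names:
            curve = read_force_curve(
                in_dir / name, membrane_thickness=config.membrane_thickness
            )
            est = mechanics.fit_surface_modulus(curve, window=config.fit_window)
            crush = mechanics.detect_crushing(curve, drop_fraction=config.drop_fraction)
            moduli[cls].append(est)
            mech_report["curves"][name] = {
                "class": cls,
                "e_s_nm": est.e_s,
                "slope_n_per_mm": est.slope,
                "r_squared": est.r_squared,
                "crushing_present": crush.present,
                "crushing_force_n": crush.force,
                "crushing_displacement_mm": crush.displacement,
            }
    if moduli.get("spherical") and moduli.get("deformed"):
        rr = mechanics.ratio_range(moduli["spherical"], moduli["deformed"])
        mech_report["e_s_ratio_spherical_over_deformed"] = {
            "min": rr.min_ratio, "max": rr.max_ratio, "n_pairs": rr.n_pairs,
        }
    (out_dir / "mechanics_report.json").write_text(
        json.dumps({**_provenance(config), **mech_report}, indent=1, sort_keys=True)
    )
    combined["mechanics"] = mech_report

    # --- permeation stage -------------------------------------------------
    perm_report: dict = {}
    fits: dict[str, permeation.UptakeFit] = {}
    for cls in ("spherical", "deformed"):
        p = in_dir / f"uptake_{cls}.csv"
        if not p.exists():
            continue
        series = read_uptake_series(p)
        fit = permeation.fit_uptake(series)
        fits[cls] = fit
        perm_report[cls] = {
            "c0_mgml": fit.c0,
            "c_eq_mgml": fit.c_eq,
            "k_per_s": fit.k,
            "half_time_s": fit.half_time,
            "initial_rate_mgml_per_s": permeation.initial_rate(
                series, config.initial_rate_window
            ),
        }
    if "spherical" in fits and "deformed" in fits:
        cmp_ = permeation.compare_permeation([fits["spherical"]], [fits["deformed"]])
        perm_report["ordering"] = cmp_.ordering
    (out_dir / "permeation_report.json").write_text(
        json.dumps({**_provenance(config), **perm_report}, indent=1, sort_keys=True)
    )
    combined["permeation"] = perm_report

    combined_path = out_dir / "combined.json"
    combined_path.write_text(json.dumps(combined, indent=1, sort_keys=True))
    return combined


def run_demo(seed: int, work_dir) -> dict:
    """Generate a default synthetic study and run the full pipeline on it."""
    from .synthetic import StudyDesign, gen_study

    work = Path(work_dir)
    data_dir = work / "data"
    design = StudyDesign(seed=seed)
    gen_study(design, data_dir)
    config = RunConfig(
        input_dir=str(data_dir), output_dir=str(work / "reports"), seed=seed
    )
    return run_pipeline(config)


__all__ = ["RunConfig", "run_pipeline", "run_demo"]
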