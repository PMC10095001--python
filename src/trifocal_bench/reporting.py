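"""Study orchestration: run the lens × condition matrix and emit report tables.

``run_study`` reproduces the structure of a full bench comparison — per-lens
synthetic measurement tables and through-focus MTFa/simulated-acuity defocus
curves at 3 mm per condition, the pupil-dependency sweep of the discrete MTF
at 50 lp/mm across apertures, foci reports with viewing distances, and the
monochromatic-to-polychromatic loss table.  Figures are emitted as data
tables (CSV/JSON); plotting is left to downstream convenience tooling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import iol_designs, metrics, model_eye, optics_engine, synthetic_bench
from .synthetic_bench import BenchRunConfig

__all__ = ["StudyManifest", "run_study"]

log = logging.getLogger("trifocal_bench")


@dataclass(frozen=True)
class StudyManifest:
    """Configuration of one virtual-bench study run."""

    lenses: tuple[str, ...] = ("triumf", "at_lisa", "synergy", "panoptix", "trinova")
    conditions: tuple[str, ...] = ("condition1", "condition2")
    apertures: tuple[float, ...] = (2.0, 3.0, 4.0, 4.5, 5.0)
    defocus_curve_aperture: float = 3.0
    defocus_grid: tuple[float, ...] = tuple(optics_engine.DEFAULT_DEFOCUS_GRID)
    grid_size: int = 1024
    n_samples: int = 2
    noise_sd: float = 0.01
    meridian_asymmetry_sd: float = 0.005
    seed: int = 0
    output_dir: str = "study_out"

    @classmethod
    def from_yaml(cls, path) -> "StudyManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _preset_hash(design) -> str:
    payload = json.dumps(dataclasses.asdict(design), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_study(manifest: StudyManifest) -> dict:
    """Execute the study matrix; failures are isolated per combination.

    Returns a bundle dict with the summary tables; all artefacts are also
    written under ``manifest.output_dir``.  Deterministic for a given
    manifest and seed.
    """
    out = Path(manifest.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"manifest": dataclasses.asdict(manifest), "presets": {}}
    mtfa_curves: dict[tuple[str, str], metrics.MTFaCurve] = {}
    loaded: dict[str, object] = {}
    foci_rows, errors = [], []

    for lens in manifest.lenses:
        try:
            design = iol_designs.preset(lens)
            loaded[lens] = design
            provenance["presets"][lens] = _preset_hash(design)
        except Exception as exc:
            log.error("preset %s failed: %s", lens, exc)
            errors.append({"lens": lens, "stage": "preset", "error": str(exc)})
            continue
        for cond in manifest.conditions:
            try:
                eye = model_eye.condition(cond)
                cfg = BenchRunConfig(lens, cond, manifest.defocus_curve_aperture,
                                     n_samples=manifest.n_samples,
                                     noise_sd=manifest.noise_sd,
                                     meridian_asymmetry_sd=manifest.meridian_asymmetry_sd,
                                     seed=manifest.seed)
                samples = synthetic_bench.generate_bench_run(
                    cfg, grid_size=manifest.grid_size,
                    defocus_grid=np.asarray(manifest.defocus_grid))
                synthetic_bench.write_bench_csv(
                    samples, out / f"tf_mtf_{lens}_{cond}.csv")
                avg = synthetic_bench.average_samples(samples)
                curve = metrics.tf_mtfa(avg, eye)
                mtfa_curves[(lens, cond)] = curve
                va = metrics.defocus_va_curve(curve)
                pd.DataFrame({"defocus_spec_D": curve.defocus_grid,
                              "mtfa": curve.mtfa,
                              "simva_logmar": va.simva}).to_csv(
                    out / f"defocus_curve_{lens}_{cond}.csv", index=False)
                rep = metrics.find_foci(va, design, eye)
                rep.to_json(out / f"foci_{lens}_{cond}.json")
                for focus in ("far", "intermediate", "near"):
                    pt = getattr(rep, focus)
                    foci_rows.append({
                        "lens": lens, "condition": cond, "focus": focus,
                        "present": pt.present, "defocus_spec_D": pt.defocus_spec,
                        "distance_cm": pt.distance_cm, "simva_logmar": pt.value,
                        "inferred_design": bool(design.inferred)})
            except Exception as exc:
                log.error("defocus pipeline %s/%s failed: %s", lens, cond, exc)
                log.debug("%s", traceback.format_exc())
                errors.append({"lens": lens, "condition": cond,
                               "stage": "defocus_curve", "error": str(exc)})

    # pupil dependency (TF MTF at 50 lp/mm per aperture)
    pupil_tables = []
    for cond in manifest.conditions:
        try:
            eye = model_eye.condition(cond)
            designs = [loaded[l] for l in manifest.lenses if l in loaded]
            tab = metrics.pupil_dependency(
                designs, eye, apertures=manifest.apertures,
                defocus_grid=np.asarray(manifest.defocus_grid),
                grid_size=manifest.grid_size)
            tab.insert(1, "condition", cond)
            pupil_tables.append(tab)
        except Exception as exc:
            log.error("pupil dependency %s failed: %s", cond, exc)
            errors.append({"condition": cond, "stage": "pupil_dependency",
                           "error": str(exc)})
    if pupil_tables:
        pd.concat(pupil_tables, ignore_index=True).to_csv(
            out / "pupil_dependency_tf_mtf50.csv", index=False)

    # condition-loss table at the far focus
    loss_rows = []
    if set(manifest.conditions) >= {"condition1", "condition2"}:
        for lens in manifest.lenses:
            c1 = mtfa_curves.get((lens, "condition1"))
            c2 = mtfa_curves.get((lens, "condition2"))
            if c1 is None or c2 is None:
                continue
            try:
                design = iol_designs.preset(lens)
                eye = model_eye.condition("condition1")
                loss = metrics.condition_loss(c1, c2, design, eye, focus="far")
                loss_rows.append({"lens": lens, "focus": "far",
                                  "mtfa_loss_percent": loss})
            except Exception as exc:
                errors.append({"lens": lens, "stage": "condition_loss",
                               "error": str(exc)})

    foci_table = pd.DataFrame(foci_rows)
    loss_table = pd.DataFrame(loss_rows)
    if len(foci_table):
        foci_table.to_csv(out / "foci_summary.csv", index=False)
    if len(loss_table):
        loss_table.to_csv(out / "condition_loss.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump({**provenance, "errors": errors}, fh, indent=2, default=str)
    return {"foci": foci_table, "condition_loss": loss_table,
            "mtfa_curves": mtfa_curves, "errors": errors,
            "output_dir": str(out)}
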