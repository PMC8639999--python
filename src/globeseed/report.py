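"""End-to-end pipeline orchestration and the run manifest.

``run_all`` executes the full analysis in the canonical order —
validate -> standardize -> diagnose (semivariogram, Kruskal-Wallis,
hemisphere comparison) -> fit full forests -> select variables -> fit final
forests -> cross-validate -> map — on either a synthetic world generated on
the fly or records/predictors loaded from files.  Every seed is logged and
a rerun with the same config and seed reproduces all numeric outputs.

When the generator's ground-truth ledger is available the manifest also
carries recovery metrics (species-area Z error, season-ratio error, latent
recovery, selection support recovery, pH partial-effect argmax).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import mapping, model, standardize, synth
from .core import (
    MEASURES,
    PREDICTOR_NAMES,
    SeedBankRecord,
    read_predictor_table,
    read_records,
    validate_dataset,
    write_records,
)

__all__ = ["RunConfig", "RunManifest", "run_all", "build_model_table"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    generator: synth.GeneratorConfig | None = None  # default: synth.default_config()
    records_path: str | None = None  # load instead of generate
    predictors_path: str | None = None
    n_trees: int = 100
    cv_iterations: int = 99
    cv_holdout: float = 0.10
    selection_trees: int = 50
    run_selection: bool = True
    run_cv: bool = True
    run_mapping: bool = True
    semivariogram_max_points: int = 800
    standardization: standardize.StandardizationOptions = field(
        default_factory=standardize.StandardizationOptions
    )
    output_dir: str | None = None


@dataclass
class RunManifest:
    seed: int
    counts: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    standardization_report: dict = field(default_factory=dict)
    season_ratios: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    full_models: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    final_models: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def build_model_table(
    records: Sequence[SeedBankRecord], predictors: pd.DataFrame, measure: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Join standardized records of one measure with their covariates.

    Returns (X, y) aligned by record_id; rows whose record lacks covariates
    are dropped (missing covariate cells survive — the forest stage counts
    and drops incomplete rows itself).
    """
    sel = [r for r in records if r.measure == measure]
    ids = [r.record_id for r in sel]
    present = [i for i, rid in enumerate(ids) if rid in predictors.index]
    X = predictors.loc[[ids[i] for i in present], list(PREDICTOR_NAMES)].reset_index(
        drop=True
    )
    y = np.array([sel[i].value for i in present], dtype=float)
    return X, y


def run_all(config: RunConfig) -> RunManifest:
    """Execute the whole pipeline; see module docstring for the stage order."""
    rng = np.random.default_rng(config.seed)
    manifest = RunManifest(seed=config.seed)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- inputs
    truth = None
    if config.records_path:
        report = read_records(config.records_path)
        records = report.records
        manifest.counts["read_rejections"] = report.n_rejected
        predictors = read_predictor_table(config.predictors_path)
    else:
        gen_cfg = config.generator or synth.default_config()
        records, predictors, truth = synth.generate_dataset(gen_cfg, config.seed)
        if out_dir:
            write_records(records, out_dir / "records.csv")
            predictors.reset_index().to_csv(out_dir / "predictors.csv", index=False)
            (out_dir / "truth.json").write_text(
                json.dumps(truth, indent=2, default=_jsonable)
            )
            manifest.artifacts["records"] = str(out_dir / "records.csv")

    # ---- validate
    vreport = validate_dataset(records)
    manifest.validation = {
        "n_records": vreport.n_records,
        "violations": vreport.violation_counts,
        "biome_counts": vreport.biome_counts,
    }
    manifest.counts["input"] = len(records)

    # ---- standardize
    std = standardize.run_standardization(records, config.standardization)
    manifest.standardization_report = std.report
    manifest.counts["standardized"] = len(std.records)
    if std.models.season_ratios is not None:
        manifest.season_ratios = std.models.season_ratios.ratios
    std_records = std.records

    # ---- diagnostics
    for measure in MEASURES:
        sel = [r for r in std_records if r.measure == measure]
        if len(sel) < 2:
            continue
        if len(sel) > config.semivariogram_max_points:
            idx = rng.choice(len(sel), config.semivariogram_max_points, replace=False)
            sub = [sel[i] for i in idx]
        else:
            sub = sel
        coords = np.array([[r.latitude, r.longitude] for r in sub])
        values = [r.value for r in sub]
        sv = model.empirical_semivariogram(coords, values)
        manifest.diagnostics.setdefault("semivariogram", {})[measure] = {
            "bin_centers": sv.bin_centers.tolist(),
            "gamma": sv.gamma.tolist(),
            "counts": sv.counts.tolist(),
            "sample_variance": sv.sample_variance,
        }
        biomes_present = {r.biome for r in sel}
        if len(biomes_present) >= 2:
            manifest.diagnostics.setdefault("kruskal_wallis", {})[measure] = (
                model.kruskal_wallis_by_biome(std_records, measure)
            )
        hemi = model.hemisphere_comparison(std_records, measure)
        manifest.diagnostics.setdefault("hemisphere", {})[measure] = hemi.to_dict(
            orient="records"
        )

    # ---- models per response
    final_fits: dict[str, model.ForestFit] = {}
    for measure in MEASURES:
        X, y = build_model_table(std_records, predictors, measure)
        if len(y) < 10:
            continue
        seed_m = int(rng.integers(2**31 - 1))
        full = model.fit_forest(
            X, y, response_name=measure, n_trees=config.n_trees, seed=seed_m
        )
        manifest.full_models[measure] = {
            "n_trees": full.n_trees,
            "oob_mse": full.oob_mse,
            "oob_r2": full.oob_r2,
            "n_used": full.n_used,
            "n_dropped_missing": full.n_dropped_missing,
            "seed": seed_m,
            "importance": full.importance.reset_index().to_dict(orient="records"),
        }
        selected = list(PREDICTOR_NAMES)
        if config.run_selection:
            sel_res = model.select_variables(
                X, y, n_trees=config.selection_trees, seed=seed_m
            )
            selected = sel_res.selected or sel_res.candidates[:1]
            manifest.selection[measure] = {
                "candidates": sel_res.candidates,
                "selected": sel_res.selected,
                "noise_threshold": sel_res.noise_threshold,
                "step_decreases": sel_res.step_decreases,
            }
        if not selected:
            selected = list(PREDICTOR_NAMES)
        final = model.fit_forest(
            X[selected], y, response_name=measure,
            n_trees=config.n_trees, seed=seed_m,
        )
        final_fits[measure] = final
        manifest.final_models[measure] = {
            "predictors": selected,
            "oob_mse": final.oob_mse,
            "oob_r2": final.oob_r2,
            "explains_more_than_full": final.oob_r2 >= full.oob_r2,
        }
        if config.run_cv:
            cv = model.kfold_cv(
                X[selected], y, n_trees=config.n_trees,
                iterations=config.cv_iterations,
                holdout_fraction=config.cv_holdout, seed=seed_m,
            )
            manifest.cv[measure] = {
                "iterations": cv.iterations,
                "holdout_fraction": cv.holdout_fraction,
                "mean_mse": cv.mean_mse,
                "mean_r2": cv.mean_r2,
                "sd_r2": cv.sd_r2,
            }

    # ---- mapping
    if config.run_mapping and final_fits:
        gen_cfg = config.generator or synth.default_config()
        bundle = synth.generate_grid(gen_cfg, config.seed)
        grid = mapping.PredictorGrid(
            layers=bundle.layers, lat=bundle.lat, lon=bundle.lon,
            resolution_arcmin=bundle.resolution_arcmin,
        )
        for measure, fit in final_fits.items():
            raster = mapping.predict_grid(fit, grid)
            if measure == "density":
                display = mapping.log10_display(raster)
            else:
                display = raster
            lat_z, mean_z = mapping.zonal_mean(raster)
            manifest.diagnostics.setdefault("zonal_mean", {})[measure] = {
                "lat": lat_z.tolist(), "mean": mean_z.tolist(),
            }
            if out_dir:
                p = out_dir / f"{measure}_map.asc"
                mapping.write_raster(display, p)
                manifest.artifacts[f"{measure}_map"] = str(p)

    # ---- recovery against the ground-truth ledger
    if truth is not None:
        manifest.recovery = _recovery_metrics(
            std, truth, manifest, final_fits, config
        )

    if out_dir:
        manifest.to_json(out_dir / "manifest.json")
        manifest.artifacts["manifest"] = str(out_dir / "manifest.json")
    return manifest


def _recovery_metrics(std, truth, manifest, final_fits, config) -> dict:
    rec: dict = {}
    params = truth["params"]
    # species-area Z per biome
    z_err = {}
    for b, m in std.models.area_models.items():
        if b == "pooled" or m.insufficient_data or m.Z is None:
            continue
        z_err[b] = abs(m.Z - params["species_area_z"][b])
    if z_err:
        rec["z_abs_error"] = z_err
        rec["z_mae"] = float(np.mean(list(z_err.values())))
    # season ratios
    if std.models.season_ratios is not None:
        true_r = params["season_ratios_true"]
        errs = []
        for measure, ratios in std.models.season_ratios.ratios.items():
            for s, r in ratios.items():
                if r is not None and s in true_r and true_r[s] > 0:
                    errs.append(abs(r - true_r[s]) / true_r[s])
        if errs:
            rec["season_ratio_max_rel_error"] = float(max(errs))
    # latent recovery (meaningful at sigma = 0)
    latents = truth["latent"]
    rel = [
        abs(r.value - latents[r.record_id]) / latents[r.record_id]
        for r in std.records
        if r.record_id in latents and latents[r.record_id] > 0
    ]
    if rel:
        rec["latent_max_rel_error"] = float(max(rel))
        rec["latent_mean_rel_error"] = float(np.mean(rel))
    # selection support recovery
    for measure, sel in manifest.selection.items():
        informative = set(params["effects"].get(measure, {}))
        if informative:
            chosen = set(sel["selected"])
            rec.setdefault("support_recovery", {})[measure] = {
                "informative": sorted(informative),
                "selected": sorted(chosen),
                "recovered_fraction": len(chosen & informative) / len(informative),
                "false_inclusions": len(chosen - informative),
            }
    # pH partial-effect shape
    div_effects = params["effects"].get("diversity", {})
    if "pH" in div_effects and div_effects["pH"]["shape"] == "humped":
        fit = final_fits.get("diversity")
        if fit is not None and "pH" in fit.predictor_names:
            pe = model.partial_effect(fit, "pH", m=41)
            rec["ph_partial_argmax"] = float(pe.grid[int(np.argmax(pe.effect))])
    return rec
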