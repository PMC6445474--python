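"""End-to-end pipeline: simulate -> stage CPUE -> hurdle fits -> validation
-> aggregation/persistence, writing plain-text artefacts per stage.

The run is a pure function of its :class:`~stagedist.io_core.RunConfig`:
every stochastic step derives its generator from the config seed, so
repeated runs produce byte-identical outputs.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd

from . import aggregation, env_layers, hurdle, life_stages, synthetic, validation
from .gam import ri, s
from .io_core import (RunConfig, RunLog, SEASON_BY_STAGE, STAGES,
                      write_grid, write_survey_tables)

#: default hurdle term lists (shared by presence and count components);
#: deliberately compact at desk scale
DEFAULT_PRESENCE_TERMS = [s("depth", k=8), s("prox_shore", k=8),
                          s("temperature", k=8), ri("survey")]
DEFAULT_COUNT_TERMS = [s("depth", k=8), s("prox_shore", k=8),
                       s("temperature", k=8), ri("survey")]


def _stage_years(config: RunConfig, stage: str):
    return (config.years_autumn if stage == "AGE0" else config.years_spring)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return a manifest of written artefacts."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    os.makedirs(os.path.join(out, "grids"), exist_ok=True)
    os.makedirs(os.path.join(out, "truth"), exist_ok=True)
    log = RunLog(config.seed)
    manifest: dict[str, str] = {}
    seed = config.seed

    # ---- simulate -------------------------------------------------------
    env = synthetic.generate_environment(
        seed, (config.nrows, config.ncols),
        years_autumn=config.years_autumn, years_spring=config.years_spring)
    truth = synthetic.default_truth(
        seed, env, config.truth,
        years_autumn=config.years_autumn, years_spring=config.years_spring)
    hauls_aut = synthetic.generate_hauls(
        env, {"SWC_IBTS": config.hauls_swc_per_year,
              "NIGFS": config.hauls_nigfs_per_year},
        config.years_autumn, "OCT_NOV", seed + 1)
    hauls_spr = synthetic.generate_hauls(
        env, {"SWC_IBTS": config.hauls_swc_per_year,
              "NIGFS": config.hauls_nigfs_per_year},
        config.years_spring, "FEB_MAR", seed + 2)
    hauls = pd.concat([hauls_aut, hauls_spr], ignore_index=True)
    smalks_aut = synthetic.generate_smalks(
        truth, config.smalks_per_region_year, config.years_autumn,
        "OCT_NOV", seed + 3)
    smalks_spr = synthetic.generate_smalks(
        truth, config.smalks_per_region_year, config.years_spring,
        "FEB_MAR", seed + 4)
    catches = pd.concat(
        [synthetic.generate_catches(env, hauls_aut, truth, seed + 5),
         synthetic.generate_catches(env, hauls_spr, truth, seed + 6)],
        ignore_index=True)
    smalks = pd.concat([smalks_aut, smalks_spr], ignore_index=True)
    paths = write_survey_tables(out, hauls, catches, smalks)
    manifest.update(paths)
    for name in ("depth", "slope", "aspect", "prox_shore", "sediment", "land"):
        p = os.path.join(out, "grids", f"{name}.asc")
        write_grid(p, env.layers[name])
        manifest[f"grid_{name}"] = p
    l50_true, truth_grids = synthetic.export_truth(truth, env)
    p = os.path.join(out, "truth", "l50_true.csv")
    l50_true.to_csv(p, index=False, float_format="%.6g")
    manifest["l50_true"] = p
    for (stage, year, kind), layer in truth_grids.items():
        p = os.path.join(out, "truth", f"{kind}_{stage}_{year}.asc")
        write_grid(p, layer)
    log.stage("simulate", n_hauls=len(hauls), n_smalks=len(smalks),
              n_catch_rows=len(catches), grid=list(env.shape))

    # ---- life stages ----------------------------------------------------
    models = {}
    for stage in STAGES:
        pool = smalks_aut if stage == "AGE0" else smalks_spr
        for survey in ("SWC_IBTS", "NIGFS"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models[(stage, survey)] = life_stages.fit_stage_model(
                    pool, stage, survey, interactions=(), select=True)
    l50_est = life_stages.l50_table(models, smalks)
    p = os.path.join(out, "l50_estimated.csv")
    l50_est.to_csv(p, index=False, float_format="%.6g")
    manifest["l50_estimated"] = p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cpue = life_stages.decompose_cpue(catches, hauls, models,
                                          truth.regions.region_of, smalks)
    p = os.path.join(out, "stage_cpue.csv")
    cpue.to_csv(p, index=False, float_format="%.6g")
    manifest["stage_cpue"] = p
    log.stage("stages", n_models=len(models), n_cpue_rows=len(cpue))

    # ---- covariate extraction and bandwidth demonstration ---------------
    cov_table, excluded = env_layers.extract_at_hauls(env, hauls)
    p = os.path.join(out, "haul_covariates.csv")
    cov_table.to_csv(p, index=False, float_format="%.6g")
    manifest["haul_covariates"] = p
    # kernel bandwidth selection demonstrated on pseudo-casts sampled from
    # the first spring temperature layer
    rng = np.random.default_rng(seed + 7)
    year0 = config.years_spring[0]
    tlayer = env.layers[("temperature", year0, "FEB_MAR")]
    sea_idx = np.argwhere(np.isfinite(tlayer.values))
    pick = sea_idx[rng.choice(len(sea_idx), size=min(40, len(sea_idx)),
                              replace=False)]
    casts = pd.DataFrame({
        "station_id": [f"st{i:03d}" for i in range(len(pick))],
        "lon": tlayer.lon_centers()[pick[:, 1]],
        "lat": tlayer.lat_centers()[pick[:, 0]],
        "year": year0, "season": "FEB_MAR", "pressure": 100.0,
        "temperature": tlayer.values[pick[:, 0], pick[:, 1]]
                       + rng.normal(0, 0.1, len(pick)),
        "salinity": 34.5})
    kfit = env_layers.select_bandwidth_loocv(casts, config.bandwidth_grid_km)
    p = os.path.join(out, "kernel_fit.csv")
    pd.DataFrame({"year": [year0], "season": ["FEB_MAR"],
                  "variable": ["temperature"], "theta_km": [kfit.theta_km],
                  "loocv_score": [kfit.score]}).to_csv(
                      p, index=False, float_format="%.6g")
    manifest["kernel_fit"] = p
    log.stage("layers", n_extracted=len(cov_table), n_excluded=len(excluded),
              theta_km=kfit.theta_km)

    # ---- hurdle fits ----------------------------------------------------
    data = cov_table.merge(cpue, on=["haul_id", "survey", "year", "season",
                                     "lon", "lat"])
    fitted = {}
    stage_tables = {}
    for stage in STAGES:
        season = SEASON_BY_STAGE[stage]
        sub = data[data["season"] == season].reset_index(drop=True)
        y = np.round(sub[f"cpue_{stage.lower()}"].to_numpy(dtype=float))
        sub = sub[np.isfinite(y)].reset_index(drop=True)
        y = y[np.isfinite(y)].astype(int)
        presence_terms = list(DEFAULT_PRESENCE_TERMS)
        count_terms = list(DEFAULT_COUNT_TERMS)
        if config.stepwise:
            presence_terms, _, _ = hurdle.stepwise_aic(
                sub, y > 0, presence_terms, family="binomial",
                keep=(presence_terms[-1],))
            pos = y >= 1
            count_terms, _, _ = hurdle.stepwise_aic(
                sub[pos], y[pos], count_terms, family="ztp",
                keep=(count_terms[-1],))
        pres = hurdle.fit_presence_gam(sub, y > 0, presence_terms)
        pos = y >= 1
        cnt = hurdle.fit_ztp_gam(sub[pos].reset_index(drop=True), y[pos],
                                 count_terms)
        model = hurdle.HurdleModel(stage, pres, cnt, presence_terms,
                                   count_terms)
        fitted[stage] = model
        stage_tables[stage] = (sub, y)
        imp_p = hurdle.term_importance(pres, sub, y > 0)
        imp_p["component"] = "binomial"
        imp_n = hurdle.term_importance(cnt, sub[pos].reset_index(drop=True),
                                       y[pos])
        imp_n["component"] = "ztp"
        p = os.path.join(out, f"model_summary_{stage}.csv")
        pd.concat([imp_p, imp_n], ignore_index=True).to_csv(
            p, index=False, float_format="%.6g")
        manifest[f"model_summary_{stage}"] = p
        log.stage(f"fit_{stage}", n=len(sub), n_positive=int(pos.sum()),
                  presence_edf=round(pres.edf_total, 3),
                  count_edf=round(cnt.edf_total, 3))

    # ---- validation -----------------------------------------------------
    if config.cv_iterations > 0:
        cv_rows = []
        for stage, model in fitted.items():
            sub, y = stage_tables[stage]
            res = validation.cross_validate(
                sub, y, model.presence_terms, model.count_terms, stage=stage,
                iterations=config.cv_iterations, seed=seed + 8,
                train_fraction=config.cv_train_fraction)
            cv_rows.append(res.summary())
        cv_table = pd.concat(cv_rows, ignore_index=True)
        p = os.path.join(out, "cv_results.csv")
        cv_table.to_csv(p, index=False, float_format="%.6g")
        manifest["cv_results"] = p
        log.stage("validate", iterations=config.cv_iterations)
    else:
        log.stage("validate", skipped=True,
                  reason="cv_iterations = 0: validation stage skipped")

    # ---- prediction, aggregation, persistence ---------------------------
    agg_rows = []
    curve_rows = []
    for stage, model in fitted.items():
        season = SEASON_BY_STAGE[stage]
        classified = []
        for year in _stage_years(config, stage):
            grid = hurdle.predict_combined(model, env, year, season)
            for key, layer in grid.layers().items():
                write_grid(os.path.join(out, "grids", f"{key}.asc"), layer)
            dens = grid.template.like(grid.combined, "combined")
            curve = aggregation.build_curve(grid.combined, source="grid")
            tangent = aggregation.tangent_threshold(curve, mode="cubic")
            cls = aggregation.classify_cells(dens, tangent.z_star)
            classified.append(cls)
            write_grid(os.path.join(out, "grids",
                                    f"classified_{stage}_{year}.asc"), cls)
            precision = aggregation.classification_precision(curve, tangent)
            share20 = float(np.interp(0.2, curve.x, curve.y))
            agg_rows.append({"stage": stage, "year": year,
                             "x_star": tangent.x_star, "y_star": tangent.y_star,
                             "z_star": tangent.z_star,
                             "pct_outside_band": precision,
                             "pct_abundance_in_20pct_area": 100 * share20,
                             "degenerate": tangent.degenerate})
            for xv, yv in zip(curve.x, curve.y):
                curve_rows.append({"stage": stage, "year": year,
                                   "x": xv, "y": yv})
        pers = aggregation.persistence(classified)
        write_grid(os.path.join(out, "grids", f"persistence_{stage}.asc"), pers)
        manifest[f"persistence_{stage}"] = os.path.join(
            out, "grids", f"persistence_{stage}.asc")
    p = os.path.join(out, "aggregation_summary.csv")
    pd.DataFrame(agg_rows).to_csv(p, index=False, float_format="%.6g")
    manifest["aggregation_summary"] = p
    p = os.path.join(out, "aggregation_curves.csv")
    pd.DataFrame(curve_rows).to_csv(p, index=False, float_format="%.10g")
    manifest["aggregation_curves"] = p
    log.stage("aggregate", n_curves=len(agg_rows))

    p = os.path.join(out, "run_log.json")
    log.write(p)
    manifest["run_log"] = p
    return manifest
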