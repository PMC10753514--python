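"""End-to-end orchestration: generate, process, analyse, summarise.

The pipeline mirrors the study's analysis chain:

1. generate (or load) the overnight experiment;
2. calibrate and QC body-temperature streams;
3. baseline-correct the gas streams and compute per-second rates;
4. extract RMR per bird x ambient temperature (stablest-2-min rule,
   lowest cycle) and time-match body temperature;
5. 1-min-bin the night profiles and compute CV and the consecutive
   disparity index;
6. fit the mixed models, select by AICc, and produce marginal means,
   contrasts, Welch ANOVA / Games-Howell tables and balance checks.

`run_pipeline` writes every stage output as CSV/JSON under an output
directory together with a manifest (config hash, seed, artifact hashes,
QC counters) so identical config+seed runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .calibration import fit_calibration, fit_for_method, apply_calibration, \
    fits_to_frame
from .config import ExperimentConfig
from .respirometry import correct_baseline_drift, rate_series
from .stats_models import (balance_checks, emmeans, emmeans_pairwise,
                           fit_candidates_and_select, games_howell,
                           lrt_random_intercept, wald_chisq, welch_anova)
from .synthetic import SyntheticExperiment, generate_experiment
from .temperature_qc import qc_pipeline, round_and_bin
from .variability import variability_table
from .window_matching import analysis_table, window_table

log = logging.getLogger("thermoresp")


def process_experiment(exp: SyntheticExperiment, window_on: str = "watts"
                       ) -> dict:
    """Stages 2-5: from raw streams to the analysis and variability tables."""
    fits = fit_calibration(exp.calibration, grouping="sensor")

    cleaned, binned, qc_counts = {}, {}, {}
    for bird in exp.birds:
        series = exp.temps.get(bird.bird_id)
        if series is None:
            continue
        series = apply_calibration(series, fit_for_method(fits, bird.method))
        series = qc_pipeline(series)
        cleaned[bird.bird_id] = series
        binned[bird.bird_id] = round_and_bin(series)
        qc_counts[bird.bird_id] = series.qc_counts
    log.info("temperature QC: %d birds, %d misreads removed, %d out of range",
             len(cleaned),
             sum(c.get("misreads_removed", 0) for c in qc_counts.values()),
             sum(c.get("out_of_range", 0) for c in qc_counts.values()))

    per_bird_windows = {}
    chan_map = {(b.night, str(b.channel)): b.bird_id for b in exp.birds}
    for gas in exp.gas:
        night = int(gas["night"].iloc[0])
        rates = rate_series(correct_baseline_drift(gas))
        wins = window_table(rates, on=window_on)
        for ch, sub in wins.groupby("channel"):
            bird_id = chan_map[(night, str(ch))]
            per_bird_windows[bird_id] = sub.reset_index(drop=True)
    log.info("respirometry: %d nights, %d stablest windows",
             len(exp.gas), sum(len(w) for w in per_bird_windows.values()))

    analysis = analysis_table(per_bird_windows, exp.birds, cleaned)
    variability = variability_table(binned, exp.birds)
    log.info("extraction: %d bird x temperature estimates, %d variability rows",
             len(analysis), len(variability))
    return {"analysis": analysis, "variability": variability,
            "calibration_fits": fits, "qc_counts": qc_counts,
            "cleaned_temps": cleaned, "binned_temps": binned,
            "windows": per_bird_windows}


def run_stats(analysis: pd.DataFrame, variability: pd.DataFrame,
              birds: pd.DataFrame) -> dict:
    """Stage 6: models, marginal means, post hoc tests, balance checks."""
    out: dict = {}
    df = analysis.copy()
    df["t_air"] = df["t_air"].astype(float)

    fit_rmr, aicc_rmr = fit_candidates_and_select(df, "rmr_w")
    out["rmr"] = {
        "fit": fit_rmr, "aicc": aicc_rmr, "wald": wald_chisq(fit_rmr),
        "emmeans_method": emmeans(fit_rmr, ["method"]),
        "emmeans_t_air": emmeans(fit_rmr, ["t_air"]),
        "emmeans_grid": emmeans(fit_rmr, ["method", "t_air"]),
        "contrasts": emmeans_pairwise(fit_rmr, "method"),
        "lrt_random": lrt_random_intercept(
            df, "rmr_w", fit_rmr.design.terms, ["method", "t_air", "age"],
            ["mass"]),
    }

    tb = df[(df["method"] != "C") & df["tb_mean"].notna()].copy()
    fit_tb, aicc_tb = fit_candidates_and_select(tb, "tb_mean")
    out["tb"] = {
        "fit": fit_tb, "aicc": aicc_tb, "wald": wald_chisq(fit_tb),
        "emmeans_grid": emmeans(fit_tb, ["method", "t_air"]),
        "emmeans_t_air": emmeans(fit_tb, ["t_air"]),
        "contrasts": emmeans_pairwise(fit_tb, "method", by="t_air"),
        "lrt_random": lrt_random_intercept(
            tb, "tb_mean", fit_tb.design.terms, ["method", "t_air", "age"],
            ["mass"]),
    }

    out["variability"] = {}
    for index in ("cv", "d_index"):
        groups = {m: g[index].to_numpy(dtype=float)
                  for m, g in variability.groupby("method")}
        out["variability"][index] = {"welch": welch_anova(groups),
                                     "games_howell": games_howell(groups)}
    out["balance"] = balance_checks(birds)
    return out


def analyze_experiment(config: ExperimentConfig) -> dict:
    """Generate one seeded experiment and run the full analysis in memory."""
    exp = generate_experiment(config)
    proc = process_experiment(exp)
    stats = run_stats(proc["analysis"], proc["variability"],
                      tio.birds_frame(exp.birds))
    return {"experiment": exp, **proc, "stats": stats}


# --- headline quantities ------------------------------------------------------


def recovery_summary(result: dict) -> dict:
    """Headline numbers of one analysed experiment.

    Percent RMR increases between ambient temperatures (from the final
    model's marginal means), the fitted mass coefficient, the minimum
    cutaneous body-temperature deficit at 5 degC, and the CV / disparity
    contrasts between methods.
    """
    stats = result["stats"]
    emm_t = stats["rmr"]["emmeans_t_air"].set_index("t_air")["emmean"]
    fit = stats["rmr"]["fit"]
    mass_coef = float(fit.beta[fit.design.term_cols["mass"][0]])

    emm_tb = stats["tb"]["emmeans_grid"]
    at5 = emm_tb[emm_tb["t_air"] == 5.0].set_index("method")["emmean"]
    cu_deficit_5 = float(min(at5[m] - at5["CU"] for m in at5.index
                             if m != "CU"))

    var = result["variability"]
    cv = var.groupby("method")["cv"].mean()
    cv_excess = float(min(100.0 * (cv["CU"] / cv[m] - 1.0)
                          for m in cv.index if m != "CU"))
    d = var.groupby("method")["d_index"]
    d_cl = float(d.mean()["CL"])
    d_core = float(var[var["method"].isin(["SC", "IP"])]["d_index"].mean())

    return {
        "rmr_pct_5_vs_25": float(100.0 * (emm_t[5.0] / emm_t[25.0] - 1.0)),
        "rmr_pct_m15_vs_5": float(100.0 * (emm_t[-15.0] / emm_t[5.0] - 1.0)),
        "mass_slope_w_per_g": mass_coef,
        "cu_tb_deficit_5c": cu_deficit_5,
        "cv_cu_excess_pct": cv_excess,
        "d_cl_excess_pct": float(100.0 * (d_cl / d_core - 1.0)),
    }


def multi_seed_summary(config: ExperimentConfig, seeds) -> pd.DataFrame:
    """Recovery summaries for several seeded replicates of one config."""
    rows = []
    for seed in seeds:
        cfg = dataclasses.replace(config, seed=int(seed))
        rows.append({"seed": int(seed),
                     **recovery_summary(analyze_experiment(cfg))})
    return pd.DataFrame(rows)


# --- filesystem pipeline ------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def stage_generate(config: ExperimentConfig, out: Path) -> list[Path]:
    exp = generate_experiment(config)
    paths = []
    for gas in exp.gas:
        p = out / f"gas_night{int(gas['night'].iloc[0]):02d}.csv"
        _write_csv(tio.gas_to_tidy(gas), p)
        paths.append(p)
    tio.write_temps(exp.temps, out / "temperatures.csv")
    _write_csv(exp.calibration, out / "calibration.csv")
    tio.write_birds(exp.birds, out / "birds.csv")
    config.to_yaml(out / "config.yaml")
    paths += [out / "temperatures.csv", out / "calibration.csv",
              out / "birds.csv"]
    log.info("generate: %d nights, %d temperature streams, %d birds",
             len(exp.gas), len(exp.temps), len(exp.birds))
    return paths


def stage_process(config: ExperimentConfig, out: Path) -> list[Path]:
    birds = tio.read_birds(out / "birds.csv")
    temps = tio.read_temps(out / "temperatures.csv")
    calib = pd.read_csv(out / "calibration.csv")
    gas = [tio.gas_from_tidy(pd.read_csv(p))
           for p in sorted(out.glob("gas_night*.csv"))]
    for g, p in zip(gas, sorted(out.glob("gas_night*.csv"))):
        g["night"] = int(p.stem.replace("gas_night", ""))
    exp = SyntheticExperiment(config=config, birds=birds, gas=gas,
                              temps=temps, calibration=calib, truth=None)
    proc = process_experiment(exp)
    _write_csv(proc["analysis"], out / "analysis_table.csv")
    _write_csv(proc["variability"], out / "variability.csv")
    _write_csv(fits_to_frame(proc["calibration_fits"]),
               out / "calibration_fits.csv")
    with open(out / "qc_summary.json", "w") as fh:
        json.dump(proc["qc_counts"], fh, indent=1, sort_keys=True)
    return [out / "analysis_table.csv", out / "variability.csv",
            out / "calibration_fits.csv", out / "qc_summary.json"]


def stage_stats(config: ExperimentConfig, out: Path) -> list[Path]:
    analysis = pd.read_csv(out / "analysis_table.csv")
    variability = pd.read_csv(out / "variability.csv")
    birds = pd.read_csv(out / "birds.csv")
    stats = run_stats(analysis, variability, birds)
    paths = []
    for resp in ("rmr", "tb"):
        for name in ("aicc", "wald", "contrasts"):
            p = out / f"{resp}_{name}.csv"
            _write_csv(stats[resp][name], p)
            paths.append(p)
        for name in [k for k in stats[resp] if k.startswith("emmeans")]:
            p = out / f"{resp}_{name}.csv"
            _write_csv(stats[resp][name], p)
            paths.append(p)
    for index in ("cv", "d_index"):
        p = out / f"{index}_games_howell.csv"
        _write_csv(stats["variability"][index]["games_howell"], p)
        paths.append(p)
    extra = {"balance": stats["balance"],
             "welch": {i: stats["variability"][i]["welch"]
                       for i in ("cv", "d_index")},
             "lrt_random": {r: stats[r]["lrt_random"] for r in ("rmr", "tb")}}
    with open(out / "stats_summary.json", "w") as fh:
        json.dump(extra, fh, indent=1, sort_keys=True)
    paths.append(out / "stats_summary.json")
    return paths


def run_pipeline(config: ExperimentConfig, out_dir, seed: int | None = None
                 ) -> dict:
    """Run generate -> process -> stats, writing a manifest of all artifacts."""
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    out = tio.ensure_dir(out_dir)
    t0 = time.time()
    paths = []
    for stage in (stage_generate, stage_process, stage_stats):
        try:
            paths += stage(config, out)
        except Exception:
            log.exception("pipeline stage %s failed", stage.__name__)
            raise
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(paths))},
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
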