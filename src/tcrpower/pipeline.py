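"""Pipeline stages tying the analysis together.

Each stage reads validated CSV tables, runs one analysis step and writes
its outputs plus a ``run_metadata.json`` record (stage, seed, config hash,
package version) into the output directory.  Fixed seed implies
bit-identical outputs for every stochastic stage.

Stages: ``synth`` (ground-truth-known inputs), ``spr-fit`` (free +
constrained Langmuir KDs), ``potency`` (sigmoid fits and PX
interpolation), ``powerlaw`` (discrimination power per experiment and
aggregate), ``kp-fit`` (annealed MH ensemble), ``kp-map`` (phase maps)
and ``simulate`` (one stochastic ensemble).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, kp_inference, kp_model, kp_stochastic, potency as potency_mod, powerlaw, spr, synthetic
from .config import PipelineConfig
from .tables import read_table, write_table

log = logging.getLogger("tcrpower")

STAGES = ("synth", "spr-fit", "potency", "powerlaw", "kp-fit", "kp-map",
          "simulate")


def _write_metadata(out_dir: Path, stage: str, config: PipelineConfig) -> None:
    meta = {"stage": stage, "seed": config.seed,
            "config_hash": config.content_hash(), "version": __version__,
            "units": config.units.__dict__}
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing stage input: {path}")
    return path


def stage_synth(config: PipelineConfig, out_dir: Path) -> None:
    """Generate SPR, potency and dose-response tables with a truth sidecar."""
    sy = config.synth
    kd_panel = {f"L{j + 1:02d}": kd
                for j, kd in enumerate(synthetic.DEFAULT_KD_PANEL)}
    spr_truth = synthetic.default_spr_truth(
        kd_panel, seed=config.seed, sigma_ru=sy.sigma_ru,
        n_replicates=sy.n_spr_replicates)
    binding, traces, spr_dict = synthetic.generate_spr_dataset(
        spr_truth, seed=config.seed)
    kp_truth = synthetic.default_kp_truth(
        sy.n_experiments, seed=config.seed, sigma_log=sy.sigma_log,
        prior_set=config.kpfit.prior_set)
    pot_table, kp_dict = synthetic.generate_kp_potency_dataset(
        kp_truth, seed=config.seed + 1)
    threshold = config.potency.threshold_percent["CD69"]
    dose_resp = synthetic.generate_dose_response_dataset(
        pot_table, hill_shape=(sy.hill_emin, sy.hill_emax, sy.hill_coeff),
        threshold_percent=threshold, seed=config.seed + 2)
    write_table(binding, out_dir / "binding_curve.csv", "binding_curve")
    write_table(traces, out_dir / "antibody_trace.csv", "antibody_trace")
    write_table(pot_table, out_dir / "potency_table.csv", "potency_table")
    write_table(dose_resp, out_dir / "dose_response.csv", "dose_response")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump({"spr": spr_dict, "kp": kp_dict,
                   "hill_shape": [sy.hill_emin, sy.hill_emax, sy.hill_coeff],
                   "threshold_percent": threshold}, fh, indent=1,
                  sort_keys=True)
    log.info("synth: wrote %d binding rows, %d potency rows",
             len(binding), len(pot_table))


def stage_spr_fit(config: PipelineConfig, in_dir: Path, out_dir: Path) -> None:
    """Free + constrained Langmuir fits and the per-ligand KD report."""
    binding = read_table(_require(in_dir / "binding_curve.csv"), "binding_curve")
    traces = read_table(_require(in_dir / "antibody_trace.csv"), "antibody_trace")
    rmax_by_ligand: dict[str, float] = {}
    for ligand, grp in traces.groupby("ligand_id", sort=True):
        w = spr.fit_w632_rmax(str(ligand), grp["time_s"], grp["response_RU"])
        rmax_by_ligand[str(ligand)] = w.rmax
    curves, free_fits = [], []
    if "replicate_id" not in binding.columns:
        binding = binding.assign(replicate_id="1")
    for (ligand, rep), grp in binding.groupby(
            ["ligand_id", "replicate_id"], sort=True):
        grp = grp.sort_values("tcr_conc_uM")
        curve = spr.BindingCurve(str(ligand), grp["tcr_conc_uM"].to_numpy(),
                                 grp["response_RU"].to_numpy(), str(rep))
        curves.append(curve)
        free_fits.append(spr.fit_langmuir_free(curve))
    std = spr.build_standard_curve(
        [(rmax_by_ligand[f.ligand_id], f) for f in free_fits],
        saturation_ratio=config.spr.saturation_ratio)
    rows = []
    for curve, free in zip(curves, free_fits):
        rmax = rmax_by_ligand[curve.ligand_id]
        try:
            constrained = spr.fit_langmuir_constrained(curve, std, rmax)
            kd_rep, method = spr.select_reported_kd(
                free, constrained, config.spr.kd_switch_threshold)
            kd_con = constrained.kd
        except ValueError:  # Rmax outside the standard curve: free fit only
            kd_con, kd_rep, method = np.nan, free.kd, "free"
        rows.append({"ligand_id": curve.ligand_id,
                     "replicate_id": curve.replicate_id,
                     "kd_free": free.kd, "kd_constrained": kd_con,
                     "kd_reported": kd_rep, "method": method,
                     "bmax_free": free.bmax, "rmax": rmax,
                     "saturation_ratio": free.saturation_ratio})
    report = pd.DataFrame(rows)
    cv = (report.groupby("ligand_id")["kd_reported"]
          .apply(lambda s: spr.replicate_cv(s) if len(s) > 1 else np.nan)
          .rename("cv"))
    report = report.merge(cv, on="ligand_id", how="left")
    report.to_csv(out_dir / "kd_report.csv", index=False, float_format="%.17g")
    with open(out_dir / "standard_curve.json", "w") as fh:
        json.dump({"slope": std.slope, "intercept": std.intercept,
                   "n_points": std.n_points,
                   "rmax_range": [std.rmax_min, std.rmax_max]}, fh, indent=1)
    log.info("spr-fit: %d curves, standard-curve slope %.3f",
             len(curves), std.slope)


def stage_potency(config: PipelineConfig, in_dir: Path, out_dir: Path) -> None:
    """Sigmoid fits + PX interpolation, merged with ligand affinities."""
    dose_resp = read_table(_require(in_dir / "dose_response.csv"),
                           "dose_response")
    affinities = read_table(_require(in_dir / "potency_table.csv"),
                            "potency_table")
    threshold = config.potency.threshold_percent["CD69"]
    kd_of = {(r["experiment_id"], r["ligand_id"]): r.get("kd_uM", np.nan)
             for _, r in affinities.iterrows()}
    rows = []
    for (exp, ligand), grp in dose_resp.groupby(
            ["experiment_id", "ligand_id"], sort=True):
        grp = grp.sort_values("dose")
        doses = grp["dose"].to_numpy()
        try:
            fit = potency_mod.fit_hill(doses, grp["response_percent"].to_numpy())
            result = potency_mod.interpolate_potency(
                fit, threshold, max_dose=float(doses.max()))
        except (spr.FitError, ValueError) as err:
            log.warning("potency: %s/%s failed: %s", exp, ligand, err)
            result = potency_mod.PotencyResult(None, "fit_failed")
        rows.append({"study_id": "measured", "experiment_id": exp,
                     "ligand_id": ligand,
                     "kd_uM": kd_of.get((exp, ligand), np.nan),
                     "potency": result.px if not result.excluded else np.nan,
                     "readout": "CD69", "flag": result.flag})
    write_table(pd.DataFrame(rows), out_dir / "potency_measured.csv",
                "potency_table")
    log.info("potency: %d ligand curves processed", len(rows))


def stage_powerlaw(config: PipelineConfig, in_dir: Path, out_dir: Path) -> None:
    """Per-experiment discrimination powers and their aggregate."""
    path = in_dir / "potency_measured.csv"
    if not path.exists():
        path = _require(in_dir / "potency_table.csv")
    records = read_table(path, "potency_table")
    kept, audit = powerlaw.apply_inclusion_rules(
        records, config.powerlaw.kd_exclusion_floor)
    fits, rows = [], []
    for exp, grp in kept.groupby("experiment_id", sort=True):
        if len(grp.dropna(subset=["potency"])) < 3:
            raise ValueError(
                f"insufficient points for regression in experiment {exp}")
        fit = powerlaw.fit_power_law(grp, affinity_axis="KD")
        fits.append(fit)
        rows.append({"experiment_id": exp, "alpha": fit.alpha, "C": fit.C,
                     "r_squared": fit.r_squared, "p_slope": fit.p_slope,
                     "alpha_ci_lo": fit.alpha_ci[0],
                     "alpha_ci_hi": fit.alpha_ci[1],
                     "n_points": fit.n_points})
    mean, ci, n_inc = powerlaw.aggregate_alpha(
        fits, config.powerlaw.significance_alpha)
    tstat, pval = powerlaw.test_alpha_vs_one(
        [f.alpha for f in fits
         if f.p_slope < config.powerlaw.significance_alpha])
    pd.DataFrame(rows).to_csv(out_dir / "powerlaw_report.csv", index=False,
                              float_format="%.17g")
    audit.to_csv(out_dir / "exclusion_audit.csv", index=False)
    with open(out_dir / "aggregate.json", "w") as fh:
        json.dump({"alpha_mean": mean, "alpha_ci95": list(ci),
                   "n_included": n_inc, "t_vs_one": tstat,
                   "p_vs_one": pval}, fh, indent=1)
    log.info("powerlaw: mean alpha %.3f over %d experiments", mean, n_inc)


def stage_kp_fit(config: PipelineConfig, in_dir: Path, out_dir: Path) -> None:
    """Annealed MH ensemble fit of the KP potency model."""
    records = read_table(_require(in_dir / "potency_table.csv"),
                         "potency_table")
    data = kp_inference.potency_data_from_table(records)
    priors = kp_inference.make_priors(data.n_experiments,
                                      config.kpfit.prior_set)
    kf = config.kpfit
    if kf.schedule == "plate":
        schedule = kp_inference.PLATE_SCHEDULE
    elif kf.schedule == "cell":
        schedule = kp_inference.CELL_SCHEDULE
    else:
        schedule = kp_inference.synthetic_schedule(
            data.n_points, kf.sigma_log, kf.max_steps)
    ensemble = kp_inference.fit_ensemble(
        data, priors, schedule, n_chains=kf.n_chains, seed=config.seed,
        kon=kf.kon)
    ensemble.table.to_csv(out_dir / "ensemble.csv", index=False,
                          float_format="%.17g")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(ensemble.summary(), fh, indent=1)
    log.info("kp-fit: %d/%d chains converged, median N %.3f",
             len(ensemble.table), kf.n_chains,
             ensemble.summary()["N"]["median"])


def stage_kp_map(config: PipelineConfig, out_dir: Path) -> None:
    """Deterministic and stochastic sensitivity/discrimination phase maps."""
    hm = config.heatmap
    stoch_config = kp_stochastic.StochasticConfig(
        n_realisations=hm.n_realisations, t_end=hm.t_end,
        lambda_threshold=hm.lambda_threshold, R0=int(hm.R0),
        L_high=int(hm.L_high), koff1=hm.koff1,
        kon_occupancy_factor=hm.kon_occupancy_factor)
    det = kp_stochastic.phase_map(hm.n_values, hm.tau_values, hm.alpha,
                                  stoch_config, mode="deterministic")
    stoch = kp_stochastic.phase_map(
        [n for n in hm.n_values if n == int(n)], hm.tau_values, hm.alpha,
        stoch_config, mode="stochastic", seed=config.seed)
    combined = pd.concat([det.table, stoch.table], ignore_index=True)
    combined.to_csv(out_dir / "phase_map.csv", index=False,
                    float_format="%.17g")
    log.info("kp-map: %d cells (alpha=%.3g)", len(combined), hm.alpha)


def stage_simulate(config: PipelineConfig, out_dir: Path) -> None:
    """Stochastic ensemble for the single-agonist sensitivity scenario."""
    hm = config.heatmap
    stoch_config = kp_stochastic.StochasticConfig(
        n_realisations=hm.n_realisations, t_end=hm.t_end,
        lambda_threshold=hm.lambda_threshold, R0=int(hm.R0),
        L_high=int(hm.L_high), koff1=hm.koff1,
        kon_occupancy_factor=hm.kon_occupancy_factor)
    results = []
    for n in hm.n_values:
        if n != int(n):
            continue
        for tau in hm.tau_values:
            sys = kp_model.KPSystem(N=int(n), kp=1.0 / tau,
                                    kon=stoch_config.kon,
                                    koff=stoch_config.koff1, L0=1,
                                    R0=stoch_config.R0)
            mean, se = kp_stochastic.ensemble_mean_cn(
                sys, stoch_config.n_realisations, stoch_config.t_end,
                seed=config.seed + int(n) * 1000 + int(tau * 10))
            results.append({"N": int(n), "tau": tau, "mean_cn": mean,
                            "se": se,
                            "deterministic_cn": kp_stochastic.deterministic_cn(sys)})
    pd.DataFrame(results).to_csv(out_dir / "simulate.csv", index=False,
                                 float_format="%.17g")
    log.info("simulate: %d systems", len(results))


def run_pipeline(config: PipelineConfig, stage: str,
                 in_dir: str | Path | None = None,
                 out_dir: str | Path = ".") -> Path:
    """Run one pipeline stage; returns the output directory.

    ``in_dir`` defaults to ``out_dir`` (stages chained in one directory).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; know {STAGES}")
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inp = Path(in_dir) if in_dir is not None else out
    if stage == "synth":
        stage_synth(config, out)
    elif stage == "spr-fit":
        stage_spr_fit(config, inp, out)
    elif stage == "potency":
        stage_potency(config, inp, out)
    elif stage == "powerlaw":
        stage_powerlaw(config, inp, out)
    elif stage == "kp-fit":
        stage_kp_fit(config, inp, out)
    elif stage == "kp-map":
        stage_kp_map(config, out)
    elif stage == "simulate":
        stage_simulate(config, out)
    _write_metadata(out, stage, config)
    return out
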