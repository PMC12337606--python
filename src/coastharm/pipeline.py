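"""End-to-end pipeline: QC -> AOU -> harmonic fits -> trends -> subsampling.

A run is driven by a JSON/YAML config and writes a bundle of CSV tables,
JSON summaries and a plain-text log recording every seed, so a re-run
with the same config and inputs reproduces every output byte for byte.

Config keys (all optional unless noted)::

    site:            site code used in outputs (default "SYN")
    seed:            master seed for every random stage (default 0)
    simulate:        true to generate the synthetic site suite as input
    input_files:     {variable: csv path} when not simulating
    qc:              {spike_filter: bool, chauvenet: bool, chauvenet_iterate: bool}
    daily_average:   bool, average sub-daily records before analysis
    harmonics:       {K: int, n_boot: int, level: float}
    trends:          bool, GLS trend on deseasonalized anomalies
    split_half:      bool, seasonal-shift analysis (needs >= 10 yr)
    subsampling:     {enabled: bool, counts_per_quarter: int,
                      n_yrs_grid: [..], n_trials: int}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .harmonics import (
    bootstrap_fit,
    composite_extrema,
    deseasonalize,
    fit_harmonics,
    to_climatology,
)
from .oxygen import derive_aou_series
from .qc import chauvenet_screen, daily_average, log10_chl, spike_filter
from .series import SampleSeries, read_series, write_series
from .subsampling import (
    duration_table,
    minimum_duration,
    reference_fit,
    subsample_density,
    sweep_duration,
    trial_summary,
)
from .synthetic import generate_site_suite, write_truth_sidecar
from .trends import gls_trend, split_half_shift

DEFAULT_CONFIG = {
    "site": "SYN",
    "seed": 0,
    "simulate": True,
    "input_files": {},
    "qc": {"spike_filter": True, "chauvenet": True, "chauvenet_iterate": False},
    "daily_average": True,
    "harmonics": {"K": 2, "n_boot": 1000, "level": 0.95},
    "trends": True,
    "split_half": False,
    "subsampling": {
        "enabled": True,
        "counts_per_quarter": 8,
        "n_yrs_grid": [5, 10, 15, 20, 25, 30, 40, 50],
        "n_trials": 200,
    },
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)  # YAML is a superset of JSON
    return merge_config(cfg or {})


def merge_config(overrides: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


class RunLog:
    def __init__(self) -> None:
        self.lines: list[str] = [f"coastharm {__version__}"]

    def log(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path) -> None:
        Path(path).write_text("\n".join(self.lines) + "\n")


def _fit_outputs(series: SampleSeries, cfg: dict, outdir: Path,
                 log: RunLog, seed: int) -> dict:
    hcfg = cfg["harmonics"]
    clim = to_climatology(series)
    fit = fit_harmonics(clim, K=hcfg["K"])
    comp = composite_extrema(fit)
    ci = bootstrap_fit(clim, n_boot=hcfg["n_boot"], level=hcfg["level"],
                       seed=seed, K=hcfg["K"])
    log.log(f"bootstrap seed for {series.variable}: {seed}")
    summary = {
        "site": series.site,
        "variable": series.variable,
        "n_obs": fit.n_obs,
        "elements": {**fit.elements(), **comp.elements()},
        "var_fraction": fit.var_fraction.tolist(),
        "dominant_harmonic": fit.dominant_harmonic,
        "resid_sd": fit.resid_sd,
        "red_chisq": fit.red_chisq,
        "ci": {k: list(v) for k, v in ci.intervals.items()},
        "n_boot": ci.n_boot,
        "level": ci.level,
    }
    with open(outdir / f"fit_{series.variable}.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    days = np.arange(1.0, 366.0)
    pd.DataFrame({"day_of_year": days.astype(int),
                  "fitted": fit.predict(days)}).to_csv(
        outdir / f"curve_{series.variable}.csv", index=False)
    return {"fit": fit, "composite": comp, "ci": ci, "summary": summary}


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured pipeline and write the report bundle.

    Returns a dict of in-memory results keyed by stage; everything is
    also written under ``outdir``.
    """
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    master_seed = int(cfg["seed"])
    log.log(f"master seed: {master_seed}")
    rng_seeds = np.random.SeedSequence(master_seed).generate_state(64) % (2**31)
    seed_iter = iter(int(s) for s in rng_seeds)

    # --- inputs -----------------------------------------------------------
    if cfg["simulate"]:
        sim_seed = next(seed_iter)
        log.log(f"synthetic suite seed: {sim_seed}")
        suite = generate_site_suite(seed=sim_seed, site=cfg["site"])
        aou_truth = suite.pop("aou_truth")
        write_truth_sidecar(aou_truth, outdir / "truth_aou.json")
        for name, s in suite.items():
            write_series(s, outdir / f"input_{name}.csv")
            if s.truth is not None:
                write_truth_sidecar(s, outdir / f"truth_{name}.json")
        series_by_var = suite
    else:
        series_by_var = {
            var: read_series(path) for var, path in cfg["input_files"].items()
        }
        if not series_by_var:
            raise ValueError("no inputs: set simulate=true or input_files")

    # --- qc ---------------------------------------------------------------
    qc_reports = {}
    for var, s in list(series_by_var.items()):
        reports = {}
        if cfg["qc"]["spike_filter"] and len(s) >= 2:
            s, rep = spike_filter(s)
            reports["spike_filter"] = rep.to_dict()
        if cfg["qc"]["chauvenet"]:
            s, rep = chauvenet_screen(s, iterate=cfg["qc"]["chauvenet_iterate"])
            reports["chauvenet"] = rep.to_dict()
        series_by_var[var] = s
        qc_reports[var] = reports
    if "chl" in series_by_var:
        logchl, rep = log10_chl(series_by_var["chl"])
        qc_reports["chl"]["log10"] = rep.to_dict()
        series_by_var["log10chl"] = logchl
        del series_by_var["chl"]
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(qc_reports, fh, indent=2)

    # --- oxygen -----------------------------------------------------------
    if {"temperature", "salinity", "do"} <= set(series_by_var):
        t, s_, d = (series_by_var[v] for v in ("temperature", "salinity", "do"))
        common = t.times.intersection(s_.times).intersection(d.times)
        aligned = [x.select(np.asarray(x.times.isin(common))) for x in (t, s_, d)]
        aou_series = derive_aou_series(*aligned)
        series_by_var["aou"] = aou_series
        write_series(aou_series, outdir / "derived_aou.csv")
        log.log(f"AOU derived on {len(common)} co-located samples")

    # --- daily averaging --------------------------------------------------
    if cfg["daily_average"]:
        for var, s in list(series_by_var.items()):
            if len(s) > 1:
                step = (s.times[1:] - s.times[:-1]).min()
                if step < pd.Timedelta(days=1):
                    daily, _counts = daily_average(s)
                    series_by_var[var] = daily

    # --- harmonics --------------------------------------------------------
    fits = {}
    for var, s in series_by_var.items():
        fits[var] = _fit_outputs(s, cfg, outdir, log, seed=next(seed_iter))

    # --- trends -----------------------------------------------------------
    results: dict = {"fits": fits, "qc": qc_reports}
    if cfg["trends"]:
        rows = []
        trend_results = {}
        for var, s in series_by_var.items():
            anomalies = deseasonalize(s, fits[var]["fit"])
            try:
                tr = gls_trend(anomalies)
            except ValueError as exc:
                log.log(f"trend skipped for {var}: {exc}")
                continue
            trend_results[var] = tr
            rows.append({"site": s.site, "variable": var, **tr.to_dict()})
        if rows:
            pd.DataFrame(rows).to_csv(outdir / "trends.csv", index=False)
        results["trends"] = trend_results

    # --- split half -------------------------------------------------------
    if cfg["split_half"]:
        sh = {}
        for var, s in series_by_var.items():
            try:
                sh[var] = split_half_shift(s, K=cfg["harmonics"]["K"])
            except ValueError as exc:
                log.log(f"split-half skipped for {var}: {exc}")
        if sh:
            pd.DataFrame([
                {"variable": var, **r.deltas} for var, r in sh.items()
            ]).to_csv(outdir / "split_half_deltas.csv", index=False)
        results["split_half"] = sh

    # --- subsampling ------------------------------------------------------
    sub_cfg = cfg["subsampling"]
    if sub_cfg["enabled"]:
        density_rows, duration_frames, nmin_summary = [], [], {}
        for var, s in series_by_var.items():
            ref_seed, den_seed, dur_seed = (next(seed_iter) for _ in range(3))
            log.log(f"subsampling seeds for {var}: ref={ref_seed} "
                    f"density={den_seed} duration={dur_seed}")
            ref = reference_fit(s, n_boot=cfg["harmonics"]["n_boot"],
                                seed=ref_seed)
            if ref.degenerate_sd:
                log.log(f"subsampling skipped for {var}: zero anomaly SD")
                continue
            trials = subsample_density(
                s, sub_cfg["counts_per_quarter"], reference=ref,
                n_trials=sub_cfg["n_trials"], seed=den_seed)
            density_rows.append({"variable": var, **trial_summary(trials)})
            curve = sweep_duration(
                s, n_yrs_grid=sub_cfg["n_yrs_grid"], reference=ref,
                n_trials=sub_cfg["n_trials"], seed=dur_seed)
            duration_frames.append(duration_table(curve))
            nmin = minimum_duration(curve, ref.ci)
            nmin_summary[var] = [
                {"element": r.element, "n_min": r.n_min,
                 "attained": r.attained, "note": r.note}
                for r in nmin
            ]
        if density_rows:
            pd.DataFrame(density_rows).to_csv(
                outdir / "subsample_density.csv", index=False)
        if duration_frames:
            pd.concat(duration_frames, ignore_index=True).to_csv(
                outdir / "subsample_duration.csv", index=False)
        with open(outdir / "minimum_duration.json", "w") as fh:
            json.dump(nmin_summary, fh, indent=2, default=float)
        results["minimum_duration"] = nmin_summary

    log.write(outdir / "run.log")
    with open(outdir / "config_used.json", "w") as fh:
        json.dump(cfg, fh, indent=2)
    return results
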