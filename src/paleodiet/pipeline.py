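"""Staged, seeded pipeline orchestration.

Each stage reads its upstream artifacts from the working directory, writes
its outputs plus a small JSON log, and derives its random stream from the
master seed and the stage name, so any stage is independently reproducible
and a full rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from . import demography as dm
from .calibration import calibrate, read_curve, read_dates, write_dates
from .climate import read_climate
from .effects import cumulative_comparison, effect_size
from .exposure import build_exposures, exposures_frame
from .forest import (FEATURES_CORRECTED, FEATURES_UNCORRECTED,
                     collinearity_screen, fit_forest, residual_diagnostics)
from .qc import classify_zone, qc_filter, read_individuals, write_individuals, ZONES
from .synthetic import make_bundle, write_bundle
from .trends import fit_trend_ensemble

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "qc", "calibrate", "kde", "assign", "trends",
          "model", "effects", "report")


@dataclass
class PipelineConfig:
    """All pipeline tunables.  Defaults are the full-study settings
    (10,000 Monte-Carlo draws, 1000 KDE fits, 10,000 trend runs, 100
    effect-size iterations over 100-value grids, 200-yr binning cutoff,
    0.70 collinearity threshold, tenfold CV); the ``demo`` constructor
    scales the iteration counts down for quick runs."""

    workdir: str = "paleodiet_run"
    seed: int = 1
    # synthetic-data scale
    n_individuals: int = 500
    n_dates_per_zone: int = 300
    window_width: float = 200.0
    # stage tunables
    n_draws: int = 10_000
    n_fits: int = 1000
    n_runs: int = 10_000
    n_iter: int = 100
    m: int = 100
    bandwidth: float = 50.0
    cutoff: float = 200.0
    collinearity_threshold: float = 0.70
    cv_folds: int = 10
    n_trees: int = 500
    kde_variants: tuple[str, ...] = ("uncorrected", "corrected")
    isotopes: tuple[str, ...] = ("d15N", "d13C")

    @classmethod
    def demo(cls, workdir: str, seed: int = 1) -> "PipelineConfig":
        return cls(workdir=workdir, seed=seed, n_individuals=400,
                   n_dates_per_zone=200, n_draws=400, n_fits=60,
                   n_runs=40, n_iter=10, m=40, n_trees=100)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["kde_variants"] = list(self.kde_variants)
        data["isotopes"] = list(self.isotopes)
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def path(self, name: str) -> str:
        return os.path.join(self.workdir, name)


class MissingUpstreamError(FileNotFoundError):
    pass


def _require(cfg: PipelineConfig, filename: str, stage: str) -> str:
    p = cfg.path(filename)
    if not os.path.exists(p):
        raise MissingUpstreamError(
            f"missing artifact {filename!r}: run the {stage!r} stage first")
    return p


def _log(cfg: PipelineConfig, stage: str, info: dict) -> None:
    info = dict(info)
    info.update(stage=stage, seed=cfg.stage_seed(stage),
                config_hash=cfg.config_hash())
    with open(cfg.path(f"log_{stage}.json"), "wt", encoding="utf-8") as fh:
        json.dump(info, fh, indent=2, default=str)


def _date_zone(elevation: float) -> str:
    """Zone for a radiocarbon date (no distance-to-coast column in date
    compilations: below the coastal elevation threshold counts as coastal)."""
    if elevation < 350.0:
        return "coastal"
    return classify_zone(elevation, 100.0)


def _load_calibrated_dates(cfg: PipelineConfig):
    curve = read_curve(_require(cfg, "curve.14c", "simulate"))
    dates = read_dates(_require(cfg, "retained_dates.csv", "qc"))
    densities = [calibrate(d, curve) for d in dates]
    return curve, dates, densities


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig) -> dict:
    bundle = make_bundle(
        seed=cfg.stage_seed("simulate"), n_individuals=cfg.n_individuals,
        n_dates_per_zone=cfg.n_dates_per_zone, n_fits=max(cfg.n_fits // 5, 20),
        bandwidth=cfg.bandwidth, window_width=cfg.window_width,
    )
    write_bundle(bundle, cfg.workdir)
    return {"n_individuals": len(bundle.individuals),
            "n_dates": len(bundle.dates)}


def _stage_qc(cfg: PipelineConfig) -> dict:
    individuals = read_individuals(_require(cfg, "individuals.csv", "simulate"))
    retained, report = qc_filter(individuals)
    write_individuals(retained, cfg.path("retained_individuals.csv"))
    with open(cfg.path("qc_report.json"), "wt", encoding="utf-8") as fh:
        fh.write(report.to_json())
    dates = read_dates(_require(cfg, "dates.csv", "simulate"))
    retained_dates, date_report = dm.qc_dates(dates)
    write_dates(retained_dates, cfg.path("retained_dates.csv"))
    with open(cfg.path("date_qc_report.json"), "wt", encoding="utf-8") as fh:
        fh.write(date_report.to_json())
    return {"individuals_retained": report.retained,
            "dates_retained": date_report.retained}


def _stage_calibrate(cfg: PipelineConfig) -> dict:
    from .calibration import density_median

    _, dates, densities = _load_calibrated_dates(cfg)
    pd.DataFrame({
        "lab_id": [d.lab_id for d in dates],
        "site_id": [d.site_id for d in dates],
        "elevation": [d.elevation for d in dates],
        "median_cal_bp": [density_median(c) for c in densities],
        "mean_cal_bp": [float(np.sum(c.years * c.p)) for c in densities],
    }).to_csv(cfg.path("calibrated_dates.csv"), index=False)
    return {"n_calibrated": len(dates)}


def _stage_kde(cfg: PipelineConfig) -> dict:
    _require(cfg, "calibrated_dates.csv", "calibrate")
    curve, dates, densities = _load_calibrated_dates(cfg)
    med = pd.read_csv(cfg.path("calibrated_dates.csv")).set_index("lab_id")
    grid = dm.default_grid(7400.0, 0.0, 20.0)
    counts = {}
    for zone in ZONES:
        idx = [i for i, d in enumerate(dates) if _date_zone(d.elevation) == zone]
        zdates = [dates[i] for i in idx]
        zdens = [densities[i] for i in idx]
        medians = [float(med.loc[d.lab_id, "median_cal_bp"]) for d in zdates]
        bins = dm.bin_dates(zdates, medians, cutoff=cfg.cutoff)
        ens = dm.composite_kde(
            zdates, zdens, bins, zone=zone, n_fits=cfg.n_fits,
            bandwidth=cfg.bandwidth, grid=grid,
            seed=cfg.stage_seed(f"kde:{zone}"),
        )
        dm.write_ensemble(ens, cfg.path(f"kde_{zone}_uncorrected.csv"),
                          cfg.path(f"kde_{zone}_uncorrected.json"))
        corr = dm.taphonomic_correct(ens)
        dm.write_ensemble(corr, cfg.path(f"kde_{zone}_corrected.csv"),
                          cfg.path(f"kde_{zone}_corrected.json"))
        counts[zone] = len(zdates)
    return {"dates_per_zone": counts}


def _load_ensembles(cfg: PipelineConfig, variant: str):
    out = {}
    for zone in ZONES:
        out[zone] = dm.read_ensemble(
            _require(cfg, f"kde_{zone}_{variant}.csv", "kde"),
            cfg.path(f"kde_{zone}_{variant}.json"))
    return out


def _stage_assign(cfg: PipelineConfig) -> dict:
    individuals = read_individuals(
        _require(cfg, "retained_individuals.csv", "qc"))
    climate = read_climate(_require(cfg, "climate_long.csv", "simulate"))
    curve = read_curve(_require(cfg, "curve.14c", "simulate"))
    ens_u = _load_ensembles(cfg, "uncorrected")
    ens_c = _load_ensembles(cfg, "corrected")
    records = build_exposures(individuals, climate, ens_u, ens_c,
                              n_draws=cfg.n_draws,
                              seed=cfg.stage_seed("assign"), curve=curve)
    exposures_frame(records).to_csv(cfg.path("exposures.csv"), index=False)
    return {"n_exposures": len(records)}


def _stage_trends(cfg: PipelineConfig) -> dict:
    individuals = read_individuals(
        _require(cfg, "retained_individuals.csv", "qc"))
    curve = read_curve(_require(cfg, "curve.14c", "simulate"))
    written = []
    for zone in ZONES:
        for iso in cfg.isotopes:
            try:
                res = fit_trend_ensemble(
                    individuals, zone, iso, n_runs=cfg.n_runs,
                    seed=cfg.stage_seed(f"trends:{zone}:{iso}"), curve=curve)
            except ValueError:
                continue  # too few individuals in this zone
            name = f"trend_{zone}_{iso}.csv"
            res.to_frame().to_csv(cfg.path(name), index=False)
            written.append(name)
    return {"files": written}


def _design_and_response(cfg: PipelineConfig, isotope: str):
    exposures = pd.read_csv(_require(cfg, "exposures.csv", "assign"))
    individuals = read_individuals(
        _require(cfg, "retained_individuals.csv", "qc"))
    iso = {i.id: getattr(i, isotope) for i in individuals}
    exposures = exposures[exposures["individual_id"].map(iso).notna()].copy()
    exposures["response"] = exposures["individual_id"].map(iso)
    return exposures


def _stage_model(cfg: PipelineConfig) -> dict:
    out = {}
    for iso in cfg.isotopes:
        df = _design_and_response(cfg, iso)
        for variant in cfg.kde_variants:
            features = (FEATURES_UNCORRECTED if variant == "uncorrected"
                        else FEATURES_CORRECTED)
            _, corr = collinearity_screen(df[features],
                                          cfg.collinearity_threshold)
            diag = residual_diagnostics(
                df, df["response"].to_numpy(),
                lats=df["lat"].to_numpy(), lons=df["lon"].to_numpy(),
                mean_death_years=df["mean_death_year"].to_numpy(),
                features=features, k=cfg.cv_folds,
                seed=cfg.stage_seed(f"model:{iso}:{variant}"),
                n_trees=cfg.n_trees)
            model = fit_forest(df, df["response"].to_numpy(),
                               features=features, n_trees=cfg.n_trees,
                               seed=cfg.stage_seed(f"model:{iso}:{variant}"))
            key = f"{iso}_{variant}"
            out[key] = {
                "rmse_cv": diag.rmse_cv,
                "pct_variance_explained_cv": diag.pct_variance_explained_cv,
                "oob_r2": model.oob_r2,
                "morans_i": diag.morans_i,
                "acf": {"lags_yr": diag.acf_lags_yr.tolist(),
                        "values": diag.acf_values.tolist()},
                "collinearity_flagged": int(corr["flagged"].sum()),
            }
    with open(cfg.path("model_diagnostics.json"), "wt", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2)
    return {"models": list(out.keys())}


def _stage_effects(cfg: PipelineConfig) -> dict:
    _require(cfg, "model_diagnostics.json", "model")
    rows = []
    for iso in cfg.isotopes:
        df = _design_and_response(cfg, iso)
        for variant in cfg.kde_variants:
            features = (FEATURES_UNCORRECTED if variant == "uncorrected"
                        else FEATURES_CORRECTED)
            model = fit_forest(df, df["response"].to_numpy(),
                               features=features, n_trees=cfg.n_trees,
                               seed=cfg.stage_seed(f"model:{iso}:{variant}"))
            for zone in ZONES:
                zrows = df[df["zone"] == zone]
                if len(zrows) < max(20, cfg.m // 2):
                    continue
                for var in features:
                    dec = effect_size(
                        model, zrows, var, zone=zone, n_iter=cfg.n_iter,
                        m=cfg.m,
                        seed=cfg.stage_seed(f"effects:{iso}:{variant}:{zone}:{var}"))
                    rows.append({
                        "isotope": iso, "kde_variant": variant, "zone": zone,
                        "variable": var, "h": dec.h, "ss_raw": dec.ss_raw,
                        "ss_deducted": dec.ss_deducted,
                        "effect_permil": dec.effect_permil,
                        "percent_of_total": dec.percent_of_total,
                    })
    pd.DataFrame(rows).to_csv(cfg.path("effects.csv"), index=False)
    return {"n_rows": len(rows)}


def _stage_report(cfg: PipelineConfig) -> dict:
    from .effects import EffectDecomposition

    eff = pd.read_csv(_require(cfg, "effects.csv", "effects"))
    frames = []
    for (iso, variant), sub in eff.groupby(["isotope", "kde_variant"]):
        pop_var = ("mean_kde_uncorrected" if variant == "uncorrected"
                   else "mean_kde_corrected")
        decs = [EffectDecomposition(
            zone=r["zone"], variable=r["variable"], h=r["h"],
            ss_raw=r["ss_raw"], ss_deducted=r["ss_deducted"], ss_total=np.nan,
            effect_permil=r["effect_permil"],
            percent_of_total=r["percent_of_total"], n_iterations=cfg.n_iter,
        ) for _, r in sub.iterrows()]
        table = cumulative_comparison(decs, pop_var)
        table.insert(0, "isotope", iso)
        table.insert(1, "kde_variant", variant)
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(cfg.path("cumulative_effects.csv"), index=False)
    return {"n_rows": len(out)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "calibrate": _stage_calibrate,
    "kde": _stage_kde,
    "assign": _stage_assign,
    "trends": _stage_trends,
    "model": _stage_model,
    "effects": _stage_effects,
    "report": _stage_report,
}


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    """Run one pipeline stage; returns its log dict."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    os.makedirs(cfg.workdir, exist_ok=True)
    t0 = time.time()
    info = _STAGE_FUNCS[name](cfg)
    info["elapsed_s"] = round(time.time() - t0, 3)
    _log(cfg, name, info)
    return info


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the per-stage logs."""
    logs = {}
    for name in STAGES:
        logs[name] = run_stage(name, cfg)
    return logs
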