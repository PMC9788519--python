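"""End-to-end pipeline: simulate -> qc -> screen -> train -> evaluate ->
project -> recovery -> inflammation.

Stages communicate through files under the configured output directory so
each is independently runnable and resumable; every artifact carries a
provenance block (schema version, seed, configuration hash).
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

from . import evaluate as ev
from . import inflammation as infl
from . import oplsda, preprocess, recovery, screen, synthgen
from .errors import ConfigError, PhenorevertError
from .sampletable import SampleTable

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
ALL_STAGES = ["simulate", "qc", "screen", "train", "evaluate", "project",
              "recovery", "inflammation"]


@dataclass
class PipelineConfig:
    out_dir: str = "phenorevert_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    generator: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    permutation_runs: int = 100
    cv_folds: int = 5
    cv_repeats: int = 10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**doc)

    def generator_config(self) -> synthgen.GeneratorConfig:
        kwargs = dict(self.generator)
        kwargs.setdefault("seed", self.seed)
        return synthgen.GeneratorConfig(**kwargs)

    def qc_config(self) -> preprocess.QCConfig:
        return preprocess.QCConfig(**self.qc)

    def selection_config(self) -> screen.SelectionConfig:
        return screen.SelectionConfig(**self.selection)

    def recovery_config(self) -> recovery.RecoveryConfig:
        return recovery.RecoveryConfig(**self.recovery)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths and logging
        verbosity excluded, so reruns elsewhere are recognized as identical)."""
        doc = dataclasses.asdict(self)
        doc.pop("out_dir", None)
        doc.pop("log_level", None)
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(cfg: PipelineConfig) -> dict:
    return {"schema_version": SCHEMA_VERSION, "seed": cfg.seed,
            "config_hash": cfg.config_hash()}


def _write_json(path: Path, payload: dict, cfg: PipelineConfig) -> None:
    doc = {"provenance": _provenance(cfg), **payload}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")


def _log_matrix(table: SampleTable) -> pd.DataFrame:
    """Log-transformed (unstandardized) values with zero replacement."""
    values = table.values_matrix()
    half_min = values.where(values > 0).min() / 2.0
    return np.log(values.where(values > 0, half_min.fillna(1.0), axis=1))


# -- stages ----------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    gcfg = cfg.generator_config()
    pop = synthgen.generate_population(gcfg)
    lon = synthgen.generate_longitudinal(gcfg)
    prov = _provenance(cfg)
    pop.to_csv(out / "population.csv", prov)
    lon.to_csv(out / "longitudinal.csv", prov)
    combined = SampleTable(
        pd.concat([pop.data.loc[pop.data["cohort"] == "HC"], lon.data],
                  ignore_index=True), list(pop.variables))
    labeled = preprocess.assign_days_since_covid(combined)
    cyt = synthgen.generate_cytokines(gcfg, labeled)
    with open(out / "cytokines.csv", "w") as fh:
        for key, val in prov.items():
            fh.write(f"# {key}: {val}\n")
        cyt.to_csv(fh, index=False)
    truth = {
        "planted_panel": {n: s * e for n, e, s in gcfg.informative_panel},
        "gev": {"location": gcfg.gev_location, "scale": gcfg.gev_scale,
                "shape": gcfg.gev_shape},
        "true_recovery_day": {
            str(k): float(v) for k, v in
            lon.data.groupby("subject_id")["true_recovery_day"].first().items()},
    }
    _write_json(out / "truth.json", truth, cfg)


def stage_qc(cfg: PipelineConfig, out: Path) -> None:
    pop = SampleTable.from_csv(out / "population.csv")
    kept, discarded = preprocess.qc_filter_dbscan(pop, cfg.qc_config())
    kept.to_csv(out / "population_qc.csv", _provenance(cfg))
    knn = preprocess.knn_distances(pop, cfg.qc_config().k_for_knn_plot)
    _write_json(out / "qc_report.json", {
        "discarded": discarded,
        "n_kept": len(kept),
        "knn_distance_quantiles": {
            q: float(np.quantile(knn, float(q))) for q in ("0.5", "0.9", "0.99")},
    }, cfg)


def stage_screen(cfg: PipelineConfig, out: Path) -> None:
    pop = SampleTable.from_csv(out / "population_qc.csv")
    logx = _log_matrix(pop)
    y = (pop.data["cohort"] != "HC").astype(int).to_numpy()
    results = screen.univariate_screen(logx, y, pop.data, cfg.selection_config())
    results = screen.correlation_prune(results, logx, cfg.selection_config())
    frame = screen.selection_frame(results)
    with open(out / "selection.csv", "w") as fh:
        for key, val in _provenance(cfg).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)


def _selected_panel(out: Path) -> list[str]:
    sel = pd.read_csv(out / "selection.csv", comment="#")
    return sel.loc[sel["kept_after_prune"], "variable"].tolist()


def stage_train(cfg: PipelineConfig, out: Path) -> None:
    pop = SampleTable.from_csv(out / "population_qc.csv")
    panel = _selected_panel(out)
    if not panel:
        raise PhenorevertError("screen selected no variables; cannot train")
    logx = _log_matrix(pop)[panel]
    y = (pop.data["cohort"] != "HC").astype(int).to_numpy()
    Z, stats = preprocess.log_standardize(
        SampleTable(pop.data, panel))
    model = oplsda.fit_oplsda(Z, y, sample_ids=pop.data["sample_id"],
                              scaling=stats)
    cv = oplsda.cross_validate(logx, y, folds=cfg.cv_folds,
                               repeats=cfg.cv_repeats, seed=cfg.seed)
    model.to_json(out / "model.json")
    scores = model.training_scores.copy()
    scores["oof_tpred"] = cv.aggregate
    scores["y"] = y
    with open(out / "scores.csv", "w") as fh:
        for key, val in _provenance(cfg).items():
            fh.write(f"# {key}: {val}\n")
        scores.to_csv(fh, index=False)


def stage_evaluate(cfg: PipelineConfig, out: Path) -> None:
    scores = pd.read_csv(out / "scores.csv", comment="#")
    pop = SampleTable.from_csv(out / "population_qc.csv")
    panel = _selected_panel(out)
    logx = _log_matrix(pop)[panel]
    y = scores["y"].to_numpy()
    curve = ev.roc_auc(scores["oof_tpred"].to_numpy(), y)
    payload = {
        "auc": curve.auc,
        "youden_cutoff": curve.youden_cutoff,
        "youden_j": curve.youden_j,
        "sensitivity": curve.sens_at_cutoff,
        "specificity": curve.spec_at_cutoff,
        "permutation": {},
    }
    if cfg.permutation_runs > 0:
        for metric in ("auc", "sensitivity", "specificity"):
            perm = ev.permutation_test(logx, y, metric=metric,
                                       n_runs=cfg.permutation_runs,
                                       seed=cfg.seed, folds=cfg.cv_folds,
                                       repeats=cfg.cv_repeats)
            payload["permutation"][metric] = {
                "observed": perm.observed, "p_value": perm.p_value,
                "n_runs": perm.n_runs}
    _write_json(out / "evaluation.json", payload, cfg)
    model = oplsda.OPLSModel.from_json(out / "model.json")
    model.cutoff_tpred = float(curve.youden_cutoff)
    model.to_json(out / "model.json")


def stage_project(cfg: PipelineConfig, out: Path) -> None:
    lon = SampleTable.from_csv(out / "longitudinal.csv")
    lon = preprocess.assign_days_since_covid(lon)
    model = oplsda.OPLSModel.from_json(out / "model.json")
    Z, _ = preprocess.log_standardize(lon, model.scaling)
    proj = oplsda.project(model, Z, sample_ids=lon.data["sample_id"])
    proj["subject_id"] = lon.data["subject_id"].to_numpy()
    proj["day"] = lon.data["days_since_covid"].to_numpy()
    for col in ("age", "sex", "severity", "true_recovery_day"):
        proj[col] = lon.data[col].to_numpy()
    with open(out / "projected.csv", "w") as fh:
        for key, val in _provenance(cfg).items():
            fh.write(f"# {key}: {val}\n")
        proj.to_csv(fh, index=False)


def stage_recovery(cfg: PipelineConfig, out: Path) -> None:
    rcfg = cfg.recovery_config()
    model = oplsda.OPLSModel.from_json(out / "model.json")
    proj = pd.read_csv(out / "projected.csv", comment="#")
    d = recovery.distance_to_recovery(proj, model, rcfg)
    frac = recovery.recovered_fraction(d)
    estimates = recovery.estimate_all_subjects(proj, model.hc_mean_tpred, rcfg)
    valid_days = np.array([e.recovery_days for e in estimates if e.valid])
    fit = recovery.fit_gev(valid_days)
    meta = proj.groupby("subject_id").first()
    sev_groups = meta["severity"].to_dict()
    age_groups = {s: (f">={rcfg.age_split}" if a >= rcfg.age_split
                      else f"<{rcfg.age_split}")
                  for s, a in meta["age"].items()}
    subs = {"severity": recovery.subgroup_models(estimates, sev_groups),
            "age": recovery.subgroup_models(estimates, age_groups)}
    est_frame = pd.DataFrame([e.__dict__ for e in estimates])
    with open(out / "recovery_estimates.csv", "w") as fh:
        for key, val in _provenance(cfg).items():
            fh.write(f"# {key}: {val}\n")
        est_frame.to_csv(fh, index=False)
    payload = {
        "gev": {"location": fit.location, "scale": fit.scale,
                "shape": fit.shape, "loglik": fit.loglik, "n": fit.n,
                "converged": fit.converged,
                "mode_days": fit.mode(),
                "model_q95_days": fit.quantile(0.95)},
        "empirical_q95_days": float(np.quantile(valid_days, 0.95)),
        "n_valid": int(len(valid_days)),
        "n_subjects": len(estimates),
        "recovered_fraction": frac,
        "subgroups": {
            dim: {label: {"location": f.location, "scale": f.scale,
                          "shape": f.shape, "n": f.n}
                  for label, f in fits.items()}
            for dim, fits in subs.items()},
    }
    _write_json(out / "recovery.json", payload, cfg)


def stage_inflammation(cfg: PipelineConfig, out: Path) -> None:
    cyt = pd.read_csv(out / "cytokines.csv", comment="#")
    proj = pd.read_csv(out / "projected.csv", comment="#")
    hc_ids = cyt.loc[cyt["day"].isna(), "sample_id"].unique()
    acute_ids = cyt.loc[cyt["day"] <= 7, "sample_id"].unique()
    fc = infl.fold_change_analysis(cyt, acute_ids, hc_ids)
    healthy_mean = {m: g.loc[g["sample_id"].isin(hc_ids), "level"].mean()
                    for m, g in cyt.groupby("marker")}
    decays = []
    mcp = cyt[cyt["marker"] == "MCP-1"]
    for sid, grp in mcp.dropna(subset=["day"]).groupby("subject_id"):
        decays.append(infl.marker_decay(grp, healthy_mean["MCP-1"]))
    rcfg = cfg.recovery_config()
    model = oplsda.OPLSModel.from_json(out / "model.json")
    estimates = recovery.estimate_all_subjects(proj, model.hc_mean_tpred, rcfg)
    payload: dict = {
        "fold_changes": {r.marker: {"log2_fc": r.log2_fc, "p": r.p_mw,
                                    "significant": r.significant}
                         for r in fc},
    }
    try:
        corr = infl.correlate_recovery(decays, estimates)
        payload["mcp1_correlation"] = {"r": corr.r, "p": corr.p,
                                       "slope": corr.slope, "n": corr.n}
    except PhenorevertError as exc:
        payload["mcp1_correlation"] = {"error": str(exc)}
    _write_json(out / "inflammation.json", payload, cfg)


_STAGE_FUNCS = {
    "simulate": stage_simulate, "qc": stage_qc, "screen": stage_screen,
    "train": stage_train, "evaluate": stage_evaluate,
    "project": stage_project, "recovery": stage_recovery,
    "inflammation": stage_inflammation,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in order and aggregate a report bundle.

    On a stage failure a FAILED marker naming the stage is left in the
    output directory and the error propagates (nonzero exit in the CLI);
    partial outputs are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("stage %s ...", stage)
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
            logger.error("stage %s failed: %s", stage, exc)
            raise
    report = {"stages_run": [s for s in ALL_STAGES if s in cfg.stages]}
    for name in ("qc_report", "evaluation", "recovery", "inflammation"):
        path = out / f"{name}.json"
        if path.exists():
            with open(path) as fh:
                doc = json.load(fh)
            doc.pop("provenance", None)
            report[name] = doc
    sel_path = out / "selection.csv"
    if sel_path.exists():
        sel = pd.read_csv(sel_path, comment="#")
        report["panel"] = sel.loc[sel["kept_after_prune"], "variable"].tolist()
    _write_json(out / "report.json", report, cfg)
    _write_markdown_report(out, report)
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return report


def _write_markdown_report(out: Path, report: dict) -> None:
    lines = ["# Phenoreversion pipeline report", ""]
    if "panel" in report:
        lines += [f"Selected panel ({len(report['panel'])} variables): "
                  + ", ".join(report["panel"]), ""]
    if "evaluation" in report:
        e = report["evaluation"]
        lines += [f"Discrimination: AUC {e['auc']:.4f}, Youden cutoff "
                  f"{e['youden_cutoff']:.3f} (sens {e['sensitivity']:.3f}, "
                  f"spec {e['specificity']:.3f})", ""]
    if "recovery" in report:
        g = report["recovery"]["gev"]
        lines += [f"Recovery-day GEV: location {g['location']:.2f} d, scale "
                  f"{g['scale']:.2f} d, shape {g['shape']:.3f} "
                  f"(n = {report['recovery']['n_valid']})",
                  f"Mode {g['mode_days']:.1f} d; model 95% quantile "
                  f"{g['model_q95_days']:.0f} d; empirical 95% quantile "
                  f"{report['recovery']['empirical_q95_days']:.0f} d", ""]
        lines += ["Recovered fraction per day bin: "
                  + ", ".join(f"{k}: {v:.2f}" for k, v in
                              report["recovery"]["recovered_fraction"].items()), ""]
    if "inflammation" in report and "mcp1_correlation" in report["inflammation"]:
        c = report["inflammation"]["mcp1_correlation"]
        if "r" in c:
            lines += [f"MCP-1 vs metabolic recovery: r = {c['r']:.3f} "
                      f"(p = {c['p']:.3g}, n = {c['n']})", ""]
    (out / "report.md").write_text("\n".join(lines))
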