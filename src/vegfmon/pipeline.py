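"""End-to-end orchestration: simulate -> model -> rules -> networks ->
clustering -> survival, driven by a single YAML config.

Every stage derives its own seed from the master seed, logs inputs and
runtime, and writes its exports plus a sidecar metadata record (config
hash + seed) so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation_networks as cn
from . import prognostic_survival as ps
from . import response_progression as rp
from . import trajectory_clustering as tc
from . import trajectory_model as tm
from . import synthetic_cohort as sc

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "load_config"]

log = logging.getLogger("vegfmon")


@dataclass
class PipelineConfig:
    """Single source of truth for a pipeline run."""

    out_dir: str = "vegfmon_out"
    seed: int = 0
    n_patients: int = 70
    missing_rate: float = 0.1
    biomarkers: list[dict] = field(default_factory=lambda: [
        dataclasses.asdict(sc.TIE2_SPEC),
        dataclasses.asdict(sc.CK18_SPEC),
        dataclasses.asdict(sc.KTRANS_SPEC),
    ])
    schedule: list[float] = field(
        default_factory=lambda: list(sc.DEFAULT_SCHEDULE))
    phase_windows: dict = field(
        default_factory=lambda: {k: list(v) for k, v in cn.DEFAULT_PHASES.items()})
    model_biomarker: str = "Tie2"
    run_mcmc: bool = True
    mcmc: dict = field(default_factory=lambda: {
        "n_chains": 3, "burn_in_iters": 500, "sample_iters": 1000, "thin": 1})
    response_threshold: float = 0.30
    progression_threshold: float = 0.40
    response_window_days: float = 63.0
    threshold_grid: list[float] = field(
        default_factory=lambda: [0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5])
    pseudo_trial_reps: int = 50
    vascular_biomarker: str = "Tie2"
    epithelial_biomarker: str = "CK18"
    survival_covariates: list[str] = field(
        default_factory=lambda: ["ratio", "noise"])
    n_bootstrap: int = 200
    km_percentile: float = 33.0
    input_cohort: str | None = None


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return all violations (empty list when the config is valid)."""
    errors: list[str] = []
    if config.n_patients < 1:
        errors.append("n_patients must be >= 1")
    if not 0.0 <= config.missing_rate < 1.0:
        errors.append("missing_rate must lie in [0, 1)")
    if not config.schedule:
        errors.append("schedule must be non-empty")
    names = []
    for spec in config.biomarkers:
        try:
            s = sc.BiomarkerSpec(**spec)
            s.validate()
            names.append(s.name)
        except (TypeError, sc.CohortValidationError) as exc:
            errors.append(f"biomarker spec invalid: {exc}")
    for ref, label in ((config.model_biomarker, "model_biomarker"),
                       (config.vascular_biomarker, "vascular_biomarker"),
                       (config.epithelial_biomarker, "epithelial_biomarker")):
        if names and ref not in names:
            errors.append(f"{label} {ref!r} is not a defined biomarker")
    if not 0.0 <= config.response_threshold < 1.0:
        errors.append("response_threshold must lie in [0, 1)")
    if config.progression_threshold < 0:
        errors.append("progression_threshold must be >= 0")
    if not config.threshold_grid:
        errors.append("threshold_grid must be non-empty")
    if config.pseudo_trial_reps < 1:
        errors.append("pseudo_trial_reps must be >= 1")
    if config.n_bootstrap < 1:
        errors.append("n_bootstrap must be >= 1")
    if not 0.0 < config.km_percentile < 100.0:
        errors.append("km_percentile must lie in (0, 100)")
    return errors


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return None if not np.isfinite(v) else v
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig,
                 stages: list[str] | None = None) -> dict:
    """Execute the analysis stages in order and write a report bundle.

    ``stages`` restricts execution (subset of simulate/fit/rules/networks/
    cluster/survival); simulation always runs first to provide inputs when
    no input cohort is configured.  Returns the summary dict that is also
    written to ``summary.json``.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    all_stages = ["simulate", "fit", "rules", "networks", "cluster", "survival"]
    wanted = stages or all_stages
    bad = set(wanted) - set(all_stages)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": _config_hash(config), "seed": config.seed}
    _write_json(out / "run_meta.json", {**meta,
                                        "config": dataclasses.asdict(config)})
    summary: dict = {"meta": meta, "stages": {}}

    def stage(name):
        def deco(fn):
            if name not in wanted and not (name == "simulate"
                                           and config.input_cohort is None):
                return None
            t0 = time.perf_counter()
            seed = _stage_seed(config.seed, name)
            log.info("stage %s starting (seed %d)", name, seed)
            try:
                result = fn(seed)
            except Exception as exc:
                raise StageFailure(name, exc) from exc
            dt = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, dt)
            summary["stages"][name] = {"seed": seed, "runtime_s": round(dt, 3)}
            return result
        return deco

    specs = [sc.BiomarkerSpec(**b) for b in config.biomarkers]

    # --- simulate (or load) -------------------------------------------------
    if config.input_cohort is not None:
        dataset = sc.read_cohort(config.input_cohort)
    else:
        @stage("simulate")
        def dataset(seed):
            ds = sc.generate_cohort(specs, config.n_patients, config.schedule,
                                    config.missing_rate, seed)
            sc.write_cohort(ds, out / "cohort")
            return ds

    # --- fit ----------------------------------------------------------------
    draws = None
    if "fit" in wanted and config.run_mcmc:
        @stage("fit")
        def draws(seed):
            cfg = tm.MCMCConfig(seed=seed, **config.mcmc)
            d = tm.run_mcmc(dataset, config.model_biomarker,
                            tm.PriorSpec(), cfg)
            d.to_csv(out / "posterior_hyper.csv")
            report = tm.gelman_rubin(d)
            _write_json(out / "convergence.json", report.to_dict())
            summary["convergence"] = report.to_dict()
            return d

    # --- rules --------------------------------------------------------------
    if "rules" in wanted:
        @stage("rules")
        def rules(seed):
            rows = []
            calls = {}
            for marker in (config.vascular_biomarker,
                           config.epithelial_biomarker):
                pairs = []
                for pid in dataset.survival["patient_id"]:
                    s = dataset.patient_series(pid, marker)
                    reps = s[s["replicate"] > 0]["value"].to_numpy(float)
                    if len(reps) >= 2 and np.all(reps > 0):
                        pairs.append((reps[0], reps[1]))
                var = rp.estimate_intra_patient_variation(pairs, marker)
                resp_thr = rp.round_threshold(var.implied_response_fraction)
                calls[marker] = {}
                for pid in dataset.survival["patient_id"]:
                    s = dataset.patient_series(pid, marker)
                    resp = rp.call_response(s, resp_thr,
                                            config.response_window_days)
                    try:
                        prog = rp.call_progression(
                            s, config.progression_threshold)
                    except ValueError:
                        prog = None
                    calls[marker][pid] = prog
                    rows.append((pid, marker, resp.responded,
                                 resp.call_time_days,
                                 prog.called if prog else None,
                                 prog.call_time_days if prog else None,
                                 prog.nadir_value if prog else None,
                                 resp_thr, config.progression_threshold))
            pd.DataFrame(rows, columns=[
                "patient_id", "biomarker", "responded", "response_time_days",
                "progressed", "progression_time_days", "nadir_value",
                "response_threshold", "progression_threshold",
            ]).to_csv(out / "calls.csv", index=False)
            vasc = calls[config.vascular_biomarker]
            epit = calls[config.epithelial_biomarker]
            co = {p for p in vasc
                  if vasc[p] is not None and epit.get(p) is not None}
            lead = rp.compute_lead_time(
                {p: vasc[p] for p in co}, {p: epit[p] for p in co})
            summary["lead_time_days"] = lead
            if draws is not None:
                ev = rp.optimize_progression_threshold(
                    draws, dataset.survival, config.threshold_grid,
                    config.pseudo_trial_reps, seed)
                _write_json(out / "threshold_evaluation.json", ev.to_dict())
                summary["optimum_threshold"] = ev.optimum
            return calls

    # --- networks -----------------------------------------------------------
    if "networks" in wanted:
        @stage("networks")
        def networks(seed):
            snaps = {}
            for phase, window in config.phase_windows.items():
                try:
                    snap = cn.build_network(dataset, tuple(window),
                                            phase=phase)
                except ValueError as exc:
                    log.warning("network phase %s skipped: %s", phase, exc)
                    continue
                snaps[phase] = snap
                snap.edges().to_csv(out / f"network_{phase}.tsv",
                                    sep="\t", index=False)
                snap.r_matrix.to_csv(out / f"network_{phase}_matrix.csv")
            names = list(snaps)
            if len(names) >= 2:
                _, diff_summary = cn.diff_networks(snaps[names[0]],
                                                   snaps[names[1]])
                summary["network_diff"] = diff_summary
            return snaps

    # --- cluster ------------------------------------------------------------
    if "cluster" in wanted:
        @stage("cluster")
        def cluster(seed):
            assign = tc.cluster_trajectories(dataset,
                                             config.vascular_biomarker)
            pd.Series(assign.labels, name="cluster").rename_axis(
                "patient_id").to_csv(out / "clusters.csv")
            reports = {}
            for marker in dataset.biomarkers():
                cmp_ = tc.project_clusters(assign, dataset, marker)
                reports[marker] = {"p_value": cmp_.p_value,
                                   "medians": cmp_.medians}
                if cmp_.curves is not None:
                    cmp_.curves.to_csv(out / f"cluster_curves_{marker}.csv",
                                       index=False)
            _write_json(out / "cluster_tests.json", reports)
            summary["cluster_tests"] = reports
            return assign

    # --- survival -----------------------------------------------------------
    if "survival" in wanted:
        @stage("survival")
        def survival(seed):
            rng = np.random.default_rng(seed)
            rec = dataset.survival.copy()
            # Pre-treatment covariates: baselines of the modeled markers,
            # their ratio, and a pure-noise control.
            for marker in dataset.biomarkers():
                rec[marker] = [dataset.baseline_value(p, marker)
                               for p in rec["patient_id"]]
            markers = dataset.biomarkers()
            if len(markers) >= 2:
                rec = ps.ratio_covariate(rec, markers[0], markers[1],
                                         name="ratio")
            rec["noise"] = rng.standard_normal(len(rec))
            covs = [c for c in config.survival_covariates if c in rec.columns]
            uni = ps.univariate_screen(rec, covs)
            entered = [u.covariate for u in uni if u.enters]
            report = {"univariate": [dataclasses.asdict(u) for u in uni]}
            if len(entered) >= 1:
                model = (ps.multivariate_select(rec, entered)
                         if len(entered) >= 2 else None)
                final = model.covariates if model else entered
                if final:
                    boot = ps.bootstrap_validate(rec, final,
                                                 config.n_bootstrap, seed)
                    report["bootstrap"] = dataclasses.asdict(boot)
                if model:
                    report["multivariate"] = dataclasses.asdict(model)
            if "ratio" in rec.columns:
                km = ps.percentile_split_km(rec.dropna(subset=["ratio"]),
                                            "ratio", config.km_percentile)
                km.curves.to_csv(out / "km_curves.csv", index=False)
                report["km_split"] = {
                    "group_sizes": km.group_sizes, "medians": km.medians,
                    "logrank_p": km.logrank_p, "cut_value": km.cut_value,
                }
            _write_json(out / "survival_report.json", report)
            summary["survival"] = {k: v for k, v in report.items()
                                   if k != "univariate"}
            return report

    _write_json(out / "summary.json", summary)
    return summary
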