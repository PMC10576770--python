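"""Orchestration: simulate -> preprocess -> baseline -> features -> train
-> predict -> evaluate -> response as one reproducible, fully logged run.

Every stage writes plain CSV/JSON artifacts into the run directory and a
manifest records row counts and SHA-256 hashes of every output, so a
rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import preprocess as pp
from .baseline import establish_baselines
from .config import RunConfig
from .features import build_feature_table, minute_feature_table
from .model import PainIndexModel, PainIndexResults
from .simulate import generate_cohort

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _rows(path) -> int:
    with open(path, "rb") as fh:
        return max(sum(1 for _ in fh) - 1, 0)


class _Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.ctx: dict = {}
        self.manifest = {"seed": cfg.seed, "stages": []}
        os.makedirs(cfg.outdir, exist_ok=True)

    def path(self, name) -> str:
        return os.path.join(self.cfg.outdir, name)

    def record(self, stage: str, outputs: dict) -> None:
        self.manifest["stages"].append({
            "stage": stage,
            "outputs": {os.path.basename(p): {"sha256": _sha256(p),
                                              "rows": _rows(p)}
                        for p in outputs.values()
                        if p.endswith((".csv", ".json"))}})

    def need(self, key: str, loader, stage: str):
        """Fetch a prior stage's product, reloading from disk if needed."""
        if key not in self.ctx:
            try:
                self.ctx[key] = loader()
            except (FileNotFoundError, ValueError) as exc:
                raise PipelineError(
                    f"stage '{stage}' requires {key!r}, which no earlier "
                    f"stage produced: {exc}") from exc
        return self.ctx[key]


def _stage_simulate(run: _Run) -> None:
    gen_cfg = run.cfg.generator
    cohort = generate_cohort(gen_cfg)
    paths = cohort.write(run.cfg.outdir)
    run.ctx["vitals_raw"] = cohort.vitals
    run.ctx["assessments"] = cohort.assessments
    run.ctx["events"] = cohort.events
    run.ctx["demographics"] = cohort.demographics
    run.ctx["ground_truth"] = cohort.ground_truth
    run.record("simulate", paths)


def _stage_preprocess(run: _Run) -> None:
    vitals = run.need("vitals_raw",
                      lambda: pp.read_vitals(run.path("vitals.csv")),
                      "preprocess")
    kept, log = pp.apply_noise_filter(vitals, run.cfg.noise_rules)
    out_v = run.path("vitals_filtered.csv")
    out_l = run.path("exclusions.csv")
    pp.write_vitals(kept, out_v)
    log.to_csv(out_l, index=False)
    run.ctx["vitals"] = kept
    run.record("preprocess", {"vitals": out_v, "log": out_l})


def _stage_baseline(run: _Run) -> None:
    vitals = run.need("vitals",
                      lambda: pp.read_vitals(run.path("vitals_filtered.csv")),
                      "baseline")
    baselines, attempts = establish_baselines(vitals, run.cfg.stability)
    out_b = run.path("baselines.csv")
    out_a = run.path("baseline_attempts.csv")
    baselines.to_csv(out_b, index=False)
    attempts.to_csv(out_a, index=False)
    run.ctx["baselines"] = baselines
    run.record("baseline", {"baselines": out_b, "attempts": out_a})


def _load_baselines(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: not a baselines table")
    return df


def _stage_features(run: _Run) -> None:
    vitals = run.need("vitals",
                      lambda: pp.read_vitals(run.path("vitals_filtered.csv")),
                      "features")
    baselines = run.need("baselines",
                         lambda: _load_baselines(run.path("baselines.csv")),
                         "features")
    assessments = run.need(
        "assessments",
        lambda: pp.read_assessments(run.path("assessments.csv")), "features")
    demographics = run.need(
        "demographics",
        lambda: pp.read_demographics(run.path("demographics.csv")),
        "features")
    feats, drops = build_feature_table(vitals, baselines, assessments,
                                       demographics, run.cfg.features)
    out_f = run.path("features.csv")
    out_d = run.path("feature_drops.csv")
    feats.to_csv(out_f, index=False)
    drops.to_csv(out_d, index=False)
    run.ctx["features"] = feats
    run.record("features", {"features": out_f, "drops": out_d})


def _load_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: not a feature table")
    return df


def _stage_train(run: _Run) -> None:
    feats = run.need("features",
                     lambda: _load_features(run.path("features.csv")),
                     "train")
    model = PainIndexModel(feats, run.cfg.model, run.cfg.features)
    results = model.fit()
    out_m = run.path("model.joblib")
    results.save(out_m)
    run.ctx["model"] = model
    run.ctx["results"] = results
    run.record("train", {"model": out_m})


def _stage_predict(run: _Run) -> None:
    if "results" not in run.ctx:
        if os.path.exists(run.path("model.joblib")):
            run.ctx["results"] = PainIndexResults.load(run.path("model.joblib"))
        else:
            raise PipelineError("stage 'predict' failed: predict requires "
                                "a model (enable the train stage)")
    results = run.ctx["results"]
    feats = run.need("features",
                     lambda: _load_features(run.path("features.csv")),
                     "predict")
    scored = results.predict_series(feats.drop(columns=["label"]))
    scored["pain_index_pct"] = (100 * scored.pop("pain_index")).round(2)
    out_s = run.path("painindex.csv")
    scored.to_csv(out_s, index=False)
    outputs = {"scores": out_s}

    events = run.need("events",
                      lambda: pp.read_events(run.path("events.csv")),
                      "predict")
    if len(events):
        w = run.cfg.response.window_min
        minutes: dict = {}
        for _, r in events.iterrows():
            minutes.setdefault(r["patient_id"], set()).update(
                range(int(r["t_min"]) - w, int(r["t_min"]) + w + 1))
        vitals = run.need(
            "vitals", lambda: pp.read_vitals(run.path("vitals_filtered.csv")),
            "predict")
        baselines = run.need(
            "baselines", lambda: _load_baselines(run.path("baselines.csv")),
            "predict")
        assessments = run.need(
            "assessments",
            lambda: pp.read_assessments(run.path("assessments.csv")),
            "predict")
        demographics = run.need(
            "demographics",
            lambda: pp.read_demographics(run.path("demographics.csv")),
            "predict")
        mf = minute_feature_table(vitals, baselines, assessments,
                                  demographics, minutes, run.cfg.features)
        series = results.predict_series(mf)
        out_pm = run.path("painindex_minutes.csv")
        series.to_csv(out_pm, index=False)
        run.ctx["painindex_minutes"] = series
        outputs["minutes"] = out_pm
    run.record("predict", outputs)


def _stage_evaluate(run: _Run) -> None:
    feats = run.need("features",
                     lambda: _load_features(run.path("features.csv")),
                     "evaluate")
    model = run.ctx.get("model") or PainIndexModel(feats, run.cfg.model,
                                                   run.cfg.features)
    cv = model.cross_validate()
    scores, labels = model.out_of_fold_scores()
    conf = ev.confusion_at_threshold(scores, labels)
    auroc = ev.roc_auc(scores, labels)
    metrics = {
        "cv_auroc_mean": cv.mean, "cv_auroc_sd": cv.sd,
        "cv_repeats": len(cv.per_repeat),
        "oof_auroc": auroc, "auroc_band": ev.classify_auroc(auroc),
        "youden_threshold": conf["threshold"],
        "sensitivity": conf["sensitivity"],
        "specificity": conf["specificity"],
        "ppv": conf["ppv"], "npv": conf["npv"],
        "harmonic_mean_sens_spec": ev.harmonic_mean_metrics(
            conf["sensitivity"], conf["specificity"])
        if conf["sensitivity"] > 0 and conf["specificity"] > 0 else None,
        "n_assessments": int(len(labels)),
        "positive_rate": float(np.mean(labels)),
    }
    out = run.path("metrics.json")
    with open(out, "w") as fh:
        json.dump(metrics, fh, indent=2)
    run.ctx["metrics"] = metrics
    run.record("evaluate", {"metrics": out})


def _stage_response(run: _Run) -> None:
    series = run.need(
        "painindex_minutes",
        lambda: pd.read_csv(run.path("painindex_minutes.csv")), "response")
    events = run.need("events",
                      lambda: pp.read_events(run.path("events.csv")),
                      "response")
    assessments = run.need(
        "assessments",
        lambda: pp.read_assessments(run.path("assessments.csv")), "response")
    rc = run.cfg.response
    res = ev.fentanyl_response_analysis(
        series, events, assessments, rc.window_min, rc.cpot_search_min,
        rc.eval_offset_min, rc.dose_range_ug)
    out_t = run.path("trajectories.csv")
    out_r = run.path("response_records.csv")
    out_c = run.path("comparison.csv")
    res.trajectories.to_csv(out_t, index=False)
    res.records.to_csv(out_r, index=False)
    comp_rows = []
    for group, d in res.stats["within"].items():
        comp_rows.append({"comparison": f"within_{group}", **d})
    comp_rows.append({"comparison": "between_at_t60", **res.stats["between"]})
    pd.DataFrame(comp_rows).to_csv(out_c, index=False)
    try:
        ev.plot_response(res.trajectories, run.path("response.png"))
    except Exception:
        pass  # plotting is best-effort; the CSVs are the record
    run.ctx["response"] = res
    run.record("response", {"trajectories": out_t, "records": out_r,
                            "comparison": out_c})


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "baseline": _stage_baseline,
    "features": _stage_features,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "response": _stage_response,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    run = _Run(cfg)
    for name in ("simulate", "preprocess", "baseline", "features",
                 "train", "predict", "evaluate", "response"):
        if name not in cfg.stages:
            continue
        try:
            _STAGES[name](run)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(run.manifest, fh, indent=2)
    return run.manifest
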