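"""End-to-end pipeline: simulate → detect → epoch → features → classify →
report, with every stage's artifacts written to an output directory and the
whole run reproducible from a single master seed."""

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

from . import biomech, classify, features, n1
from .classify import FEATURE_SETS, HyperGrid
from .synthetic import CohortParams, SubjectRecording, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "write_report",
           "detect_cohort_epochs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline constants in one place, with the protocol defaults.

    ``thresholds``: the COPv event threshold is ``copv_k_sd`` quiet-stance SDs
    (default 3) and the N1/control trough depth is ``n1_k_sd`` baseline SDs
    (default 2); ``ttb_velocity_floor`` (cm/s) and ``ttb_cap_s`` bound the
    time-to-boundary division.
    """

    cohort: CohortParams = field(default_factory=CohortParams)
    n1_search_window_ms: tuple = (-250.0, -100.0)
    feature_window_ms: tuple = (-300.0, -50.0)
    copv_k_sd: float = 3.0
    n1_k_sd: float = 2.0
    ttb_velocity_floor: float = 0.6
    ttb_cap_s: float = 10.0
    refractory_s: float = 0.5
    control_min_sep_ms: float = 400.0
    control_exclusion_ms: float = 300.0
    feature_summary: str = "median"
    grid: HyperGrid = field(default_factory=HyperGrid)
    feature_sets: tuple = ("ha", "sh", "copv", "ttb", "all4")
    repeats: int = 10
    master_seed: int = 0

    def validate(self) -> None:
        fw, ew = self.feature_window_ms, (-300.0, 100.0)
        if not (ew[0] <= fw[0] < fw[1] <= ew[1]):
            raise ValueError("feature window must nest inside the epoch window")
        if self.copv_k_sd <= 0 or self.n1_k_sd <= 0:
            raise ValueError("SD multipliers must be positive")
        for s in self.feature_sets:
            if s not in FEATURE_SETS:
                raise ValueError(f"unknown feature set '{s}'")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    config_hash: str
    counts: dict
    stage_seconds: dict
    outputs: dict


def _detect_subject(rec: SubjectRecording, cfg: PipelineConfig):
    """events, N1s, control times and labeled epochs for one subject."""
    zone = biomech.StabilityZone(*rec.stability_limits_cm)
    quiet = (0.0, rec.gain_schedule.trial_duration_s)
    derived = biomech.derive(rec.cop_ap, zone, quiet_window=quiet,
                             ttb_cap_s=cfg.ttb_cap_s,
                             velocity_floor=cfg.ttb_velocity_floor)
    # re-apply the configured SD multiplier on top of the 3-SD default
    thr = derived.copv_threshold_cm_s * (cfg.copv_k_sd / 3.0)
    events = biomech.detect_instability_events(derived.copv, thr, cfg.refractory_s)
    ic_corr, stats = n1.baseline_correct(rec.ic_trace)
    n1s = n1.detect_n1(ic_corr, stats, events, cfg.n1_search_window_ms,
                       depth_k=cfg.n1_k_sd)
    controls = n1.detect_control_troughs(
        ic_corr, stats, n1s, min_sep_ms=cfg.control_min_sep_ms,
        exclusion_ms=cfg.control_exclusion_ms,
        task_window=(0.0, rec.cop_ap.t_end), events=events)
    centers = ([(e.time_s, 1) for e in n1s]
               + [(t, 0) for t in controls])
    centers.sort(key=lambda c: c[0])
    epochs = n1.extract_epochs(rec, derived, centers)
    return derived, events, n1s, controls, epochs


def detect_cohort_epochs(recordings: list, cfg: PipelineConfig):
    """Run detection and epoching for every subject; returns (per-subject
    detail dict, pooled epoch list)."""
    detail = {}
    pooled = []
    for rec in recordings:
        derived, events, n1s, controls, epochs = _detect_subject(rec, cfg)
        detail[rec.subject_id] = {
            "derived": derived, "events": events, "n1s": n1s,
            "controls": controls, "epochs": epochs,
        }
        pooled.extend(epochs)
    return detail, pooled


def run_pipeline(config: PipelineConfig, out_dir, force: bool = False) -> RunManifest:
    """Execute all stages, writing every intermediate artifact under
    ``out_dir``; fully deterministic given ``config.master_seed``."""
    config.validate()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output dir {out} not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    stage_s: dict = {}

    def _stage(name):
        t0 = time.perf_counter()
        return lambda: stage_s.__setitem__(name, round(time.perf_counter() - t0, 3))

    try:
        done = _stage("simulate")
        cohort_params = dataclasses.replace(config.cohort, seed=config.master_seed)
        recordings = generate_cohort(cohort_params)
        write_cohort(recordings, out / "cohort", cohort_params)
        counts["subjects"] = len(recordings)
        done()

        done = _stage("detect")
        detail, epochs = detect_cohort_epochs(recordings, config)
        for sid, d in detail.items():
            ev = [{"peak_time_s": e.peak_time_s,
                   "peak_copv_cm_s": e.peak_copv_cm_s,
                   "zero_crossing_time_s": e.zero_crossing_time_s}
                  for e in d["events"]]
            (out / "cohort" / sid / "events.json").write_text(json.dumps(ev, indent=1))
        counts["events"] = sum(len(d["events"]) for d in detail.values())
        counts["n1s"] = sum(len(d["n1s"]) for d in detail.values())
        counts["controls"] = sum(len(d["controls"]) for d in detail.values())
        counts["epochs"] = len(epochs)
        index = [{"subject": e.subject_id, "center_time_s": e.center_time_s,
                  "label": e.label,
                  "n_samples": {k: len(v[1]) for k, v in e.traces.items()}}
                 for e in epochs]
        (out / "epochs_index.json").write_text(json.dumps(index, indent=1))
        done()

        done = _stage("features")
        table = features.feature_table(epochs, config.feature_window_ms,
                                       config.feature_summary)
        table.to_csv(out / "features.csv", index=False)
        descriptives = {
            "class_contrast": features.class_contrast(table),
            "correlation_screen": features.correlation_screen(table),
        }
        (out / "descriptives.json").write_text(json.dumps(descriptives, indent=1))
        done()

        done = _stage("classify")
        all_results = []
        for fs_name in config.feature_sets:
            all_results.extend(classify.loso_evaluate(
                table, fs_name, grid=config.grid, repeats=config.repeats,
                seed=config.master_seed,
                collect_importance=(fs_name == "all4"),
            ))
        runs = pd.DataFrame([{
            "left_out_subject": r.left_out_subject, "repeat": r.repeat_index,
            "feature_set": r.feature_set, "accuracy": r.accuracy,
            "sensitivity": r.sensitivity, "auc": r.auc, "n_test": r.n_test,
            "best_params": json.dumps(r.best_params),
        } for r in all_results])
        runs.to_csv(out / "runs.csv", index=False)
        counts["runs"] = len(runs)
        comparison = (classify.compare_models(all_results)
                      if len(config.feature_sets) > 1 else None)
        if comparison is not None:
            (out / "comparison.json").write_text(json.dumps(comparison, indent=1))
        imps = [r.importance for r in all_results if r.importance is not None]
        importance = None
        if imps:
            mean_abs = {k: float(np.mean([i.mean_abs_shap[k] for i in imps]))
                        for k in imps[0].mean_abs_shap}
            direction = {k: int(np.sign(np.mean([i.direction[k] for i in imps])))
                         for k in imps[0].direction}
            ranking = sorted(mean_abs, key=mean_abs.get, reverse=True)
            importance = {"mean_abs_shap": mean_abs, "direction": direction,
                          "ranking": ranking}
            (out / "importance.json").write_text(json.dumps(importance, indent=1))
        done()

        done = _stage("report")
        latencies = [x.latency_ms for d in detail.values() for x in d["n1s"]]
        manifest = RunManifest(
            config_hash=config.config_hash(), counts=counts,
            stage_seconds=stage_s,
            outputs={p.name: str(p) for p in out.iterdir()},
        )
        write_report(out, manifest, comparison, descriptives, importance, latencies)
        done()
    except Exception as exc:  # annotate the failing stage for the operator
        stage = [s for s in ("simulate", "detect", "features", "classify", "report")
                 if s not in stage_s]
        raise RuntimeError(
            f"pipeline failed in stage '{stage[0] if stage else '?'}': {exc}"
        ) from exc

    (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest),
                                                  indent=1, default=str))
    return manifest


def write_report(out_dir, manifest: RunManifest, comparison, descriptives,
                 importance, latencies_ms) -> None:
    """Machine-readable JSON + human-readable Markdown report with the
    metrics table, the per-parameter effect sizes, the importance ranking and
    the N1 latency summary."""
    out = Path(out_dir)
    lat = np.asarray(latencies_ms, dtype=float)
    lat_summary = None
    if lat.size:
        lat_summary = {"mean_ms": float(lat.mean()),
                       "se_ms": float(lat.std(ddof=1) / np.sqrt(lat.size)),
                       "n": int(lat.size)}
    report = {"config_hash": manifest.config_hash, "counts": manifest.counts,
              "n1_latency": lat_summary, "metrics": comparison,
              "effect_sizes": descriptives["class_contrast"],
              "importance": importance}
    (out / "report.json").write_text(json.dumps(report, indent=1))

    lines = ["# Balance instability / N1 prediction report", "",
             f"Config hash: `{manifest.config_hash}`", "",
             "## Record counts", ""]
    lines += [f"- {k}: {v}" for k, v in manifest.counts.items()]
    if lat_summary:
        lines += ["", "## N1 latency before the corrective zero-crossing", "",
                  f"mean ± SE: {lat_summary['mean_ms']:.1f} ± "
                  f"{lat_summary['se_ms']:.1f} ms (n = {lat_summary['n']})"]
    lines += ["", "## Effect sizes (Instability vs Control)", "",
              "| feature | instability mean ± SE | control mean ± SE | d | p |",
              "|---|---|---|---|---|"]
    for k, v in descriptives["class_contrast"].items():
        lines.append(
            f"| {k} | {v['instability_mean']:.3g} ± {v['instability_se']:.2g} "
            f"| {v['control_mean']:.3g} ± {v['control_se']:.2g} "
            f"| {v['cohens_d']:.2f} | {v['welch_p']:.2g} |")
    if comparison is not None:
        lines += ["", "## Classification metrics (mean ± SE over runs; chance 50%)",
                  "", "| feature set | accuracy | sensitivity | AUC |",
                  "|---|---|---|---|"]
        for s, row in comparison["table"].items():
            lines.append(
                "| " + s + " | " + " | ".join(
                    f"{row[m]['mean']:.3f} ± {row[m]['se']:.3f}"
                    for m in ("accuracy", "sensitivity", "auc")) + " |")
    if importance is not None:
        lines += ["", "## Feature importance (mean |Shapley value|, combined model)",
                  ""]
        for k in importance["ranking"]:
            sign = {1: "+", -1: "-", 0: "0"}[importance["direction"][k]]
            lines.append(f"- {k}: {importance['mean_abs_shap'][k]:.4f} "
                         f"(direction {sign})")
    (out / "report.md").write_text("\n".join(lines) + "\n")
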