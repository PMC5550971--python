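"""End-to-end pipeline: generate -> (fit) -> classify -> associate -> report.

The pipeline has two modes mirroring the generator:

* ``calibrated`` (default): draw a labelled cohort from the calibrated
  feature generator, run the eight-classifier study on datasets D1-D3,
  generate outcomes and the association/group-comparison tables, and
  write a versioned report bundle (CSV tables + ``summary.json``).

* ``pipeline``: run forward-model-backed subjects through the inverse
  stage (contractility recovery) and report ground-truth vs recovered
  T_req alongside the forward biomarkers.  The classification study
  needs cohort-scale n and is run only when at least 12 subjects are
  requested.

Every stage is seeded from the single pipeline seed; rerunning with the
same configuration reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import associate as assoc
from .cohort import (CohortConfig, DATASETS, dataset_columns, generate_cohort,
                     generate_feature_table, generate_outcomes)
from .inverse import fit_contractility

log = logging.getLogger("lvmech")

__all__ = ["PipelineConfig", "run_pipeline"]

_OUTCOME_BASELINES = ["LVEF", "GLS", "CS", "T_req", "T_a", "sigma_f",
                      "T_a_norm", "sigma_f_norm", "C_s"]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    mode: str = "calibrated"          # calibrated | pipeline
    out_dir: str = "lvmech_out"
    n_healthy: int | None = None      # defaults to the cohort config (27)
    n_mi: int | None = None           # defaults to the cohort config (11)
    noise: float = 0.0                # pipeline-mode observation noise
    cohort_yaml: str | None = None    # override the generator calibration
    plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("calibrated", "pipeline"):
            raise ValueError("mode must be 'calibrated' or 'pipeline'")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _classification_stage(table: pd.DataFrame, seed: int, out: Path,
                          plots: bool) -> dict:
    tables = {name: table[["subject_id", "label"] + dataset_columns(name)]
              for name in DATASETS}
    study = cls.run_study(tables, seed=seed)
    rows, roc_rows, rank_rows = [], [], []
    summary = {}
    for name, res in study["datasets"].items():
        df = res["metrics"].copy()
        df.insert(0, "dataset", name)
        rows.append(df)
        for (x, y) in res["roc_points"]:
            roc_rows.append({"dataset": name, "fpr": x, "tpr": y})
        r = res["ranks"].copy()
        r.insert(0, "dataset", name)
        r.insert(1, "feature", r.index)
        rank_rows.append(r.reset_index(drop=True))
        summary[name] = {"auroc": res["auroc"],
                         "hull": res["hull"]["vertices"]}
        res["importance"].to_csv(out / f"importance_{name}.csv")
    pd.concat(rows, ignore_index=True).to_csv(out / "classification_metrics.csv",
                                              index=False)
    pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False)
    pd.concat(rank_rows, ignore_index=True).to_csv(out / "importance_ranks.csv",
                                                   index=False)
    study["method_ranking"].to_csv(out / "method_ranking.csv", index=False)
    summary["method_ranking"] = study["method_ranking"].to_dict("records")
    if plots:
        _plot_roc(study, out)
    return summary


def _plot_roc(study: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(study["datasets"]), figsize=(12, 4))
    axes = np.atleast_1d(axes)
    for ax, (name, res) in zip(axes, study["datasets"].items()):
        pts = np.array(res["roc_points"])
        hull = np.array(res["hull"]["vertices"])
        ax.plot([0, 1], [0, 1], ":", color="grey")
        ax.plot(pts[:, 0], pts[:, 1], "o", ms=5)
        ax.plot(hull[:, 0], hull[:, 1], "--k")
        ax.set(title=f"{name} (AUROC {res['auroc']:.2f})",
               xlabel="1 - specificity", ylabel="sensitivity",
               xlim=(-0.02, 1.02), ylim=(-0.02, 1.02))
    fig.tight_layout()
    fig.savefig(out / "roc_hull.png", dpi=120)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured pipeline and return the summary dict.

    Writes the report bundle under ``cfg.out_dir``; the same summary is
    stored as ``summary.json``.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    ccfg = (CohortConfig.from_yaml(cfg.cohort_yaml) if cfg.cohort_yaml
            else CohortConfig.default())
    summary: dict = {"config": asdict(cfg), "stages": {}}
    rng_seeds = np.random.SeedSequence(cfg.seed).generate_state(8)

    if cfg.mode == "calibrated":
        t0 = time.time()
        table = generate_feature_table(ccfg, n_healthy=cfg.n_healthy,
                                       n_mi=cfg.n_mi, seed=int(rng_seeds[0]),
                                       extra=True)
        table = generate_outcomes(ccfg, table, seed=int(rng_seeds[1]))
        table.to_csv(out / "cohort.csv", index=False)
        for name in DATASETS:
            table[["subject_id", "label"] + dataset_columns(name)].to_csv(
                out / f"features_{name}.csv", index=False)
        mi = table[table["label"] == "mi"]
        mi[["subject_id", "dLVEF6", "GLS6"]].to_csv(out / "outcomes.csv", index=False)
        summary["stages"]["generate"] = {
            "n_healthy": int((table["label"] == "healthy").sum()),
            "n_mi": int(len(mi)), "seconds": time.time() - t0}
        log.info("generated cohort: %s", summary["stages"]["generate"])

        t0 = time.time()
        summary["stages"]["classify"] = _classification_stage(
            table, int(rng_seeds[2]), out, cfg.plots)
        summary["stages"]["classify"]["seconds"] = time.time() - t0

        t0 = time.time()
        at = assoc.association_table(mi, _OUTCOME_BASELINES, ["dLVEF6", "GLS6"])
        at.to_csv(out / "associations.csv", index=False)
        gc = assoc.compare_table(
            table, ["SBP", "EDV", "LVEF", "GLS", "CS", "T_req", "T_a",
                    "sigma_f", "T_a_norm", "sigma_f_norm", "C_s"])
        gc.to_csv(out / "group_comparison.csv", index=False)
        summary["stages"]["associate"] = {
            "significant": at.loc[at["significant"],
                                  ["baseline", "outcome", "r"]].to_dict("records"),
            "seconds": time.time() - t0}
    else:  # pipeline mode
        t0 = time.time()
        n_h = 3 if cfg.n_healthy is None else cfg.n_healthy
        n_m = 2 if cfg.n_mi is None else cfg.n_mi
        subjects = generate_cohort(ccfg, seed=int(rng_seeds[0]), noise=cfg.noise,
                                   n_healthy=n_h, n_mi=n_m)
        rows = []
        for i, s in enumerate(subjects):
            mode = "mi" if s.group == "mi" else "healthy"
            fit = fit_contractility(s.measurements, s.mesh, s.fibers, s.infarct,
                                    s.passive_params, mode=mode)
            rows.append({"subject_id": f"P{i:03d}", "label": s.group,
                         "EDV": s.measurements.edv, "ESV": s.measurements.esv,
                         "SBP": s.measurements.sbp, "EDP": s.measurements.edp,
                         "T_req_true": s.t_req_true, "T_req_fit": fit.T_req,
                         "abs_error": abs(fit.T_req - s.t_req_true),
                         "n_remote": s.n_remote, **s.biomarkers})
            log.info("subject %d/%d (%s): true %.1f fit %.1f kPa",
                     i + 1, len(subjects), s.group, s.t_req_true, fit.T_req)
        rec = pd.DataFrame(rows)
        rec.to_csv(out / "recovery.csv", index=False)
        summary["stages"]["fit"] = {
            "n_subjects": len(rec),
            "median_abs_error_kpa": float(rec["abs_error"].median()),
            "max_abs_error_kpa": float(rec["abs_error"].max()),
            "seconds": time.time() - t0}
        if len(rec) >= 12:
            feats = rec.rename(columns={"T_req_fit": "T_req"})
            cols = ["subject_id", "label", "T_req", "T_a", "SBP", "EDV",
                    "C_s", "T_a_norm"]
            summary["stages"]["classify"] = _classification_stage(
                feats[cols], int(rng_seeds[2]), out, cfg.plots)

    summary["seconds_total"] = time.time() - t_start
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_json_default, sort_keys=True))
    log.info("pipeline finished in %.1fs -> %s", summary["seconds_total"], out)
    return summary
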