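"""End-to-end runner: simulate -> ingest -> metrics -> fit -> SHAP -> report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import ClusteredQuadraticLogit
from .audit_log import read_encounter_table, read_event_log
from .event_shap import EventShapModel, aggregate_by_metric, build_event_features
from .metrics import METRICS_CSV_COLUMNS, compute_metrics, outlier_outcome_association, tukey_flags
from .simulate import SimConfig, generate_cohort, write_fixture

log = logging.getLogger("cogload")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit routing."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: Path = Path("cogload_out")
    event_log_path: Path | None = None
    encounter_table_path: Path | None = None
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    gap_minutes: float = 30.0
    n_repeats: int = 20
    seed: int = 0
    curve_points: int = 200


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:
                raise StageError(name, str(err)) from err
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("simulate")
def _simulate(cfg: PipelineConfig) -> dict[str, Path]:
    events, meta = generate_cohort(cfg.sim)
    log.info("simulated %d events across %d encounters", len(events), len(meta))
    return write_fixture(events, meta, cfg.out_dir / "data")


@_stage("ingest")
def _ingest(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    events = read_event_log(cfg.event_log_path)
    meta = read_encounter_table(cfg.encounter_table_path)
    log.info("read %d events, %d encounters", len(events), len(meta))
    return events, meta


@_stage("metrics")
def _metrics(cfg: PipelineConfig, events: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    records = compute_metrics(events, gap_minutes=cfg.gap_minutes)
    records = tukey_flags(records)
    records = records.merge(meta, on="encounter_id", how="left", validate="many_to_one")
    log.info("metric rows: %d (outlier fraction %.3f)", len(records), records["outlier_any"].mean())
    return records


@_stage("fit")
def _fit(cfg: PipelineConfig, records: pd.DataFrame) -> tuple[ClusteredQuadraticLogit, dict]:
    model = ClusteredQuadraticLogit()
    model.fit(records)
    out: dict = {"summary": {}}
    for metric in model.quadratic_terms:
        x = records[metric].to_numpy(dtype=float)
        grid = np.linspace(x.min(), x.max(), cfg.curve_points)
        out["summary"][metric] = model.predicted_curve(metric, grid)
    log.info("fit %d obs, converged=%s", model.nobs_, model.converged_)
    return model, out


@_stage("shap")
def _shap(
    cfg: PipelineConfig, events: pd.DataFrame, meta: pd.DataFrame
) -> tuple[EventShapModel, pd.DataFrame]:
    X = build_event_features(events, gap_minutes=cfg.gap_minutes)
    y = meta.set_index("encounter_id").loc[X.index, "initiated"].to_numpy()
    model = EventShapModel(n_repeats=cfg.n_repeats, random_state=cfg.seed)
    model.fit(X, y)
    summary = model.shap_summary()
    log.info("SHAP over %d features, AUROC CI (%.3f, %.3f)", X.shape[1], *model.auroc_ci_)
    return model, summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write the report bundle under ``cfg.out_dir``.

    Outputs: ``metrics.csv``, ``fit.json``, ``curve_<metric>.csv``,
    ``shap_summary.csv`` and ``summary.json``. Returns the summary dict.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        paths = _simulate(cfg)
        cfg.event_log_path = paths["events"]
        cfg.encounter_table_path = paths["encounters"]
    if cfg.event_log_path is None or cfg.encounter_table_path is None:
        raise StageError("ingest", "no input paths and simulate disabled")

    events, meta = _ingest(cfg)
    records = _metrics(cfg, events, meta)
    records[METRICS_CSV_COLUMNS].to_csv(out_dir / "metrics.csv", index=False)

    assoc = outlier_outcome_association(records["outlier_any"], records["initiated"])

    model, curves = _fit(cfg, records)
    fit_report = {
        "coefficients": model.summary_frame().round(10).to_dict(orient="index"),
        "n_obs": model.nobs_,
        "pseudo_r2": round(model.pseudo_r2_, 10),
        "adj_pseudo_r2": round(model.adj_pseudo_r2_, 10),
        "rmse": round(model.rmse_, 10),
        "converged": model.converged_,
        "wald_quadratic": model.wald_quadratic(),
    }
    (out_dir / "fit.json").write_text(
        json.dumps(fit_report, indent=2, sort_keys=True, default=_json_default)
    )

    vertex_table = {}
    ame_table = {}
    for metric, curve in curves["summary"].items():
        curve.curve.to_csv(out_dir / f"curve_{metric}.csv", index=False)
        vertex_table[metric] = {"vertex": curve.vertex, "shape": curve.shape,
                                "peak_x": curve.peak_x, "peak_p": curve.peak_p}
        ame_table[metric] = {"below_vertex": curve.ame_below, "above_vertex": curve.ame_above,
                             "all": model.average_marginal_effect(metric, "all")}

    shap_model, shap_table = _shap(cfg, events, meta)
    shap_table.to_csv(out_dir / "shap_summary.csv", index=True, index_label="feature")

    summary = {
        "version": __version__,
        "n_encounters": int(meta.shape[0]),
        "n_metric_rows": int(records.shape[0]),
        "outlier_association": {k: v for k, v in assoc.items() if k != "table"},
        "vertices": vertex_table,
        "ame": ame_table,
        "fit": {k: fit_report[k] for k in ("n_obs", "pseudo_r2", "adj_pseudo_r2", "rmse", "converged")},
        "auroc_ci95": shap_model.auroc_ci_,
        "auroc_median": float(np.median(shap_model.auroc_distribution_)),
        "metric_category_contributions": aggregate_by_metric(shap_table)[
            "relative_contribution"
        ].to_dict(),
        "top10_shap": shap_table.head(10).reset_index().to_dict(orient="records"),
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
    )
    return summary
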