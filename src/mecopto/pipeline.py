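"""Day-level orchestration: score, classify, measure, report.

``run_day`` takes a validated day record (baseline / stimulation /
baseline), runs the full analysis chain -- tuning scores with shuffle
cutoffs, functional cell-type labels, interneuron gating, PSTH-based
excitation/inhibition classification against population nulls,
transient-window metrics for the labeled cells, and the theta-speed
regressions -- and writes CSV/JSON reports plus a run manifest.  The
whole chain is deterministic under the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import celltyping, lfp_analysis, optoresponse, window_metrics
from .session_io import DayRecord

logger = logging.getLogger("mecopto")

__all__ = ["RunConfig", "run_day", "summarize"]


@dataclass
class RunConfig:
    n_shuffles: int = 1000
    percentile: float = 95.0
    scores: tuple[str, ...] = ("grid", "hd", "speed", "theta")
    recovery_fraction: float = 0.5
    n_iter: int = 50
    seed: int = 0
    bin_size_cm: float = 3.0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fmt_df(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(9)


def run_day(day: DayRecord, config: RunConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Run the full analysis for one day; return the report dict.

    When ``outdir`` is given, writes scores.csv, responses.csv,
    windowed_metrics.csv, lfp_regression.json and run_manifest.json.
    """
    config = config or RunConfig()
    report: dict = {"cells": {}, "lfp": {}}

    ct_config = celltyping.CellTypeConfig(
        n_shuffles=config.n_shuffles,
        percentile=config.percentile,
        scores=config.scores,
    )
    logger.info("classifying %d cells", len(day.cell_ids))
    labels = celltyping.classify_cell_types(day, ct_config, seed=config.seed)
    profiles = celltyping.interneuron_profiles(day.sessions)

    stim_session = day.stimulation
    stim = stim_session.stim
    psths = {
        u.cell_id: optoresponse.build_psth(u.times, stim, stim_session.duration)
        for u in stim_session.units
    }
    usable = [p for p in psths.values() if p.mean_pre > 0]
    exc_thr = optoresponse.population_null(usable, "excitation") if usable else np.nan
    inh_thr = optoresponse.population_null(usable, "inhibition") if usable else np.nan
    report["thresholds"] = {"excitation": exc_thr, "inhibition": inh_thr}

    speed_series = None
    rows, resp_rows, metric_rows = [], [], []
    for label in labels:
        cid = label.cell_id
        psth = psths[cid]
        try:
            resp = optoresponse.classify_response(psth, exc_thr, inh_thr)
        except ValueError:
            resp = None
        inh_win = (
            optoresponse.inhibition_window(psth, config.recovery_fraction)
            if resp is not None and resp.inhibited
            else None
        )
        cell_report = {
            "labels": sorted(label.labels),
            "interneuron_class": celltyping.classify_interneuron(profiles[cid]),
            "burst_index": profiles[cid].burst_index,
            "response": None if resp is None else resp.category,
        }
        for name in config.scores:
            for s_idx in range(3):
                rows.append(
                    {
                        "cell_id": cid,
                        "score": name,
                        "session": s_idx,
                        "value": label.session_scores[name][s_idx],
                        "cutoff": label.session_cutoffs[name][s_idx],
                    }
                )
        if resp is not None:
            resp_rows.append(
                {
                    "cell_id": cid,
                    "category": resp.category,
                    "exc_latency_ms": resp.exc_latency_ms,
                    "jitter_ms": resp.jitter_ms,
                    "inh_latency_ms": resp.inh_latency_ms,
                    "inh_window_start_ms": np.nan if inh_win is None else inh_win.t_start_ms,
                    "inh_window_end_ms": np.nan if inh_win is None else inh_win.t_end_ms,
                }
            )

        # transient-window metrics for the functional classes
        spikes = stim_session.unit(cid).times
        traj = stim_session.trajectory
        seed_cell = (config.seed * 1000003 + celltyping.zlib.crc32(cid.encode())) % (2**31)
        if "speed" in label.labels and inh_win is not None:
            if speed_series is None:
                from .tuning import kalman_speed

                speed_series = kalman_speed(traj)
            try:
                m = window_metrics.windowed_speed_score(
                    spikes, stim, traj, speed_series, inh_win,
                    n_iter=config.n_iter, seed=seed_cell,
                )
                metric_rows.append({"cell_id": cid, **_metric_row(m)})
            except ValueError as e:
                logger.info("speed metric skipped for %s: %s", cid, e)
        if "narrow_hd" in label.labels or "broad_hd" in label.labels:
            mode = "fixed" if "narrow_hd" in label.labels else "inhibition"
            if mode == "fixed" or inh_win is not None:
                try:
                    m = window_metrics.windowed_hd_score(
                        spikes, stim, traj, mode=mode, inh=inh_win,
                        n_iter=config.n_iter, seed=seed_cell,
                    )
                    metric_rows.append({"cell_id": cid, **_metric_row(m)})
                except ValueError as e:
                    logger.info("hd metric skipped for %s: %s", cid, e)
        report["cells"][cid] = cell_report

    # LFP theta-speed regression: baseline1 vs stimulation
    lfp_report = {}
    for name, sess in (("baseline1", day.baseline1), ("stimulation", day.stimulation)):
        if not sess.lfp:
            continue
        ch = lfp_analysis.select_theta_channel(sess.lfp)
        sig = next(s for s in sess.lfp if s.channel_id == ch)
        series = lfp_analysis.theta_series(sig, sess.trajectory)
        try:
            lfp_report[name] = {
                "channel": ch,
                **lfp_analysis.theta_speed_regression(series, sess.trajectory),
            }
        except ValueError as e:
            logger.info("lfp regression skipped for %s: %s", name, e)
    report["lfp"] = lfp_report

    scores_df = _fmt_df(pd.DataFrame(rows))
    resp_df = _fmt_df(pd.DataFrame(resp_rows))
    metrics_df = _fmt_df(pd.DataFrame(metric_rows))
    report["tables"] = {
        "scores": scores_df,
        "responses": resp_df,
        "windowed_metrics": metrics_df,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scores_df.to_csv(outdir / "scores.csv", index=False)
        resp_df.to_csv(outdir / "responses.csv", index=False)
        metrics_df.to_csv(outdir / "windowed_metrics.csv", index=False)
        with open(outdir / "lfp_regression.json", "w") as fh:
            json.dump(lfp_report, fh, indent=1, sort_keys=True)
        manifest = {
            "config": asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_cells": len(day.cell_ids),
            "thresholds": {
                "excitation": None if not np.isfinite(exc_thr) else exc_thr,
                "inhibition": None if not np.isfinite(inh_thr) else inh_thr,
            },
            "cells": report["cells"],
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return report


def _metric_row(m: window_metrics.WindowedMetric) -> dict:
    return {
        "metric": m.metric,
        "value_test": m.value_test,
        "value_control": m.value_control,
        "n_spikes_test": m.n_spikes_test,
        "n_iter": m.n_iter,
    }


def summarize(report: dict) -> dict:
    """Summary tables: cells per functional type x response category and
    mean +- sem of each windowed metric."""
    cells = report.get("cells", {})
    if not cells:
        logger.warning("empty report; nothing to summarize")
        return {"counts": pd.DataFrame(), "metrics": pd.DataFrame(), "n_cells": 0}
    rows = []
    for cid, c in cells.items():
        labels = c["labels"] or ["unclassified"]
        for lab in labels:
            rows.append({"cell_id": cid, "type": lab, "response": c["response"]})
    counts = (
        pd.DataFrame(rows)
        .groupby(["type", "response"], dropna=False)
        .agg(n=("cell_id", "nunique"))
        .reset_index()
    )
    mdf = report.get("tables", {}).get("windowed_metrics", pd.DataFrame())
    if len(mdf):
        metrics = (
            mdf.groupby("metric")
            .agg(
                mean_test=("value_test", "mean"),
                sem_test=("value_test", "sem"),
                mean_control=("value_control", "mean"),
                sem_control=("value_control", "sem"),
                n=("cell_id", "nunique"),
            )
            .reset_index()
        )
    else:
        metrics = pd.DataFrame()
    return {"counts": counts, "metrics": metrics, "n_cells": len(cells)}
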