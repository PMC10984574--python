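"""Cohort-level orchestration: scoring, connectivity, graphs, statistics.

These functions tie the per-subject operations into the reproducible
pipeline the command-line interface exposes: simulate -> score behaviour
-> band coherence -> thresholded graphs and small-world coefficients ->
mixed-design ANOVAs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import connectivity as cnx
from . import graphs as grf
from .behavior import StimulusStream
from .io import PipelineConfig
from .stats import mixed_anova

logger = logging.getLogger(__name__)

__all__ = [
    "stream_from_records",
    "score_behavior_table",
    "resting_graph_metrics",
    "task_graph_metrics",
    "behavior_anovas",
    "resting_anovas",
    "task_anovas",
]


def stream_from_records(records: pd.DataFrame) -> StimulusStream:
    """Rebuild a stimulus stream from logged trials (pattern inferred)."""
    trials = records[
        ["block", "position_in_block", "direction", "trial_class"]
    ].reset_index(drop=True)
    pat = records.loc[records["trial_class"] == "pattern", "direction"].to_numpy()[:4]
    return StimulusStream(trials=trials, pattern=tuple(int(x) for x in pat))


def score_behavior_table(
    behavior: pd.DataFrame,
    unit_size_blocks: int = 5,
    baseline_threshold_pct: float = 70.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject learning scores in long format plus a subject summary.

    Subjects failing the baseline-accuracy gate (< threshold) are dropped
    from the score table and flagged in the summary. Returns
    ``(scores, summary)`` where ``scores`` has one row per subject x unit
    x probability (random trials only) with mean accuracy and median RT.
    """
    score_rows, summary_rows = [], []
    for sid, records in behavior.groupby("subject", sort=False):
        stream = stream_from_records(records)
        labels = bhv.categorize_triplets(stream)
        kept = bhv.apply_exclusions(records.reset_index(drop=True), labels)
        keep_subject = bhv.baseline_accuracy_gate(
            records, threshold_pct=baseline_threshold_pct
        )
        scores = bhv.compute_learning_scores(kept, unit_size_blocks=unit_size_blocks)
        meta = records.iloc[0]
        summary_rows.append(
            {
                "subject": sid,
                "group": meta["group"],
                "medicated": int(meta.get("medicated", 0)),
                "baseline_accuracy_pct": scores.baseline_accuracy,
                "included": bool(keep_subject),
                "overall_acc_learning_pp": scores.overall_acc_learning,
                "overall_rt_learning_ms": scores.overall_rt_learning,
            }
        )
        if not keep_subject:
            logger.warning("subject %s excluded by baseline-accuracy gate", sid)
            continue
        unit = scores.unit_scores
        rnd = unit[unit["trial_type"].isin(["random_high", "random_low"])].copy()
        rnd["probability"] = rnd["trial_type"].map(
            {"random_high": "high", "random_low": "low"}
        )
        rnd.insert(0, "subject", sid)
        rnd.insert(1, "group", meta["group"])
        rnd.insert(2, "medicated", int(meta.get("medicated", 0)))
        score_rows.append(rnd.drop(columns=["trial_type"]))
    scores_long = pd.concat(score_rows, ignore_index=True)
    return scores_long, pd.DataFrame(summary_rows)


def _metrics_row(coh_list, config: PipelineConfig, cache) -> dict:
    gm = grf.subject_condition_metrics(
        coh_list,
        percentile=config.percentile,
        reps=config.null_reps,
        percentile_mode=config.percentile_mode,
        averaging_mode=config.averaging_mode,
        null_cache=cache,
    )
    return {
        "mean_degree_2k": gm.mean_degree_2k,
        "L_real": gm.L_real,
        "C_real": gm.C_real,
        "L_rand": gm.L_rand,
        "C_latt": gm.C_latt,
        "omega": gm.omega,
        "n_segments": gm.n_segments,
    }


def resting_graph_metrics(
    recordings: dict,
    subjects: pd.DataFrame,
    config: PipelineConfig,
    bands=None,
) -> pd.DataFrame:
    """Small-world metrics per subject, resting condition and band."""
    bands = list(bands if bands is not None else config.bands)
    cache = grf._NullCache(reps=config.null_reps, seed=config.seed)
    meta = subjects.set_index("subject")
    rows = []
    for sid, conds in recordings.items():
        for cond in ("rest_pre", "rest_post"):
            if cond not in conds:
                continue
            epochs = cnx.segment_resting(conds[cond])
            for band in bands:
                coh = cnx.band_coherence_per_segment(
                    epochs, band, n_tapers=config.n_tapers, nw=config.nw
                )
                rows.append(
                    {
                        "subject": sid,
                        "group": meta.loc[sid, "group"],
                        "condition": cond,
                        "band": band.name,
                        **_metrics_row(coh, config, cache),
                    }
                )
    return pd.DataFrame(rows)


def task_graph_metrics(
    recordings: dict,
    behavior: pd.DataFrame,
    subjects: pd.DataFrame,
    config: PipelineConfig,
    bands=None,
) -> pd.DataFrame:
    """Small-world metrics per subject, task condition (probability x
    half) and band; subjects with an empty condition bin are dropped."""
    bands = list(bands if bands is not None else config.bands)
    cache = grf._NullCache(reps=config.null_reps, seed=config.seed)
    meta = subjects.set_index("subject")
    rows = []
    for sid, conds in recordings.items():
        if "task" not in conds:
            continue
        records = behavior[behavior["subject"] == sid].reset_index(drop=True)
        labels = bhv.categorize_triplets(stream_from_records(records))
        epoch_bins = cnx.segment_task(
            conds["task"], records, labels,
            half_size_blocks=config.eeg_block_half_size,
        )
        if len(epoch_bins) < 4:
            logger.warning("subject %s dropped: empty task-condition bin", sid)
            continue
        for key, epochs in epoch_bins.items():
            prob, half = key.split("_")
            for band in bands:
                coh = cnx.band_coherence_per_segment(
                    epochs, band, n_tapers=config.n_tapers, nw=config.nw
                )
                rows.append(
                    {
                        "subject": sid,
                        "group": meta.loc[sid, "group"],
                        "probability": prob,
                        "half": half,
                        "band": band.name,
                        **_metrics_row(coh, config, cache),
                    }
                )
    return pd.DataFrame(rows)


def behavior_anovas(scores_long: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group x Probability x Unit mixed ANOVAs on accuracy and median RT."""
    return {
        "accuracy": mixed_anova(
            scores_long, dv="mean_acc_pct", between="group",
            within=["probability", "unit"], subject="subject",
        ),
        "rt": mixed_anova(
            scores_long.dropna(subset=["median_rt_ms"]), dv="median_rt_ms",
            between="group", within=["probability", "unit"], subject="subject",
        ),
    }


def resting_anovas(metrics: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group x Time (pre vs post rest) ANOVAs per band and metric."""
    out = {}
    if metrics.empty:
        logger.warning("no resting graph metrics")
        return out
    for band, sub in metrics.groupby("band"):
        for dv in ("omega", "L_real", "C_real"):
            out[f"{band}_{dv}"] = mixed_anova(
                sub, dv=dv, between="group", within=["condition"],
                subject="subject",
            )
    return out


def task_anovas(metrics: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group x Probability x Block-half ANOVAs per band and metric."""
    out = {}
    if metrics.empty:
        logger.warning("no task graph metrics (all subjects dropped?)")
        return out
    for band, sub in metrics.groupby("band"):
        for dv in ("omega", "L_real", "C_real"):
            out[f"{band}_{dv}"] = mixed_anova(
                sub, dv=dv, between="group", within=["probability", "half"],
                subject="subject",
            )
    return out
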