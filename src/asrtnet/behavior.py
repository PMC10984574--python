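"""Trial categorization and statistical-learning scores for the ASRT task.

In the alternating serial reaction time (ASRT) task, pattern and random
trials alternate (1-r-2-r-3-r-4-r). Every trial from the third position of
a block onward terminates a triplet of consecutive trials; a triplet is
*high-probability* when its final direction is the pattern successor of its
first direction, and *low-probability* otherwise. Statistical learning is
the accuracy (or reaction-time) advantage on high-probability random trials
over low-probability random trials, computed per five-block unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusStream",
    "LearningScores",
    "categorize_triplets",
    "apply_exclusions",
    "compute_learning_scores",
    "baseline_accuracy_gate",
]

DIRECTIONS = (1, 2, 3, 4)
TRIAL_TYPES = ("pattern_high", "random_high", "random_low")


@dataclass
class StimulusStream:
    """Ordered trial records plus the 4-element alternating pattern.

    ``trials`` columns: ``block`` (1-based), ``position_in_block``
    (1-based), ``direction`` (1-4) and ``trial_class`` ("pattern" or
    "random").
    """

    trials: pd.DataFrame
    pattern: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if sorted(self.pattern) != [1, 2, 3, 4]:
            raise ValueError(
                f"pattern must be a permutation of (1, 2, 3, 4), got {self.pattern}"
            )
        if not np.isin(self.trials["direction"].to_numpy(), DIRECTIONS).all():
            raise ValueError("directions must be in {1, 2, 3, 4}")

    def __len__(self) -> int:
        return len(self.trials)


def pattern_successor(pattern: tuple[int, ...]) -> dict[int, int]:
    """Map each direction to its cyclic successor in the pattern sequence."""
    return {pattern[i]: pattern[(i + 1) % 4] for i in range(4)}


def categorize_triplets(stream: StimulusStream) -> pd.DataFrame:
    """Label each trial as the terminal element of its triplet.

    The moving window runs within each block. A trial *t* (third position
    of a block onward) terminates the triplet ``(d[t-2], d[t-1], d[t])``
    and is high-probability iff ``d[t]`` equals the pattern successor of
    ``d[t-2]``. Trials that cannot terminate a triplet carry ``None``
    probability. Performance is operationalized on terminal trials only;
    each trial's earlier roles (interim and predictor element of the two
    following triplets) follow from the window and are not stored.

    Returns a frame aligned to ``stream.trials`` with columns
    ``probability`` ("high"/"low"/None), ``structure`` (the trial class)
    and ``is_trill_or_repetition`` (terminal direction equals the first
    triplet direction, covering both trills a-b-a and repetitions a-a-a).
    """
    trials = stream.trials
    d = trials["direction"].to_numpy()
    block = trials["block"].to_numpy()
    succ = pattern_successor(stream.pattern)
    succ_arr = np.zeros(5, dtype=int)
    for a, b in succ.items():
        succ_arr[a] = b

    n = len(d)
    prob = np.full(n, None, dtype=object)
    trill = np.zeros(n, dtype=bool)
    if n >= 3:
        idx = np.arange(2, n)
        same_block = (block[idx] == block[idx - 2])
        first = d[idx - 2]
        term = d[idx]
        high = succ_arr[first] == term
        prob_vals = np.where(high, "high", "low")
        prob[idx[same_block]] = prob_vals[same_block]
        trill[idx[same_block]] = (first == term)[same_block]
    return pd.DataFrame(
        {
            "probability": prob,
            "structure": trials["trial_class"].to_numpy(),
            "is_trill_or_repetition": trill,
        },
        index=trials.index,
    )


def apply_exclusions(
    records: pd.DataFrame,
    labels: pd.DataFrame,
    first_trials_excluded: int = 7,
    return_annotated: bool = False,
):
    """Apply the trial exclusions and annotate each trial with its reason.

    Removed from all analyses, in priority order per trial: the first seven
    trials of each block (five practice trials plus the first two triplet
    elements), trials terminating a trill or repetition (first and last
    triplet directions equal), and trials without a response. Accuracy uses
    the remaining responded trials; reaction times are additionally
    restricted to correct responses downstream.

    Returns the merged frame of kept trials with ``probability`` and
    ``structure`` columns; with ``return_annotated=True`` also returns the
    full annotated frame (excluded trials carry their ``excluded_reason``).
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must be aligned")
    counts = records.groupby("block").size()
    if (counts < first_trials_excluded + 1).any():
        raise ValueError(
            f"each block needs more than {first_trials_excluded} trials"
        )
    merged = pd.concat([records.reset_index(drop=True), labels.reset_index(drop=True)], axis=1)
    reason = np.full(len(merged), "none", dtype=object)
    first7 = merged["position_in_block"].to_numpy() <= first_trials_excluded
    trill = merged["is_trill_or_repetition"].to_numpy()
    noresp = ~merged["responded"].to_numpy().astype(bool) if "responded" in merged else np.zeros(len(merged), bool)
    reason[noresp] = "no_response"
    reason[trill] = "trill"
    reason[first7] = "first_seven"
    merged["excluded_reason"] = reason
    kept = merged[reason == "none"].copy()
    if return_annotated:
        return kept, merged
    return kept


@dataclass
class LearningScores:
    """Per-unit trial-type summaries and the derived learning contrasts.

    ``unit_scores`` is long-format with columns ``unit``, ``trial_type``
    (pattern_high / random_high / random_low), ``mean_acc_pct`` and
    ``median_rt_ms``. Learning contrasts use random trials only:
    ``acc_learning[u] = acc(random_high) - acc(random_low)`` in percentage
    points and ``rt_learning[u] = rt(random_low) - rt(random_high)`` in ms.
    """

    unit_scores: pd.DataFrame
    acc_learning: pd.Series
    rt_learning: pd.Series
    overall_acc_learning: float
    overall_rt_learning: float
    baseline_accuracy: float
    undefined_units: list[int] = field(default_factory=list)


def compute_learning_scores(
    filtered: pd.DataFrame, unit_size_blocks: int = 5
) -> LearningScores:
    """Statistical-learning scores per five-block unit and overall.

    Expects the output of :func:`apply_exclusions` (responded trials with
    ``correct``, ``rt_ms``, ``probability`` and ``structure`` columns).
    Mean accuracy (percent, over responded trials) and median RT (ms, over
    correct trials) are computed per unit and trial type; the overall
    learning score is the unweighted mean of the unit-level contrasts.
    """
    n_blocks = int(filtered["block"].max())
    if n_blocks % unit_size_blocks != 0:
        raise ValueError(
            f"n_blocks={n_blocks} not divisible by unit_size_blocks={unit_size_blocks}"
        )
    n_units = n_blocks // unit_size_blocks
    unit = (filtered["block"].to_numpy() - 1) // unit_size_blocks
    prob = filtered["probability"].to_numpy()
    struct = filtered["structure"].to_numpy()
    correct = filtered["correct"].to_numpy(dtype=float)
    rt_ms = filtered["rt_ms"].to_numpy(dtype=float)
    # cell index: unit x trial type (pattern_high, random_high, random_low)
    tcode = np.where(struct == "pattern", 0, np.where(prob == "high", 1, 2))
    cell = unit * 3 + tcode
    n_cells = n_units * 3
    counts = np.bincount(cell, minlength=n_cells).astype(float)
    hits = np.bincount(cell, weights=correct, minlength=n_cells)
    with np.errstate(invalid="ignore"):
        acc_grid = np.where(counts > 0, 100.0 * hits / counts, np.nan).reshape(
            n_units, 3
        )
    rt_grid = np.full((n_units, 3), np.nan)
    is_corr = correct > 0
    for c in range(n_cells):
        vals = rt_ms[is_corr & (cell == c)]
        if vals.size:
            rt_grid[c // 3, c % 3] = np.median(vals)

    unit_index = np.repeat(np.arange(1, n_units + 1), 3)
    unit_scores = pd.DataFrame(
        {
            "unit": unit_index,
            "trial_type": list(TRIAL_TYPES) * n_units,
            "mean_acc_pct": acc_grid.ravel(),
            "median_rt_ms": rt_grid.ravel(),
        }
    )
    units = pd.RangeIndex(1, n_units + 1, name="unit")
    acc_learning = pd.Series(acc_grid[:, 1] - acc_grid[:, 2], index=units)
    rt_learning = pd.Series(rt_grid[:, 2] - rt_grid[:, 1], index=units)
    undefined = sorted(acc_learning.index[acc_learning.isna()])
    if undefined:
        logger.warning("learning score undefined for units %s", undefined)
    return LearningScores(
        unit_scores=unit_scores,
        acc_learning=acc_learning,
        rt_learning=rt_learning,
        overall_acc_learning=float(acc_learning.mean()),
        overall_rt_learning=float(rt_learning.mean()),
        baseline_accuracy=float(correct.mean() * 100.0),
        undefined_units=undefined,
    )


def baseline_accuracy_gate(
    records: pd.DataFrame, threshold_pct: float = 70.0
) -> bool:
    """True if the subject is kept (baseline accuracy >= threshold).

    Baseline accuracy is the percent-correct over responded trials
    irrespective of trial type; a strictly lower value excludes the
    subject (low task engagement). A subject with no responded trials is
    excluded with a warning.
    """
    if records.empty:
        raise ValueError("records must be nonempty")
    responded = records[records["responded"].astype(bool)]
    if responded.empty:
        logger.warning("no responded trials: subject excluded")
        return False
    return float(responded["correct"].mean() * 100.0) >= threshold_pct
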