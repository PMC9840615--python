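"""Preprocessing of trial-level comparison behavior.

Trials are first screened at the participant level: a participant whose mean
reaction time falls more than three standard deviations from the mean (of
participant mean RTs within the dataset) is excluded outright.  The surviving
trials are then aggregated per stimulus into the two behavioral outcomes the
validation stage regresses on: the mean error rate and the mean reaction
time of correct trials only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["exclude_outliers", "aggregate", "BEHAVIOR_COLUMNS"]

BEHAVIOR_COLUMNS = ["STIMID", "mean_err", "mean_rt_correct",
                    "n_participants", "n_correct_trials"]


def exclude_outliers(trials: pd.DataFrame, n_sd: float = 3.0,
                     correct_only: bool = True, level: str = "participant"
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop participants with mean RT outside mean ± n_sd·SD (single pass).

    level="participant" (default): the mean and SD are taken over the
    distribution of participant mean RTs.  level="trial": over the pooled
    trial RT distribution, participants judged by their mean RT against it.
    correct_only restricts the RT means to correct trials, matching the RT
    outcome definition.

    Returns (kept trials, exclusion log with USERID/mean_rt/bounds).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if level not in ("participant", "trial"):
        raise ValueError("level must be 'participant' or 'trial'")
    rt_source = trials[trials["ERR"] == 0] if correct_only else trials
    user_means = rt_source.groupby("USERID")["RT"].mean()
    # participants with no usable trials keep their all-trials mean
    missing = np.setdiff1d(trials["USERID"].unique(), user_means.index)
    if len(missing):
        user_means = pd.concat(
            [user_means, trials[trials["USERID"].isin(missing)]
             .groupby("USERID")["RT"].mean()]).sort_index()
    if len(user_means) < 3:
        warnings.warn("fewer than 3 participants: skipping outlier exclusion",
                      RuntimeWarning, stacklevel=2)
        log = pd.DataFrame(columns=["USERID", "mean_rt", "lo", "hi"])
        return trials.copy(), log
    ref = user_means if level == "participant" else rt_source["RT"]
    m, sd = float(ref.mean()), float(ref.std(ddof=1))
    lo, hi = m - n_sd * sd, m + n_sd * sd
    out = user_means[(user_means < lo) | (user_means > hi)]
    log = pd.DataFrame({"USERID": out.index, "mean_rt": out.to_numpy(),
                        "lo": lo, "hi": hi}).reset_index(drop=True)
    kept = trials[~trials["USERID"].isin(out.index)].copy()
    return kept, log


def aggregate(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus mean error rate and mean correct-trial RT.

    Stimuli with zero correct trials keep their row with mean_rt_correct
    missing.  The input is assumed already outlier-filtered.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    g = trials.groupby("STIMID", sort=True)
    err = g["ERR"].mean()
    n_participants = g["USERID"].nunique()
    correct = trials[trials["ERR"] == 0]
    rt = correct.groupby("STIMID")["RT"].mean()
    n_correct = correct.groupby("STIMID").size()
    out = pd.DataFrame({
        "STIMID": err.index,
        "mean_err": err.to_numpy(),
        "mean_rt_correct": rt.reindex(err.index).to_numpy(),
        "n_participants": n_participants.to_numpy(),
        "n_correct_trials": n_correct.reindex(err.index, fill_value=0)
                                     .to_numpy(),
    }).reset_index(drop=True)
    return out[BEHAVIOR_COLUMNS]
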