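"""Trial-level scoring of the Stroop and go/no-go tasks.

Per subject, occasion and block the four scores are:

* ``stroop_er``      — error rate in incongruent trials,
* ``stroop_rtdiff``  — mean correct incongruent RT minus mean correct
  congruent RT (ms),
* ``gng_er``         — commission rate in no-go trials,
* ``gng_rt``         — mean correct go RT (ms),

under three validity restrictions: trials with RT < 150 ms are invalid, RT
aggregates use correct responses only, and a block-task score requires at
least 10 valid trials in each of its conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["filter_trials", "score_blocks", "score_with_subset"]

MIN_RT_MS = 150.0
MIN_TRIALS = 10

_TASK_CONDITIONS = {"stroop": {"congruent", "incongruent"},
                    "gng": {"go", "nogo"}}
_KEY = ["subject_id", "occasion_index", "block"]


def filter_trials(trials: pd.DataFrame, *, min_rt_ms: float = MIN_RT_MS,
                  practice_col: str = "practice") -> pd.DataFrame:
    """Flag per-trial validity and drop practice trials.

    A trial is invalid when a response was registered with RT below
    ``min_rt_ms`` (strict less-than).  Trials with no registered response
    (missing RT, e.g. a correctly withheld no-go response) stay valid for
    error-rate purposes.
    """
    bad_task = set(trials["task"].unique()) - set(_TASK_CONDITIONS)
    if bad_task:
        raise ValueError(f"unknown task values: {sorted(bad_task)}")
    for task, allowed in _TASK_CONDITIONS.items():
        seen = set(trials.loc[trials["task"] == task, "condition"].unique())
        if seen - allowed:
            raise ValueError(
                f"unknown conditions for task {task!r}: {sorted(seen - allowed)}")
    out = trials.copy()
    if practice_col in out.columns:
        out = out[out[practice_col] != 1].drop(columns=[practice_col])
    rt = out["rt_ms"]
    out["valid"] = (~(rt < min_rt_ms) | rt.isna()).astype(int)
    return out


def score_blocks(trials: pd.DataFrame, *, min_trials: int = MIN_TRIALS,
                 min_rt_ms: float = MIN_RT_MS,
                 stroop_nonresponse_error: bool = True,
                 prefiltered: bool = False) -> pd.DataFrame:
    """Aggregate filtered trials into per-block task scores.

    Insufficient valid trials in a condition yields an invalid flag with a
    missing score, never an error.  ``stroop_nonresponse_error`` controls
    whether incongruent Stroop trials without a registered response count
    as errors (default) or as missing.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    t = trials if prefiltered and "valid" in trials.columns else \
        filter_trials(trials, min_rt_ms=min_rt_ms)
    v = t[t["valid"] == 1].copy()
    if len(v) == 0:
        raise ValueError("no valid trials to score")
    responded = v["rt_ms"].notna()
    wrong = v["correct"] == 0
    # error numerator / denominator per condition convention
    if stroop_nonresponse_error:
        err = (wrong | ~responded).astype(float)
        den = np.ones(len(v))
    else:
        err = (wrong & responded).astype(float)
        den = responded.astype(float).to_numpy()
    nogo = (v["condition"] == "nogo").to_numpy()
    err = np.where(nogo, wrong.astype(float), err)   # commission rate
    den = np.where(nogo, 1.0, den)
    go = (v["condition"] == "go").to_numpy()
    err = np.where(go, np.nan, err)  # go omissions are not part of gng_er
    den = np.where(go, np.nan, den)
    v["_err"] = err
    v["_den"] = den
    v["_rt_c"] = np.where((v["correct"] == 1) & responded, v["rt_ms"], np.nan)

    agg = (v.groupby(_KEY + ["condition"], sort=True, observed=True)
            .agg(n=("valid", "size"), err=("_err", "sum"),
                 den=("_den", "sum"), rt_mean=("_rt_c", "mean"))
            .unstack("condition"))

    def col(stat, cond, fill=np.nan):
        if (stat, cond) in agg.columns:
            return agg[(stat, cond)]
        return pd.Series(fill, index=agg.index)

    out = pd.DataFrame(index=agg.index)
    n_inc = col("n", "incongruent", 0).fillna(0).astype(int)
    n_con = col("n", "congruent", 0).fillna(0).astype(int)
    n_nogo = col("n", "nogo", 0).fillna(0).astype(int)
    n_go = col("n", "go", 0).fillna(0).astype(int)
    has_stroop = (n_inc + n_con) > 0
    has_gng = (n_nogo + n_go) > 0
    valid_stroop = (n_inc >= min_trials) & (n_con >= min_trials) & has_stroop
    valid_gng = (n_nogo >= min_trials) & (n_go >= min_trials) & has_gng

    with np.errstate(invalid="ignore", divide="ignore"):
        stroop_er = col("err", "incongruent") / col("den", "incongruent")
        gng_er = col("err", "nogo") / col("den", "nogo")
    stroop_rtdiff = col("rt_mean", "incongruent") - col("rt_mean", "congruent")
    gng_rt = col("rt_mean", "go")

    out["stroop_er"] = stroop_er.where(valid_stroop)
    out["stroop_rtdiff"] = stroop_rtdiff.where(valid_stroop)
    out["gng_er"] = gng_er.where(valid_gng)
    out["gng_rt"] = gng_rt.where(valid_gng)
    out["valid_stroop"] = valid_stroop.astype(int)
    out["valid_gng"] = valid_gng.astype(int)
    out["n_valid_incongruent"] = n_inc
    out["n_valid_congruent"] = n_con
    out["n_valid_nogo"] = n_nogo
    out["n_valid_go"] = n_go
    out = out.reset_index()
    for extra in ("day", "beep"):
        if extra in t.columns:
            first = t.groupby(_KEY, sort=True)[extra].first()
            out[extra] = first.reindex(
                pd.MultiIndex.from_frame(out[_KEY])).to_numpy()
    front = [c for c in ("subject_id", "occasion_index", "day", "beep",
                         "block") if c in out.columns]
    return out[front + [c for c in out.columns if c not in front]]


def score_with_subset(trials: pd.DataFrame, n_per_condition: int, *,
                      min_rt_ms: float = MIN_RT_MS,
                      stroop_nonresponse_error: bool = True) -> pd.DataFrame:
    """Score blocks from the first ``n_per_condition`` trials per condition.

    Trials are taken in presentation order (``trial_index``) within each
    block and condition, mirroring test-length curves that consider
    increasing numbers of trials; no minimum-trial rule applies to the
    subset scores.
    """
    if n_per_condition <= 0:
        raise ValueError(f"n_per_condition must be > 0, got {n_per_condition}")
    t = filter_trials(trials, min_rt_ms=min_rt_ms)
    t = t.sort_values(_KEY + ["task", "trial_index"], kind="stable")
    head = (t.groupby(_KEY + ["task", "condition"], sort=False)
             .head(n_per_condition))
    return score_blocks(head, min_trials=0, min_rt_ms=min_rt_ms,
                        stroop_nonresponse_error=stroop_nonresponse_error,
                        prefiltered=True)
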