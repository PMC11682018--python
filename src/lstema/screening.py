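"""Careless-responding screening for EMA prompts.

Four rules, applied in order, with cut-offs frozen once per dataset:

1. prompts whose mean questionnaire item completion time is < 1 second are
   removed entirely;
2. Stroop blocks whose longstring (longest run of identical consecutive
   responses) exceeds the sample mean + 3 SD remove that prompt's Stroop
   scores;
3. occasions whose task error rate exceeds the sample mean + 3 SD (per
   task) drop that task's scores for the occasion;
4. subjects with fewer than 5 complete assessments are flagged for
   exclusion from model fitting.

Means and SDs for rules 2-3 are pooled over the whole dataset after rule 1,
and are recorded in the report so every removal can be reconstructed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["ScreeningReport", "flag_fast_prompts", "longstring",
           "apply_exclusions"]

_PROMPT = ["subject_id", "occasion_index"]


@dataclass
class ScreeningReport:
    """Counts, thresholds and identities of every screening removal."""

    n_prompts_flagged_itemtime: int = 0
    n_blocks_flagged_longstring: int = 0
    n_occasions_excluded: dict = field(default_factory=dict)  # per task
    n_subjects_flagged_min_assessments: int = 0
    n_subjects_retained: int = 0
    thresholds: dict = field(default_factory=dict)
    complete_definition: str = "both tasks valid on both blocks"
    flagged_prompts_itemtime: list = field(default_factory=list)
    flagged_prompts_longstring: list = field(default_factory=list)
    flagged_occasions_er: dict = field(default_factory=dict)
    flagged_subjects: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def flag_fast_prompts(questionnaire: pd.DataFrame, *,
                      threshold_s: float = 1.0) -> set:
    """Prompts whose mean per-item completion time is < ``threshold_s``.

    Returns a set of (subject_id, occasion_index) pairs.  The comparison is
    strict: a mean of exactly 1.0 s is not flagged.
    """
    if "item_time_s" not in questionnaire.columns:
        raise KeyError("questionnaire table lacks column 'item_time_s'")
    if len(questionnaire) == 0:
        warnings.warn("empty questionnaire table: no prompts flagged")
        return set()
    means = questionnaire.groupby(_PROMPT)["item_time_s"].mean()
    return set(means.index[means < threshold_s])


def longstring(response_codes) -> int:
    """Length of the longest run of identical consecutive values."""
    seq = list(response_codes)
    if not seq:
        warnings.warn("empty response sequence: longstring is 0")
        return 0
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def _degenerate(sd: float, mean: float) -> bool:
    # zero up to float cancellation noise in the moment computation
    return sd <= max(abs(mean), 1.0) * 1e-10


def _occasion_er(blocks: pd.DataFrame, col: str) -> pd.Series:
    return blocks.groupby(_PROMPT)[col].mean().dropna()


def apply_exclusions(blocks: pd.DataFrame,
                     questionnaire: pd.DataFrame | None = None,
                     trials: pd.DataFrame | None = None, *,
                     itemtime_threshold_s: float = 1.0,
                     sd_multiplier: float = 3.0,
                     min_assessments: int = 5
                     ) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply the screening rules to a scored block table.

    ``trials`` supplies Stroop response codes for the longstring rule; if
    omitted that rule is skipped.  Returns the filtered blocks (removed
    scores set to missing, with validity flags cleared) and a report that
    reconstructs every removal.
    """
    blocks = blocks.copy()
    report = ScreeningReport()
    report.thresholds["itemtime_s"] = itemtime_threshold_s
    report.thresholds["sd_multiplier"] = sd_multiplier
    report.thresholds["min_assessments"] = min_assessments

    # rule 1: fast questionnaires remove the whole prompt
    if questionnaire is not None and len(questionnaire):
        fast = flag_fast_prompts(questionnaire,
                                 threshold_s=itemtime_threshold_s)
        if fast:
            key = pd.MultiIndex.from_frame(blocks[_PROMPT])
            drop = key.isin(fast)
            blocks = blocks[~drop]
        report.n_prompts_flagged_itemtime = len(fast)
        report.flagged_prompts_itemtime = sorted(
            (int(s), int(o)) for s, o in fast)

    score_cols = {"stroop": [c for c in ("stroop_er", "stroop_rtdiff")
                             if c in blocks.columns],
                  "gng": [c for c in ("gng_er", "gng_rt")
                          if c in blocks.columns]}

    # rule 2: Stroop longstring > mean + k*SD removes the prompt's Stroop data
    # (cut-offs computed on the post-rule-1 dataset)
    if trials is not None and len(trials) and score_cols["stroop"]:
        kept = pd.MultiIndex.from_frame(blocks[_PROMPT].drop_duplicates())
        st = trials[trials["task"] == "stroop"]
        st = st[pd.MultiIndex.from_frame(st[_PROMPT]).isin(kept)]
        ls = (st.sort_values("trial_index", kind="stable")
                .groupby(_PROMPT + ["block"])["response_code"]
                .agg(longstring))
        mean, sd = float(ls.mean()), float(ls.std(ddof=1))
        report.thresholds["longstring_mean"] = mean
        report.thresholds["longstring_sd"] = sd
        if not np.isfinite(sd) or _degenerate(sd, mean):
            warnings.warn("degenerate longstring SD: no block exceeds the cut")
            flagged_blocks = ls.iloc[0:0]
        else:
            flagged_blocks = ls[ls > mean + sd_multiplier * sd]
        report.n_blocks_flagged_longstring = int(len(flagged_blocks))
        flagged_prompts = {(s, o) for s, o, _b in flagged_blocks.index}
        report.flagged_prompts_longstring = sorted(
            (int(s), int(o)) for s, o in flagged_prompts)
        if flagged_prompts:
            key = pd.MultiIndex.from_frame(blocks[_PROMPT])
            hit = key.isin(flagged_prompts)
            blocks.loc[hit, score_cols["stroop"]] = np.nan
            if "valid_stroop" in blocks.columns:
                blocks.loc[hit, "valid_stroop"] = 0

    # rule 3: occasion-level ER > mean + k*SD drops that task's scores
    for task, er_col in (("stroop", "stroop_er"), ("gng", "gng_er")):
        if er_col not in blocks.columns:
            continue
        er = _occasion_er(blocks, er_col)
        mean, sd = float(er.mean()), float(er.std(ddof=1))
        report.thresholds[f"{er_col}_mean"] = mean
        report.thresholds[f"{er_col}_sd"] = sd
        if not np.isfinite(sd) or _degenerate(sd, mean):
            warnings.warn(f"degenerate {er_col} SD: no occasion exceeds the cut")
            flagged = []
        else:
            flagged = list(er.index[er > mean + sd_multiplier * sd])
        report.flagged_occasions_er[task] = sorted(
            (int(s), int(o)) for s, o in flagged)
        report.n_occasions_excluded[task] = len(flagged)
        if flagged:
            key = pd.MultiIndex.from_frame(blocks[_PROMPT])
            hit = key.isin(set(flagged))
            blocks.loc[hit, score_cols[task]] = np.nan
            vcol = f"valid_{task}"
            if vcol in blocks.columns:
                blocks.loc[hit, vcol] = 0

    # rule 4: subjects need >= min_assessments complete assessments
    have = [c for c in ("valid_stroop", "valid_gng") if c in blocks.columns]
    if have:
        occ_complete = (blocks.groupby(_PROMPT)[have].min().min(axis=1)
                        * (blocks.groupby(_PROMPT).size() == 2))
        n_complete = occ_complete.groupby(level=0).sum()
        short = n_complete[n_complete < min_assessments]
        report.n_subjects_flagged_min_assessments = int(len(short))
        report.flagged_subjects = [int(s) for s in short.index]
        report.n_subjects_retained = int((n_complete >= min_assessments).sum())
    return blocks.reset_index(drop=True), report
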