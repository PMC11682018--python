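"""Reliability of change (R_c) from a two-way random-effects decomposition.

Block scores are modeled as

    Y_ntb = mu + p_n + (pt)_nt + e_ntb

with independent person, person-by-occasion and residual effects of
variances sigma2_person, sigma2_person_time and sigma2_error.  The
within-subject reliability of change over the m parallel block indicators
is

    R_c = sigma2_person_time / (sigma2_person_time + sigma2_error / m).

Components are estimated by restricted maximum likelihood (REML); on
balanced complete data an expected-mean-squares method-of-moments solution
is available as a cross-check and the two agree.  The REML likelihood uses
the orthogonal within-cell/cell-mean split with a rank-one Sherman-Morrison
inverse per subject, so fits are fast even for the per-trial-count curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .scoring import score_with_subset

__all__ = ["VarianceComponents", "estimate_components", "rc",
           "rc_by_trialcount", "rc_by_day"]


@dataclass
class VarianceComponents:
    """Estimated components of the two-way random-effects decomposition."""

    sigma2_person: float
    sigma2_person_time: float
    sigma2_error: float
    m: int  # number of parallel block indicators
    method: str = "reml"
    raw: dict | None = None  # pre-truncation estimates (method of moments)

    def as_dict(self) -> dict:
        return asdict(self)


def _long_table(data: pd.DataFrame, score: str | None) -> pd.DataFrame:
    if score is not None:
        cols = {"subject_id": "subject", "occasion_index": "occasion",
                score: "value"}
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"blocks table lacks columns {missing}")
        out = data.rename(columns=cols)[["subject", "occasion", "value"]]
    else:
        out = data[["subject", "occasion", "value"]].copy()
    return out.dropna(subset=["value"])


def _mom_balanced(d: pd.DataFrame) -> tuple[dict, dict]:
    """Expected-mean-squares solution on balanced complete data."""
    wide = d.pivot_table(index=["subject", "occasion"], columns=d.groupby(
        ["subject", "occasion"]).cumcount(), values="value")
    m = wide.shape[1]
    if wide.isna().any().any():
        raise ValueError("method-of-moments requires balanced complete data")
    N = wide.index.get_level_values(0).nunique()
    T = wide.groupby(level=0).size().iloc[0]
    cell = wide.mean(axis=1)
    person = cell.groupby(level=0).mean()
    grand = person.mean()
    ms_e = float(((wide.sub(cell, axis=0)) ** 2).to_numpy().sum()
                 / (N * T * (m - 1)))
    ms_pt = float(m * ((cell - person.reindex(
        cell.index.get_level_values(0)).to_numpy()) ** 2).sum()
        / (N * (T - 1)))
    ms_p = float(T * m * ((person - grand) ** 2).sum() / (N - 1))
    raw = {"sigma2_error": ms_e,
           "sigma2_person_time": (ms_pt - ms_e) / m,
           "sigma2_person": (ms_p - ms_pt) / (T * m)}
    est = {k: max(v, 0.0) for k, v in raw.items()}
    if any(v < 0 for v in raw.values()):
        warnings.warn("negative method-of-moments component truncated to 0")
    return est, raw


def _reml_suffstats(d: pd.DataFrame):
    """Per-subject cell means, replicate counts and within-cell SS."""
    g = d.groupby(["subject", "occasion"])["value"]
    cell_mean = g.mean()
    cell_n = g.size()
    sswc = (g.var(ddof=0) * cell_n).fillna(0.0)
    subjects = []
    for s in cell_mean.index.get_level_values(0).unique():
        mu_t = cell_mean.loc[s].to_numpy()
        m_t = cell_n.loc[s].to_numpy(dtype=float)
        subjects.append((mu_t, m_t, float(sswc.loc[s].sum())))
    return subjects


def _reml_nll(log_sig, subjects):
    sp, spt, se = np.exp(log_sig)
    log2pi = np.log(2.0 * np.pi)
    ll = 0.0
    xtvx = 0.0
    xtvy = 0.0
    parts = []
    for mu_t, m_t, sswc in subjects:
        n_within = m_t.sum() - len(m_t)
        ll += -0.5 * (n_within * (log2pi + np.log(se)) + sswc / se)
        # z = sqrt(m) * cell mean  ~  N(sqrt(m)*mu, D + sp * a a^T)
        a = np.sqrt(m_t)
        z = a * mu_t
        D = m_t * spt + se
        u = a / D
        s1 = float(a @ u)
        c = 1.0 / (1.0 + sp * s1)
        xtvx += s1 * c
        xtvy += float(u @ z) * c
        parts.append((a, z, D, u, c))
        ll += -0.5 * (len(m_t) * log2pi + float(np.log(D).sum())
                      + np.log1p(sp * s1))
    mu_hat = xtvy / xtvx
    for a, z, D, u, c in parts:
        r = z - a * mu_hat
        quad = float((r * r / D).sum()) - sp * float(u @ r) ** 2 * c
        ll += -0.5 * quad
    ll += -0.5 * np.log(xtvx)  # REML correction for the profiled mean
    return -ll


def estimate_components(data: pd.DataFrame, score: str | None = None, *,
                        method: str = "reml") -> VarianceComponents:
    """Estimate (sigma2_person, sigma2_person_time, sigma2_error).

    ``data`` is either a scored block table (pass the ``score`` column
    name) or a generic long table with columns subject/occasion/value.
    ``method`` is ``"reml"`` (default, handles unbalanced data) or
    ``"mom"`` (expected mean squares, balanced complete data only).
    """
    d = _long_table(data, score)
    if d["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    cell_sizes = d.groupby(["subject", "occasion"]).size()
    if (cell_sizes < 2).all():
        raise ValueError("all occasions have a single block score: "
                         "residual variance is not identified")
    m = int(cell_sizes.mode().iloc[0])

    if method == "mom":
        est, raw = _mom_balanced(d)
        return VarianceComponents(est["sigma2_person"],
                                  est["sigma2_person_time"],
                                  est["sigma2_error"], m=m, method="mom",
                                  raw=raw)
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")

    subjects = _reml_suffstats(d)
    total_var = float(d["value"].var(ddof=1))
    v0 = max(total_var / 3.0, 1e-8)
    try:
        mom_est, _ = _mom_balanced(d)
        x0 = np.log([max(mom_est["sigma2_person"], v0 * 1e-3),
                     max(mom_est["sigma2_person_time"], v0 * 1e-3),
                     max(mom_est["sigma2_error"], v0 * 1e-3)])
    except ValueError:
        x0 = np.log([v0, v0, v0])
    bounds = [(np.log(total_var) - 30.0, np.log(total_var) + 5.0)] * 3
    res = optimize.minimize(_reml_nll, x0, args=(subjects,),
                            method="L-BFGS-B", bounds=bounds)
    sp, spt, se = np.exp(res.x)
    floor = total_var * 1e-10
    return VarianceComponents(
        sigma2_person=float(0.0 if sp < floor else sp),
        sigma2_person_time=float(0.0 if spt < floor else spt),
        sigma2_error=float(se), m=m, method="reml")


def rc(components: VarianceComponents) -> float:
    """Reliability of change: sigma2_pt / (sigma2_pt + sigma2_e / m)."""
    denom = components.sigma2_person_time \
        + components.sigma2_error / components.m
    if denom == 0:
        warnings.warn("zero within-subject variance: R_c undefined")
        return float("nan")
    return components.sigma2_person_time / denom


def rc_by_trialcount(trials: pd.DataFrame, *, step: int = 2,
                     scores: tuple = ("stroop_er", "stroop_rtdiff",
                                      "gng_er", "gng_rt"),
                     max_n: int | None = None) -> pd.DataFrame:
    """R_c as a function of trials per block and condition.

    For each n in step, 2*step, ... the blocks are rescored from the first
    n trials of each condition in presentation order, components are
    re-estimated per score, and the curve is emitted as a tidy table.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    feeds = {"stroop_er": [("stroop", "incongruent")],
             "stroop_rtdiff": [("stroop", "congruent"),
                               ("stroop", "incongruent")],
             "gng_er": [("gng", "nogo")],
             "gng_rt": [("gng", "go")]}
    cond_max = trials.groupby(["task", "condition"]).apply(
        lambda g: g.groupby(["subject_id", "occasion_index", "block"])
                   .size().max(), include_groups=False)
    top = int(cond_max.max() if max_n is None else max_n)
    rows = []
    for n in range(step, top + 1, step):
        sub = score_with_subset(trials, n)
        for sc in scores:
            if sc not in sub.columns:
                continue
            limit = int(min(cond_max.get(k, 0) for k in feeds[sc]))
            if n > limit:
                continue
            try:
                comp = estimate_components(sub, sc)
            except ValueError:
                continue
            rows.append({"score": sc, "n_per_condition": n,
                         "rc": rc(comp),
                         "sigma2_person": comp.sigma2_person,
                         "sigma2_person_time": comp.sigma2_person_time,
                         "sigma2_error": comp.sigma2_error})
    return pd.DataFrame(rows)


def rc_by_day(blocks: pd.DataFrame, *,
              scores: tuple = ("stroop_er", "stroop_rtdiff",
                               "gng_er", "gng_rt"),
              method: str = "reml") -> pd.DataFrame:
    """R_c estimated separately within each study day."""
    if "day" not in blocks.columns:
        raise KeyError("blocks table lacks a 'day' column")
    rows = []
    for day, g in blocks.groupby("day", sort=True):
        occ_per_subject = g.groupby("subject_id")["occasion_index"].nunique()
        if occ_per_subject.max() < 2:
            warnings.warn(f"day {day}: fewer than 2 occasions per subject, "
                          "skipped")
            continue
        for sc in scores:
            if sc not in g.columns:
                continue
            try:
                comp = estimate_components(g, sc, method=method)
            except ValueError:
                continue
            rows.append({"day": day, "score": sc, "rc": rc(comp),
                         "sigma2_person": comp.sigma2_person,
                         "sigma2_person_time": comp.sigma2_person_time,
                         "sigma2_error": comp.sigma2_error})
    return pd.DataFrame(rows)
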