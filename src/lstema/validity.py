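"""Within/between correlation decomposition and multilevel context models.

Convergent validity between repeatedly measured scores is assessed at two
levels: the between-subject correlation of person means, and the
within-subject correlation of person-mean-centered observations pooled over
all prompts.  Contextual prediction of the task scores uses a linear mixed
model with a random intercept per subject; continuous variables are
within-subject-centered and grand-mean-standardized first, and the
explained within-subject variance of the fixed effects is reported as
var(X*beta) / (var(X*beta) + residual variance), a marginal-R2
construction restricted to the within-centered outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

__all__ = ["CorrPair", "ContextModelResult", "within_between_corr",
           "within_center_standardize", "fit_context_model"]


@dataclass
class CorrPair:
    """Between- and within-subject Pearson correlations of two streams."""

    r_between: float
    r_within: float
    p_between: float
    p_within: float
    n_subjects: int
    n_observations: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ContextModelResult:
    """Mixed-model fit of context predictors on a within-centered score."""

    coefficients: dict
    p_values: dict
    random_intercept_var: float
    residual_var: float
    r2_within: float
    n_subjects: int
    n_observations: int
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def _pearson_with_p(x: np.ndarray, y: np.ndarray, df: int):
    if len(x) < 3 or df < 1:
        return float("nan"), float("nan")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def within_between_corr(x, y, subjects) -> CorrPair:
    """Decompose the x-y association into between and within parts.

    between: Pearson correlation of per-subject means (unweighted), df =
    n_subjects - 2.  within: Pearson correlation of person-mean-centered
    values pooled over observations, df = n_observations - n_subjects - 1;
    only subjects with >= 2 paired observations contribute to it.
    """
    d = pd.DataFrame({"x": np.asarray(x, dtype=float),
                      "y": np.asarray(y, dtype=float),
                      "s": np.asarray(subjects)}).dropna()
    n_obs = len(d)
    n_subj = d["s"].nunique()
    if n_subj < 3:
        raise ValueError("between-subject correlation needs >= 3 subjects")
    means = d.groupby("s")[["x", "y"]].mean()
    r_b, p_b = _pearson_with_p(means["x"].to_numpy(), means["y"].to_numpy(),
                               n_subj - 2)
    counts = d.groupby("s").size()
    multi = d[d["s"].isin(counts.index[counts >= 2])]
    if len(multi):
        cx = multi["x"] - multi.groupby("s")["x"].transform("mean")
        cy = multi["y"] - multi.groupby("s")["y"].transform("mean")
        r_w, p_w = _pearson_with_p(cx.to_numpy(), cy.to_numpy(),
                                   n_obs - n_subj - 1)
    else:
        r_w, p_w = float("nan"), float("nan")
    return CorrPair(r_between=r_b, r_within=r_w, p_between=p_b,
                    p_within=p_w, n_subjects=n_subj, n_observations=n_obs)


def within_center_standardize(values, subjects) -> np.ndarray:
    """Within-subject-center, then divide by the pooled SD of the
    centered values."""
    v = np.asarray(values, dtype=float)
    s = pd.Series(v).groupby(np.asarray(subjects)).transform("mean")
    centered = v - s.to_numpy()
    sd = float(np.nanstd(centered, ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("pooled SD of within-centered values is zero")
    return centered / sd


def fit_context_model(outcome, predictors: pd.DataFrame, subjects,
                      *, beep_col: str = "beep",
                      continuous: tuple = ("tiredness",)) -> ContextModelResult:
    """Random-intercept mixed model of context predictors on a task score.

    ``outcome`` and continuous predictors are within-centered and
    grand-mean-standardized; the beep number is coded categorical with
    beep 1 as reference.  Fitted by REML via statsmodels MixedLM.
    """
    d = predictors.copy()
    d["_subject"] = np.asarray(subjects)
    d["_y_raw"] = np.asarray(outcome, dtype=float)
    d = d.dropna()
    d["_y"] = within_center_standardize(d["_y_raw"], d["_subject"])
    terms = []
    for c in d.columns:
        if c.startswith("_"):
            continue
        if c == beep_col:
            terms.append(f"C({beep_col}, Treatment(1))")
        elif c in continuous:
            d[c] = within_center_standardize(d[c], d["_subject"])
            terms.append(c)
        else:
            terms.append(c)
    X = pd.get_dummies(d[[t for t in d.columns if not t.startswith("_")]],
                       columns=[beep_col] if beep_col in d.columns else [],
                       drop_first=True, dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        aliased = [c for c in X.columns
                   if (corr.loc[c].drop(c) > 0.999).any()]
        raise ValueError(f"rank-deficient design; aliased predictors: "
                         f"{aliased or list(X.columns)}")
    formula = "_y ~ " + " + ".join(terms)
    # with a within-centered outcome the random-intercept variance is near
    # zero; if the mixed fit degenerates, OLS is the exact limiting model
    ri_var = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, d, groups=d["_subject"])
        try:
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
            ri_var = float(fit.cov_re.iloc[0, 0])
            exog = pd.DataFrame(model.exog, columns=model.exog_names)
        except np.linalg.LinAlgError:
            model = smf.ols(formula, d)
            fit = model.fit()
            exog = pd.DataFrame(model.exog, columns=model.exog_names)
    fe = fit.params if not hasattr(fit, "fe_params") else fit.fe_params
    coefs = {k: float(v) for k, v in fe.items() if k != "Intercept"}
    pvals = {k: float(fit.pvalues[k]) for k in coefs}
    lin = exog.drop(columns=["Intercept"]).to_numpy() @ np.array(
        [fe[k] for k in exog.columns if k != "Intercept"])
    var_fixed = float(np.var(lin, ddof=0))
    resid_var = float(fit.scale) if hasattr(fit, "scale") else \
        float(fit.mse_resid)
    r2_within = var_fixed / (var_fixed + resid_var)
    return ContextModelResult(
        coefficients=coefs, p_values=pvals,
        random_intercept_var=ri_var,
        residual_var=resid_var, r2_within=r2_within,
        n_subjects=int(d["_subject"].nunique()), n_observations=int(len(d)),
        metadata={
            "outcome_transform": "within-subject centered, divided by the "
                                 "pooled SD of centered values",
            "r2_within": "var(X beta) / (var(X beta) + residual variance) "
                         "on the within-centered outcome",
            "beep_reference": 1,
            "estimator": "statsmodels MixedLM, REML",
        })
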