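"""AR(1) latent state-trait model (DSEM) for paired block indicators.

The measurement design is two parallel block scores per scheduled occasion.
Observed score ``Y_itn`` (indicator i, occasion t, person n) decomposes as

    Y_itn = xi_n + OCC_tn + beta * time_t + eps_itn

where ``xi_n`` is the person trait at t=1 (mean ``mu_trait``, variance
``var_trait``), ``time_t = t - 1`` is the 0-based scheduled occasion index,
and the shared occasion factor follows a started AR(1) process

    OCC_1n = zeta_1n,    OCC_tn = phi * OCC_{t-1,n} + zeta_tn

with innovation variance ``var_state`` (equal over t) and measurement error
variance ``var_error`` (equal over indicators and occasions).  All latent
variables and errors are Gaussian and mutually independent.

Estimation is maximum marginal likelihood: the likelihood marginalizes the
latent trait and occasion process exactly, handles missing occasions by
restriction to observed coordinates, and is evaluated either directly from
the joint 2T-dimensional Gaussian (:func:`build_joint_covariance`, the
oracle) or by a Kalman filter (:func:`loglik`, the fast path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DSEMParams",
    "DSEMFit",
    "VarianceIndices",
    "build_joint_covariance",
    "loglik",
    "loglik_direct",
    "fit_dsem",
    "compute_indices",
    "blocks_to_wide",
]

_PARAM_NAMES = ("mu_trait", "var_trait", "beta", "phi", "var_state", "var_error")


@dataclass
class DSEMParams:
    """The six parameters of the AR(1) latent state-trait model.

    Units: ``mu_trait`` in score units, ``var_trait``/``var_state``/
    ``var_error`` in squared score units, ``beta`` in score units per
    occasion, ``phi`` dimensionless with |phi| < 1.
    """

    mu_trait: float = 0.0
    var_trait: float = 1.0
    beta: float = 0.0
    phi: float = 0.0
    var_state: float = 1.0
    var_error: float = 1.0

    def validate(self) -> "DSEMParams":
        for name in ("var_trait", "var_state", "var_error"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not np.isfinite(self.phi) or abs(self.phi) >= 1:
            raise ValueError(f"phi must satisfy |phi| < 1, got {self.phi!r}")
        return self

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class DSEMFit:
    """Result of a maximum-likelihood fit."""

    params: DSEMParams
    loglik: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    n_subjects: int = 0
    n_occasions: int = 0
    n_obs: int = 0
    indices: "VarianceIndices | None" = None
    message: str = ""

    def as_dict(self) -> dict:
        d = {
            "params": self.params.as_dict(),
            "se": dict(self.se),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_subjects": int(self.n_subjects),
            "n_occasions": int(self.n_occasions),
            "n_obs": int(self.n_obs),
            "message": self.message,
        }
        if self.indices is not None:
            d["indices"] = self.indices.as_dict()
        return d


@dataclass
class VarianceIndices:
    """Variance decomposition of the observed score.

    ``var_occ`` is the occasion-factor variance approximated by the 4-lag
    truncation var_state * (1 + phi^2 + ... + phi^8); the exact stationary
    value var_state / (1 - phi^2) is reported alongside for sensitivity.

    rel        = (var_trait + var_occ) / var_total   (overall reliability)
    con        = var_trait / var_total               (common consistency)
    spe        = var_state / var_total               (occasion specificity)
    rel_within = var_occ / (var_occ + var_error)     (within-subject reliability)
    """

    var_occ: float
    var_occ_stationary: float
    var_total: float
    rel: float
    con: float
    spe: float
    rel_within: float

    def as_dict(self) -> dict:
        return asdict(self)


def _occ_cov_matrix(phi: float, var_state: float, T: int,
                    stationary_init: bool = False) -> np.ndarray:
    """Covariance of (OCC_1, ..., OCC_T) under the started AR(1) process."""
    t = np.arange(1, T + 1)
    if stationary_init:
        var_t = np.full(T, var_state / (1.0 - phi ** 2)) if phi != 0 else np.full(T, var_state)
    else:
        if phi == 0.0:
            var_t = np.full(T, var_state)
        else:
            var_t = var_state * (1.0 - phi ** (2 * t)) / (1.0 - phi ** 2)
    tt = np.abs(t[:, None] - t[None, :])
    vmin = np.minimum.outer(var_t, var_t)  # Var(OCC_min(t,t')) since var_t nondecreasing
    return (phi ** tt) * vmin


def build_joint_covariance(params: DSEMParams, T: int, *,
                           stationary_init: bool = False
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and covariance of one subject's 2T observation vector.

    Ordering is occasion-major: ``(t=1, block 1), (t=1, block 2), (t=2,
    block 1), ...``.  Serves as the brute-force likelihood oracle for
    :func:`loglik`.
    """
    params.validate()
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    time_t = np.arange(T, dtype=float)  # time_1 = 0
    mean_occ = params.mu_trait + params.beta * time_t
    mean = np.repeat(mean_occ, 2)
    occ_cov = _occ_cov_matrix(params.phi, params.var_state, T, stationary_init)
    # both indicators load 1 on trait and OCC
    cov = params.var_trait + np.kron(occ_cov, np.ones((2, 2)))
    cov = cov + params.var_error * np.eye(2 * T)
    return mean, cov


def loglik_direct(params: DSEMParams, y: np.ndarray, *,
                  stationary_init: bool = False) -> float:
    """Direct joint-Gaussian log-likelihood (oracle path).

    ``y`` has shape (N, T, 2) with NaN marking missing entries.
    """
    mean, cov = build_joint_covariance(params, y.shape[1],
                                       stationary_init=stationary_init)
    total = 0.0
    for row in y.reshape(y.shape[0], -1):
        obs = np.isfinite(row)
        if not obs.any():
            warnings.warn("subject with zero observed entries contributes 0")
            continue
        total += stats.multivariate_normal.logpdf(
            row[obs], mean[obs], cov[np.ix_(obs, obs)])
    return float(total)


def loglik(params: DSEMParams, y: np.ndarray, *,
           stationary_init: bool = False, validate: bool = True) -> float:
    """Marginal log-likelihood via a Kalman filter, vectorized over subjects.

    Exploits exchangeability of the two block indicators: at a complete
    occasion the pair is equivalent to its mean (noise var_error/2) plus an
    independent N(0, 2*var_error) difference.  Agrees with
    :func:`loglik_direct` to numerical precision.
    """
    if validate:
        params.validate()
    y = np.asarray(y, dtype=float)
    if y.ndim != 3 or y.shape[2] != 2:
        raise ValueError("y must have shape (n_subjects, n_occasions, 2)")
    N, T, _ = y.shape
    mu, vt, beta = params.mu_trait, params.var_trait, params.beta
    phi, vs, ve = params.phi, params.var_state, params.var_error

    y1, y2 = y[:, :, 0], y[:, :, 1]
    f1, f2 = np.isfinite(y1), np.isfinite(y2)
    both = f1 & f2
    any_obs = f1 | f2
    if not any_obs.any(axis=1).all():
        warnings.warn("subject with zero observed entries contributes 0")

    ll = 0.0
    if both.any():
        d = (y1 - y2)[both]
        ll += -0.5 * np.sum(np.log(2.0 * np.pi * 2.0 * ve) + d ** 2 / (2.0 * ve))

    ybar = np.where(both, 0.5 * (y1 + y2), np.where(f1, y1, y2))
    r = np.where(both, 0.5 * ve, ve)

    m1 = np.full(N, mu)
    m2 = np.zeros(N)
    p11 = np.full(N, vt)
    p12 = np.zeros(N)
    # stationary variance is a fixed point of the predict step
    p22 = np.full(N, vs / (1.0 - phi ** 2)) if stationary_init else np.zeros(N)

    log2pi = np.log(2.0 * np.pi)
    for t in range(T):
        # predict: occ_t = phi * occ_{t-1} + zeta_t
        m2 = phi * m2
        p22 = phi * phi * p22 + vs
        p12 = phi * p12
        obs = any_obs[:, t]
        if obs.any():
            v = ybar[:, t] - (m1 + m2) - beta * t
            S = p11 + 2.0 * p12 + p22 + r[:, t]
            ph1 = p11 + p12
            ph2 = p12 + p22
            k1 = ph1 / S
            k2 = ph2 / S
            ll += -0.5 * np.sum(np.where(obs, log2pi + np.log(S) + v * v / S, 0.0))
            m1 = np.where(obs, m1 + k1 * v, m1)
            m2 = np.where(obs, m2 + k2 * v, m2)
            p11n = p11 - k1 * ph1
            p12n = p12 - k1 * ph2
            p22n = p22 - k2 * ph2
            p11 = np.where(obs, p11n, p11)
            p12 = np.where(obs, p12n, p12)
            p22 = np.where(obs, p22n, p22)
    return float(ll)


def _theta_to_params(theta: np.ndarray) -> DSEMParams:
    return DSEMParams(
        mu_trait=theta[0],
        var_trait=np.exp(theta[1]),
        beta=theta[2],
        phi=np.tanh(theta[3]),
        var_state=np.exp(theta[4]),
        var_error=np.exp(theta[5]),
    )


def _params_to_theta(p: DSEMParams) -> np.ndarray:
    clip = lambda v: np.log(max(v, 1e-8))
    return np.array([p.mu_trait, clip(p.var_trait), p.beta,
                     np.arctanh(np.clip(p.phi, -0.99, 0.99)),
                     clip(p.var_state), clip(p.var_error)])


def _moment_start(y: np.ndarray) -> DSEMParams:
    """Data-driven starting values from simple moment summaries."""
    ybar = np.nanmean(y, axis=2)  # (N, T) occasion means, NaN where empty
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        person = np.nanmean(ybar, axis=1)
        mu0 = float(np.nanmean(person))
        vt0 = float(np.nanvar(person, ddof=1))
        centered = ybar - person[:, None]
        within_var = float(np.nanvar(centered))
        # lag-1 autocorrelation of person-centered occasion means
        a, b = centered[:, :-1].ravel(), centered[:, 1:].ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        phi0 = float(np.corrcoef(a[ok], b[ok])[0, 1]) if ok.sum() > 4 else 0.0
        # slope of occasion means on time
        t = np.arange(y.shape[1], dtype=float)
        tt = np.broadcast_to(t, ybar.shape)
        okt = np.isfinite(ybar)
        if okt.sum() > 4:
            beta0 = float(np.polyfit(tt[okt], (ybar - person[:, None] + mu0)[okt], 1)[0])
        else:
            beta0 = 0.0
    if not np.isfinite(phi0):
        phi0 = 0.0
    phi0 = float(np.clip(phi0, -0.9, 0.9))
    if not np.isfinite(vt0) or vt0 <= 0:
        vt0 = max(within_var, 1e-4)
    half = max(within_var / 2.0, 1e-4)
    return DSEMParams(mu0, max(vt0, 1e-4), beta0, phi0, half, half)


def fit_dsem(y: np.ndarray | pd.DataFrame, *, score: str | None = None,
             n_occasions: int | None = None, stationary_init: bool = False,
             min_complete: int = 5, compute_se: bool = True,
             extra_starts: int = 2) -> DSEMFit:
    """Fit the AR(1) latent state-trait model by maximum marginal likelihood.

    Parameters
    ----------
    y
        Either an (N, T, 2) array with NaN for missing entries, or a long
        block-score table (columns subject_id, occasion_index, block and the
        score column named by ``score``), pivoted via :func:`blocks_to_wide`.
    score
        Score column name when ``y`` is a DataFrame.
    min_complete
        Subjects with fewer complete occasions (both blocks observed) are
        dropped before fitting.
    extra_starts
        Number of fixed perturbed starting points added to the data-driven
        start; the best final likelihood wins, deterministically.
    """
    if isinstance(y, pd.DataFrame):
        if score is None:
            raise ValueError("score column name required for DataFrame input")
        y = blocks_to_wide(y, score, n_occasions=n_occasions)
    y = np.asarray(y, dtype=float)
    complete = np.isfinite(y).all(axis=2).sum(axis=1)
    keep = complete >= min_complete
    if not keep.all():
        y = y[keep]
    if y.shape[0] < 2:
        raise ValueError("need at least 2 subjects with enough complete occasions")

    start = _moment_start(y)
    starts = [_params_to_theta(start)]
    fixed = [DSEMParams(start.mu_trait, start.var_trait, 0.0, 0.0,
                        start.var_state, start.var_error),
             DSEMParams(start.mu_trait, start.var_trait, start.beta, 0.6,
                        start.var_state * 2.0, start.var_error / 2.0)]
    starts += [_params_to_theta(p) for p in fixed[:extra_starts]]

    def nll(theta):
        p = _theta_to_params(theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = loglik(p, y, stationary_init=stationary_init, validate=False)
        return -val if np.isfinite(val) else 1e12

    best = None
    for th0 in starts:
        res = optimize.minimize(nll, th0, method="L-BFGS-B",
                                options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    params = _theta_to_params(best.x)
    fit = DSEMFit(
        params=params,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_subjects=int(y.shape[0]),
        n_occasions=int(y.shape[1]),
        n_obs=int(np.isfinite(y).sum()),
        message=str(best.message),
    )
    if compute_se:
        fit.se = _observed_info_se(best.x, nll)
    fit.indices = compute_indices(params)
    return fit


def _observed_info_se(theta: np.ndarray, nll, h: float = 1e-4) -> dict:
    """Delta-method standard errors from a central-difference Hessian."""
    k = len(theta)
    H = np.zeros((k, k))
    f0 = nll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(theta + ei + ej) - nll(theta + ei - ej)
                    - nll(theta - ei + ej) + nll(theta - ei - ej)) / (4 * h ** 2)
    try:
        cov = np.linalg.inv(H)
        var = np.diag(cov)
    except np.linalg.LinAlgError:
        return {}
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        return {}
    sd = np.sqrt(var)
    p = _theta_to_params(theta)
    # chain rule: d(exp)/dtheta = value, d(tanh)/dtheta = 1 - phi^2
    jac = np.array([1.0, p.var_trait, 1.0, 1.0 - p.phi ** 2,
                    p.var_state, p.var_error])
    return dict(zip(_PARAM_NAMES, (sd * jac).tolist()))


def compute_indices(params: DSEMParams, *, lags: int = 4) -> VarianceIndices:
    """Variance-decomposition indices from fitted parameters.

    ``var_occ`` uses the truncated sum var_state * sum_{j=0}^{lags} phi^(2j),
    the default 4-lag approximation of the occasion-factor variance; the
    exact stationary value is reported alongside.
    """
    params.validate()
    phi2 = params.phi ** 2
    var_occ = params.var_state * float(np.sum(phi2 ** np.arange(lags + 1)))
    var_occ_stat = params.var_state / (1.0 - phi2)
    var_total = params.var_trait + var_occ + params.var_error
    if var_total == 0:
        warnings.warn("zero total variance: indices undefined")
        nan = float("nan")
        return VarianceIndices(var_occ, var_occ_stat, var_total,
                               nan, nan, nan, nan)
    rel = (params.var_trait + var_occ) / var_total
    con = params.var_trait / var_total
    spe = params.var_state / var_total
    within = var_occ + params.var_error
    rel_within = var_occ / within if within > 0 else float("nan")
    return VarianceIndices(var_occ, var_occ_stat, var_total,
                           rel, con, spe, rel_within)


def blocks_to_wide(blocks: pd.DataFrame, score: str, *,
                   n_occasions: int | None = None) -> np.ndarray:
    """Pivot a long block-score table to the (N, T, 2) estimator layout.

    The scheduled occasion grid 1..T is materialized for every subject;
    unanswered occasions stay NaN (the likelihood marginalizes them).
    """
    for col in ("subject_id", "occasion_index", "block", score):
        if col not in blocks.columns:
            raise KeyError(f"blocks table lacks column {col!r}")
    T = int(n_occasions or blocks["occasion_index"].max())
    subjects = np.sort(blocks["subject_id"].unique())
    sidx = {s: i for i, s in enumerate(subjects)}
    y = np.full((len(subjects), T, 2), np.nan)
    sub = blocks.dropna(subset=[score])
    i = sub["subject_id"].map(sidx).to_numpy()
    t = sub["occasion_index"].to_numpy(dtype=int) - 1
    b = sub["block"].to_numpy(dtype=int) - 1
    y[i, t, b] = sub[score].to_numpy(dtype=float)
    return y
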