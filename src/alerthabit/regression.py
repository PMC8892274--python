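"""Regression battery for grouped alert-dismissal outcomes.

Estimators
----------
* :class:`ConditionalLogisticRegression` — fixed-effects logistic grouped
  at the physician level, estimated by conditional maximum likelihood
  (physician intercepts conditioned out via the within-group success
  total), avoiding incidental-parameter bias with many groups.
* :class:`RandomInterceptLogisticRegression` — logistic with a normal
  physician random intercept, marginal likelihood integrated by
  Gauss-Hermite quadrature; yields the latent-threshold ICC
  sigma_u^2 / (sigma_u^2 + pi^2/3).
* :class:`WithinGroupOLS` — fixed-effects linear model (within
  transformation with degrees-of-freedom correction) for processing time.

All follow the fit(X, y, groups) convention with trailing-underscore
fitted attributes; the module-level ``fit_*`` helpers assemble design
matrices from an analysis table and wrap results in :class:`ModelResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess1

from .event_log import RANKS

LOGISTIC_LATENT_VARIANCE = math.pi**2 / 3.0

#: the full control list: alert context, historical exposure, physician,
#: patient, and timing covariates
DEFAULT_COVARIATES = [
    "ward_round",
    "P_C_total", "P_C_ward", "C_total", "C_PatNum", "day_lag",
    "physician_rank", "specialty", "department",
    "patient_age", "patient_gender", "patient_race",
    "length_of_stay", "diagnosis_count",
    "day_of_week", "month",
]

CATEGORICAL_COVARIATES = {
    "physician_rank", "specialty", "department",
    "patient_gender", "patient_race", "day_of_week", "month",
}


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated on the given data."""


@dataclass
class ModelSpec:
    """What to fit: outcome, habit measure, controls, estimator, grouping."""

    outcome: str = "dismiss"
    habit: str = "H_0.05"
    covariates: Sequence[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    estimator: str = "fixed_effects"  # fixed_effects | random_effects | pooled
    group: str = "physician_id"
    rank: str | None = None  # optional subsample filter


@dataclass
class ModelResult:
    """Fitted-model container serialisable to JSON.

    ``terms`` holds one row per estimated term: coef, se, ci_low, ci_high,
    pvalue, and odds_ratio (exp(coef)) for logistic outcomes.
    """

    outcome: str
    habit: str
    estimator: str
    terms: pd.DataFrame
    nobs: int
    n_groups: int | None = None
    n_groups_dropped: int = 0
    converged: bool = True
    sigma_u2: float | None = None
    icc: float | None = None
    dropped_terms: list = field(default_factory=list)
    message: str = ""

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "habit": self.habit,
            "estimator": self.estimator,
            "nobs": int(self.nobs),
            "n_groups": None if self.n_groups is None else int(self.n_groups),
            "n_groups_dropped": int(self.n_groups_dropped),
            "converged": bool(self.converged),
            "sigma_u2": self.sigma_u2,
            "icc": self.icc,
            "dropped_terms": list(self.dropped_terms),
            "message": self.message,
            "terms": {
                name: {k: (None if pd.isna(v) else float(v))
                       for k, v in row.items()}
                for name, row in self.terms.to_dict(orient="index").items()
            },
        }
        return d


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    table: pd.DataFrame,
    habit: str | None,
    covariates: Sequence[str],
    add_intercept: bool = False,
) -> pd.DataFrame:
    """Numeric design matrix: habit column first, then covariates.

    Categorical covariates are reference-coded with the modal category as
    reference (stable under subsampling); booleans become 0/1.
    """
    cols = {}
    if add_intercept:
        cols["const"] = np.ones(len(table))
    if habit is not None:
        cols[habit] = table[habit].to_numpy(dtype=float)
    for cov in covariates:
        if cov not in table.columns:
            raise KeyError(f"covariate {cov!r} not in analysis table")
        if cov in CATEGORICAL_COVARIATES:
            s = table[cov].astype(str)
            modal = s.mode().iloc[0]
            for level in sorted(s.unique()):
                if level == modal:
                    continue
                cols[f"{cov}[{level}]"] = (s == level).to_numpy(dtype=float)
        else:
            cols[cov] = table[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=table.index)


def _drop_group_constant(X: pd.DataFrame, codes: np.ndarray) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns with no within-group variation anywhere (not
    identified once group effects are conditioned out or demeaned)."""
    dropped = []
    keep = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        means = np.bincount(codes, weights=x) / np.bincount(codes)
        if np.allclose(x, means[codes], atol=1e-12, rtol=0.0):
            dropped.append(col)
        else:
            keep.append(col)
    return X[keep], dropped


# ---------------------------------------------------------------------------
# conditional (fixed-effects) logistic regression


def _prepare_conditional(X: np.ndarray, y: np.ndarray, codes: np.ndarray):
    """Pad groups to rectangular arrays, flipping groups whose success
    count exceeds half their size (complement identity) so the recursion
    depth is min(k, n-k)."""
    G = codes.max() + 1
    sizes = np.bincount(codes, minlength=G)
    succ = np.bincount(codes, weights=y, minlength=G).astype(int)
    flip = succ > sizes - succ
    n_max = sizes.max()
    p = X.shape[1]
    Xp = np.zeros((G, n_max, p))
    Yp = np.zeros((G, n_max))
    pos = np.zeros(G, dtype=int)
    order = np.argsort(codes, kind="stable")
    for i in order:
        g = codes[i]
        Xp[g, pos[g]] = X[i]
        Yp[g, pos[g]] = y[i]
        pos[g] += 1
    mask = np.arange(n_max)[None, :] < sizes[:, None]
    Xp[flip] = -Xp[flip]
    Yp[flip] = 1.0 - Yp[flip]
    Yp[~mask] = 0.0
    k = np.where(flip, sizes - succ, succ)
    return Xp, Yp, mask, k


def _conditional_loglike_grad(beta, Xp, Yp, mask, k):
    """Conditional log-likelihood and gradient via the elementary
    symmetric function recursion, vectorised across groups."""
    G, n_max, p = Xp.shape
    eta = Xp @ beta
    # centre each group at its max: cancels exactly in the conditional
    # likelihood and keeps every weight in (0, 1], so the recursion
    # cannot overflow
    center = np.where(mask, eta, -np.inf).max(axis=1)
    eta = (eta - center[:, None]) * mask
    w = np.exp(eta) * mask

    k_max = int(k.max())
    F = np.zeros((G, k_max + 1))
    F[:, 0] = 1.0
    Dg = np.zeros((G, k_max + 1, p))
    logscale = np.zeros(G)
    for i in range(n_max):
        wi = w[:, i]
        xi = Xp[:, i, :]
        if k_max >= 1:
            # gradient recursion first (uses pre-update F)
            Dg[:, 1:, :] = (Dg[:, 1:, :]
                            + wi[:, None, None] * Dg[:, :-1, :]
                            + (wi[:, None] * F[:, :-1])[:, :, None] * xi[:, None, :])
            F[:, 1:] = F[:, 1:] + wi[:, None] * F[:, :-1]
        m = F.max(axis=1)
        small = (m < 1e-200) & (m > 0)
        if small.any():
            F[small] /= m[small, None]
            Dg[small] /= m[small, None, None]
            logscale[small] += np.log(m[small])

    idx = np.arange(G)
    Fk = F[idx, k]
    with np.errstate(divide="ignore", invalid="ignore"):
        logD = np.log(Fk) + logscale
        dlogD = Dg[idx, k, :] / Fk[:, None]

    # group-constant shifts in eta appear k times in both the numerator
    # and log D, so centring cancels and the value equals the uncentred
    # conditional log-likelihood; the subset distribution is likewise
    # invariant, so the gradient uses the raw covariates
    num = (eta * Yp).sum(axis=1)
    dnum = np.einsum("gn,gnp->gp", Yp * mask, Xp)
    loglik = float((num - logD).sum())
    grad = (dnum - dlogD).sum(axis=0)
    if not np.isfinite(loglik) or not np.all(np.isfinite(grad)):
        return -np.inf, np.zeros(p)
    return loglik, grad


class ConditionalLogisticRegression(BaseEstimator):
    """Fixed-effects logistic regression by conditional maximum likelihood.

    Group-specific intercepts are eliminated by conditioning on each
    group's success total; groups without outcome variation carry no
    information and are dropped (counted in ``n_groups_dropped_``), as are
    covariates constant within every group (listed in
    ``dropped_features_``).  Standard errors are model-based (inverse
    observed information).

    Parameters
    ----------
    tol : float
        Gradient-norm convergence tolerance for the optimiser.
    max_iter : int
        Maximum optimiser iterations.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups):
        X = pd.DataFrame(X)
        feature_names = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise EstimationError("outcome must be binary 0/1")
        codes, _ = pd.factorize(np.asarray(groups), sort=True)

        # drop groups with no outcome variation
        G = codes.max() + 1
        succ = np.bincount(codes, weights=y, minlength=G)
        sizes = np.bincount(codes, minlength=G)
        varying = (succ > 0) & (succ < sizes)
        keep = varying[codes]
        self.n_groups_dropped_ = int((~varying).sum())
        self.n_groups_ = int(varying.sum())
        if self.n_groups_ < 1:
            raise EstimationError("no group has outcome variation")
        Xk = X.loc[keep]
        yk = y[keep]
        ck, _ = pd.factorize(codes[keep], sort=True)

        Xk, self.dropped_features_ = _drop_group_constant(Xk, ck)
        if Xk.shape[1] == 0:
            raise EstimationError("no covariate varies within groups")
        self.feature_names_in_ = list(Xk.columns)
        Xa = Xk.to_numpy(dtype=float)
        self.nobs_ = len(yk)

        # internal column standardisation for optimiser conditioning;
        # a linear reparameterisation, undone exactly afterwards
        scale = Xa.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = Xa / scale

        Xp, Yp, mask, k = _prepare_conditional(Xs, yk, ck)

        def negll(beta):
            ll, g = _conditional_loglike_grad(beta, Xp, Yp, mask, k)
            return -ll, -g

        beta0 = np.zeros(Xs.shape[1])
        res = optimize.minimize(
            negll, beta0, jac=True, method="BFGS",
            options={"gtol": self.tol * max(1.0, self.nobs_), "maxiter": self.max_iter},
        )
        self.converged_ = bool(res.success or np.linalg.norm(res.jac) < 1e-4 * self.nobs_)
        self.llf_ = -res.fun

        # observed information from forward differences of the analytic
        # gradient (symmetrised)
        p_dim = Xs.shape[1]
        g0 = _conditional_loglike_grad(res.x, Xp, Yp, mask, k)[1]
        H = np.empty((p_dim, p_dim))
        h_step = 1e-6 * np.maximum(np.abs(res.x), 1.0)
        for j in range(p_dim):
            xj = res.x.copy()
            xj[j] += h_step[j]
            H[j] = (_conditional_loglike_grad(xj, Xp, Yp, mask, k)[1] - g0) / h_step[j]
        H = (H + H.T) / 2.0
        try:
            cov = np.linalg.inv(-H)
            bad = np.diag(cov) <= 0
            if bad.any():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
            self.converged_ = False
        self.coef_ = res.x / scale
        self.cov_ = cov / np.outer(scale, scale)
        self.bse_ = np.sqrt(np.clip(np.diag(self.cov_), 0, None))
        return self

    @property
    def params_(self) -> pd.Series:
        return pd.Series(self.coef_, index=self.feature_names_in_)

    def conf_int_(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"low": self.coef_ - z * self.bse_, "high": self.coef_ + z * self.bse_},
            index=self.feature_names_in_,
        )

    @property
    def pvalues_(self) -> pd.Series:
        z = np.divide(self.coef_, self.bse_, out=np.zeros_like(self.coef_),
                      where=self.bse_ > 0)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.feature_names_in_)


# ---------------------------------------------------------------------------
# random-intercept logistic regression


def _gh_group_loglike(eta0, y, codes, G, log_sigma, nodes, weights):
    """Per-group marginal log-likelihoods by Gauss-Hermite quadrature."""
    sigma = np.exp(log_sigma)
    b = math.sqrt(2.0) * sigma * nodes  # quadrature offsets
    # observation loglik at each node: y*eta - log(1+exp(eta))
    eta = eta0[:, None] + b[None, :]
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    S = np.zeros((G, len(nodes)))
    np.add.at(S, codes, ll_obs)
    logw = np.log(weights) - 0.5 * math.log(math.pi)
    return special.logsumexp(S + logw[None, :], axis=1)


class RandomInterceptLogisticRegression(BaseEstimator):
    """Logistic regression with a normal random intercept per group.

    The marginal likelihood integrates the group intercept
    u_g ~ N(0, sigma_u^2) out by Gauss-Hermite quadrature (``n_quad``
    nodes) and is maximised over (beta, log sigma_u).  ``icc_`` reports
    the latent-threshold intraclass correlation
    sigma_u^2 / (sigma_u^2 + pi^2/3): the share of unexplained
    latent-scale variance attributable to the grouping level.
    """

    def __init__(self, n_quad: int = 25, tol: float = 1e-8, max_iter: int = 200):
        self.n_quad = n_quad
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups):
        X = pd.DataFrame(X)
        self.feature_names_in_ = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        codes, _ = pd.factorize(np.asarray(groups), sort=True)
        G = codes.max() + 1
        self.n_groups_ = int(G)
        self.nobs_ = len(y)
        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)

        def negll(theta):
            beta, log_sigma = theta[:-1], theta[-1]
            lg = _gh_group_loglike(Xa @ beta, y, codes, G, log_sigma, nodes, weights)
            return -float(lg.sum())

        start = np.zeros(Xa.shape[1] + 1)
        try:
            pooled = sm.Logit(y, Xa).fit(disp=0, maxiter=100)
            start[:-1] = pooled.params
        except Exception:
            pass
        start[-1] = math.log(0.5)

        res = optimize.minimize(
            negll, start, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        self.converged_ = bool(res.success)
        self.coef_ = res.x[:-1]
        self.log_sigma_ = float(res.x[-1])
        self.sigma_u_ = math.exp(self.log_sigma_)
        self.sigma_u2_ = self.sigma_u_**2
        self.icc_ = icc_logistic(self.sigma_u2_)
        self.llf_ = -res.fun

        H = approx_hess1(res.x, negll)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            self.converged_ = False
        self.cov_ = cov[:-1, :-1]
        self.bse_ = np.sqrt(np.clip(np.diag(self.cov_), 0, None))
        return self

    @property
    def params_(self) -> pd.Series:
        return pd.Series(self.coef_, index=self.feature_names_in_)

    def conf_int_(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"low": self.coef_ - z * self.bse_, "high": self.coef_ + z * self.bse_},
            index=self.feature_names_in_,
        )

    @property
    def pvalues_(self) -> pd.Series:
        z = np.divide(self.coef_, self.bse_, out=np.zeros_like(self.coef_),
                      where=self.bse_ > 0)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.feature_names_in_)


# ---------------------------------------------------------------------------
# linear models for processing time


class WithinGroupOLS(BaseEstimator):
    """Fixed-effects linear regression via the within transformation.

    Demeans outcome and covariates within groups and runs OLS; standard
    errors use the fixed-effects residual degrees of freedom
    n - p - n_groups.
    """

    def fit(self, X, y, groups):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        codes, _ = pd.factorize(np.asarray(groups), sort=True)
        self.n_groups_ = int(codes.max() + 1)
        X, self.dropped_features_ = _drop_group_constant(X, codes)
        if X.shape[1] == 0:
            raise EstimationError("no covariate varies within groups")
        self.feature_names_in_ = list(X.columns)
        Xa = X.to_numpy(dtype=float)
        counts = np.bincount(codes)

        def demean(v):
            means = np.bincount(codes, weights=v) / counts
            return v - means[codes]

        Xd = np.column_stack([demean(Xa[:, j]) for j in range(Xa.shape[1])])
        yd = demean(y)
        n, p = Xd.shape
        df_resid = n - p - self.n_groups_
        if df_resid <= 0:
            raise EstimationError("not enough residual degrees of freedom")
        beta, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        resid = yd - Xd @ beta
        sigma2 = float(resid @ resid) / df_resid
        XtX_inv = np.linalg.pinv(Xd.T @ Xd)
        self.coef_ = beta
        self.cov_ = sigma2 * XtX_inv
        self.bse_ = np.sqrt(np.diag(self.cov_))
        self.df_resid_ = df_resid
        self.nobs_ = n
        self.converged_ = True
        return self

    @property
    def params_(self) -> pd.Series:
        return pd.Series(self.coef_, index=self.feature_names_in_)

    def conf_int_(self, alpha: float = 0.05) -> pd.DataFrame:
        t = stats.t.ppf(1 - alpha / 2, self.df_resid_)
        return pd.DataFrame(
            {"low": self.coef_ - t * self.bse_, "high": self.coef_ + t * self.bse_},
            index=self.feature_names_in_,
        )

    @property
    def pvalues_(self) -> pd.Series:
        tstat = np.divide(self.coef_, self.bse_, out=np.zeros_like(self.coef_),
                          where=self.bse_ > 0)
        return pd.Series(2 * stats.t.sf(np.abs(tstat), self.df_resid_),
                         index=self.feature_names_in_)


# ---------------------------------------------------------------------------
# scalar helpers


def icc_logistic(sigma_u2: float) -> float:
    """Latent-threshold ICC for random-intercept logistic models:
    sigma_u^2 / (sigma_u^2 + pi^2/3)."""
    if sigma_u2 < 0:
        raise ValueError(f"variance must be non-negative, got {sigma_u2}")
    return sigma_u2 / (sigma_u2 + LOGISTIC_LATENT_VARIANCE)


def standardized_odds_effect(result: ModelResult, predictor: str, sd: float) -> dict:
    """Per-SD odds effect of a predictor.

    Reports exp(beta*sd) as the odds ratio for a one-SD increase and
    exp(beta*sd) - 1 as the relative 'increase in odds by X times'.
    """
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    beta = float(result.terms.loc[predictor, "coef"])
    per_sd_or = math.exp(beta * sd)
    return {
        "predictor": predictor,
        "sd": float(sd),
        "beta": beta,
        "per_sd_odds_ratio": per_sd_or,
        "odds_increase_times": per_sd_or - 1.0,
    }


# ---------------------------------------------------------------------------
# table-level fitting helpers


def _result_from_estimator(est, spec_outcome, spec_habit, estimator_name,
                           logistic: bool, n_groups=None, n_dropped=0,
                           sigma_u2=None, icc=None, message="") -> ModelResult:
    ci = est.conf_int_()
    terms = pd.DataFrame({
        "coef": est.params_,
        "se": pd.Series(est.bse_, index=est.feature_names_in_),
        "ci_low": ci["low"],
        "ci_high": ci["high"],
        "pvalue": est.pvalues_,
    })
    if logistic:
        terms["odds_ratio"] = np.exp(terms["coef"])
    return ModelResult(
        outcome=spec_outcome, habit=spec_habit, estimator=estimator_name,
        terms=terms, nobs=est.nobs_,
        n_groups=n_groups if n_groups is not None else getattr(est, "n_groups_", None),
        n_groups_dropped=n_dropped, converged=bool(est.converged_),
        sigma_u2=sigma_u2, icc=icc,
        dropped_terms=list(getattr(est, "dropped_features_", [])),
        message=message,
    )


def _spec_table(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.rank is not None:
        table = table[table["physician_rank"] == spec.rank]
    return table


def fit_fe_logit(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Conditional-ML fixed-effects logistic fit of a binary outcome."""
    t = _spec_table(table, spec)
    X = build_design(t, spec.habit, spec.covariates, add_intercept=False)
    y = t[spec.outcome].to_numpy(dtype=float)
    est = ConditionalLogisticRegression().fit(X, y, t[spec.group])
    return _result_from_estimator(
        est, spec.outcome, spec.habit, "fixed_effects", logistic=True,
        n_groups=est.n_groups_, n_dropped=est.n_groups_dropped_,
    )


def fit_re_logit(table: pd.DataFrame, spec: ModelSpec, n_quad: int = 25) -> ModelResult:
    """Random-intercept logistic fit with latent-threshold ICC."""
    t = _spec_table(table, spec)
    X = build_design(t, spec.habit, spec.covariates, add_intercept=True)
    y = t[spec.outcome].to_numpy(dtype=float)
    est = RandomInterceptLogisticRegression(n_quad=n_quad).fit(X, y, t[spec.group])
    return _result_from_estimator(
        est, spec.outcome, spec.habit, "random_effects", logistic=True,
        sigma_u2=est.sigma_u2_, icc=est.icc_,
    )


def fit_pooled_logit(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Plain (pooled) logistic fit ignoring the grouping."""
    t = _spec_table(table, spec)
    X = build_design(t, spec.habit, spec.covariates, add_intercept=True)
    y = t[spec.outcome].to_numpy(dtype=float)
    model = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0, maxiter=200)
    ci = model.conf_int()
    terms = pd.DataFrame({
        "coef": pd.Series(model.params, index=X.columns),
        "se": pd.Series(model.bse, index=X.columns),
        "ci_low": pd.Series(ci[:, 0], index=X.columns),
        "ci_high": pd.Series(ci[:, 1], index=X.columns),
        "pvalue": pd.Series(model.pvalues, index=X.columns),
    })
    terms["odds_ratio"] = np.exp(terms["coef"])
    return ModelResult(
        outcome=spec.outcome, habit=spec.habit, estimator="pooled",
        terms=terms, nobs=int(model.nobs),
        converged=bool(model.mle_retvals.get("converged", True)),
    )


def fit_logit(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Dispatch on ``spec.estimator``."""
    if spec.estimator == "fixed_effects":
        return fit_fe_logit(table, spec)
    if spec.estimator == "random_effects":
        return fit_re_logit(table, spec)
    if spec.estimator == "pooled":
        return fit_pooled_logit(table, spec)
    raise ValueError(f"unknown estimator {spec.estimator!r}")


def fit_by_rank(table: pd.DataFrame, spec: ModelSpec) -> dict[str, ModelResult]:
    """One fixed-effects fit per physician-rank subsample.

    Strata that cannot be estimated (absent, or too little within-group
    outcome variation) yield a failure record rather than an exception.
    """
    out: dict[str, ModelResult] = {}
    for rank in RANKS:
        sub = table[table["physician_rank"] == rank]
        if len(sub) == 0:
            out[rank] = ModelResult(
                outcome=spec.outcome, habit=spec.habit, estimator="fixed_effects",
                terms=pd.DataFrame(columns=["coef", "se", "ci_low", "ci_high", "pvalue"]),
                nobs=0, n_groups=0, converged=False, message="empty rank stratum",
            )
            continue
        rank_spec = ModelSpec(
            outcome=spec.outcome, habit=spec.habit,
            covariates=[c for c in spec.covariates if c != "physician_rank"],
            estimator="fixed_effects", group=spec.group,
        )
        try:
            out[rank] = fit_fe_logit(sub, rank_spec)
        except (EstimationError, np.linalg.LinAlgError) as exc:
            out[rank] = ModelResult(
                outcome=spec.outcome, habit=spec.habit, estimator="fixed_effects",
                terms=pd.DataFrame(columns=["coef", "se", "ci_low", "ci_high", "pvalue"]),
                nobs=len(sub), n_groups=sub[spec.group].nunique(),
                converged=False, message=f"estimation failed: {exc}",
            )
    return out


def fit_processing_time(
    table: pd.DataFrame,
    estimator: str = "fixed_effects",
    habit: str = "H_0.05",
    covariates: Sequence[str] | None = None,
    group: str = "physician_id",
    log_transform: bool = False,
) -> ModelResult:
    """Linear model of processing time on habit strength and controls.

    ``estimator`` selects fixed_effects (within transformation),
    random_effects (normal random intercept via REML) or pooled OLS;
    ``log_transform`` models log seconds instead of seconds.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES]
    y = table["processing_time"].to_numpy(dtype=float)
    if log_transform:
        if (y <= 0).any():
            raise EstimationError("processing_time must be positive for log transform")
        y = np.log(y)
    outcome = "log_processing_time" if log_transform else "processing_time"

    if estimator == "fixed_effects":
        X = build_design(table, habit, covariates, add_intercept=False)
        est = WithinGroupOLS().fit(X, y, table[group])
        return _result_from_estimator(est, outcome, habit, "fixed_effects", logistic=False)

    X = build_design(table, habit, covariates, add_intercept=True)
    if estimator == "pooled":
        model = sm.OLS(y, X.to_numpy(dtype=float)).fit()
        ci = model.conf_int()
        terms = pd.DataFrame({
            "coef": pd.Series(model.params, index=X.columns),
            "se": pd.Series(model.bse, index=X.columns),
            "ci_low": pd.Series(ci[:, 0], index=X.columns),
            "ci_high": pd.Series(ci[:, 1], index=X.columns),
            "pvalue": pd.Series(model.pvalues, index=X.columns),
        })
        return ModelResult(outcome=outcome, habit=habit, estimator="pooled",
                           terms=terms, nobs=int(model.nobs))
    if estimator == "random_effects":
        model = sm.MixedLM(y, X.to_numpy(dtype=float), groups=table[group]).fit(reml=True)
        names = list(X.columns)
        params = pd.Series(model.fe_params, index=names)
        bse = pd.Series(np.asarray(model.bse)[: len(names)], index=names)
        ci_low = params - 1.96 * bse
        ci_high = params + 1.96 * bse
        z = params / bse
        terms = pd.DataFrame({
            "coef": params, "se": bse, "ci_low": ci_low, "ci_high": ci_high,
            "pvalue": 2 * stats.norm.sf(np.abs(z)),
        })
        sigma_u2 = float(np.asarray(model.cov_re)[0, 0])
        sigma_e2 = float(model.scale)
        return ModelResult(
            outcome=outcome, habit=habit, estimator="random_effects",
            terms=terms, nobs=int(model.nobs),
            n_groups=table[group].nunique(),
            converged=bool(model.converged),
            sigma_u2=sigma_u2, icc=sigma_u2 / (sigma_u2 + sigma_e2),
        )
    raise ValueError(f"unknown estimator {estimator!r}")
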