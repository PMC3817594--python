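"""Maximum-likelihood fitting of Poisson / NB / ZIP / ZINB count models.

All four families share a log link for the count mean; the zero-inflated
families add a logit-linked structural-zero probability pi, with

    P(y = 0) = pi + (1 - pi) f(0),    P(y > 0) = (1 - pi) f(y),

where f is the base pmf.  The negative binomial uses the (mu, theta)
parameterization with variance mu + mu^2 / theta; theta is estimated on the
log scale so it stays positive.

Fitting is quasi-Newton (BFGS with analytic gradients) on the joint negative
log-likelihood.  Zero-inflated and overdispersed fits are multi-started from
their nested special cases (a ZINB start includes the fitted ZIP and NB
solutions), which makes the likelihood-nesting inequalities hold to optimizer
tolerance by construction.  Standard errors come from the inverse of the
numerically evaluated observed-information Hessian; Wald p-values are
two-sided normal and are computed identically for count-part and zero-part
coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from snowcross.synthetic import (
    CountDataset,
    DISPERSED_FAMILIES,
    FAMILIES,
    ZERO_INFLATED_FAMILIES,
)

INTERCEPT = "intercept"

_ETA_CLIP = 30.0
_NEAR_LIMIT_LOG_THETA = 20.0  # theta ~ 5e8: numerically the Poisson limit
_NEAR_LIMIT_LOGIT = -15.0  # pi ~ 3e-7: numerically no zero inflation


@dataclass(frozen=True)
class StandardizationParams:
    """Per-predictor training means and standard deviations."""

    means: pd.Series
    sds: pd.Series

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            bad = self.sds.index[self.sds <= 0].tolist()
            raise ValueError(f"non-positive sd for predictors {bad}")

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name in self.means.index:
            if name not in out.columns:
                raise KeyError(f"missing predictor column {name!r}")
            out[name] = (out[name] - self.means[name]) / self.sds[name]
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name in self.means.index:
            out[name] = out[name] * self.sds[name] + self.means[name]
        return out


def standardize_predictors(
    table: pd.DataFrame,
    params: StandardizationParams | None = None,
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Standardize predictor columns to mean 0, sd 1 (sample sd).

    Without ``params`` this is a training call: means/sds are estimated from
    ``table`` and returned.  With ``params`` the stored training moments are
    applied to new rows.  A constant column is an error (its sd is zero).
    """
    if params is not None:
        return params.apply(table), params
    cols = list(columns) if columns is not None else list(table.columns)
    sub = table[cols]
    means = sub.mean()
    sds = sub.std(ddof=1)
    constant = sds.index[~(sds > 0)].tolist()
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    params = StandardizationParams(means=means, sds=sds)
    return params.apply(table), params


@dataclass(frozen=True)
class CountModelSpec:
    """One model to fit: family plus count-part and zero-part predictors.

    ``zero_predictors`` is ``None`` for poisson/negbin; for zip/zinb it is
    ``()`` for an intercept-only zero part (variant a) or a mirror of the
    count predictors (variant b).
    """

    family: str
    count_predictors: tuple[str, ...] = ()
    zero_predictors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        zero_inflated = self.family in ZERO_INFLATED_FAMILIES
        if zero_inflated and self.zero_predictors is None:
            raise ValueError(f"{self.family} requires zero_predictors (may be empty)")
        if not zero_inflated and self.zero_predictors is not None:
            raise ValueError(f"{self.family} must not have a zero part")

    @property
    def zero_inflated(self) -> bool:
        return self.family in ZERO_INFLATED_FAMILIES

    @property
    def dispersed(self) -> bool:
        return self.family in DISPERSED_FAMILIES

    @property
    def df(self) -> int:
        k = 1 + len(self.count_predictors)
        if self.zero_inflated:
            k += 1 + len(self.zero_predictors or ())
        if self.dispersed:
            k += 1
        return k


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(table))]
    for name in predictors:
        if name not in table.columns:
            raise KeyError(f"missing predictor column {name!r}")
        cols.append(table[name].to_numpy(dtype=float))
    return np.column_stack(cols)


class _Likelihood:
    """Joint negative log-likelihood and analytic gradient for one spec.

    Parameter layout: count-part coefficients, then zero-part coefficients
    (if zero-inflated), then log(theta) (if overdispersed).
    """

    def __init__(self, spec: CountModelSpec, y: np.ndarray, table: pd.DataFrame):
        self.spec = spec
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("response must be non-negative integers")
        self.Xc = _design(table, spec.count_predictors)
        self.Xz = (
            _design(table, spec.zero_predictors or ()) if spec.zero_inflated else None
        )
        self.kc = self.Xc.shape[1]
        self.kz = self.Xz.shape[1] if self.Xz is not None else 0
        self.n_params = self.kc + self.kz + (1 if spec.dispersed else 0)
        self.zero_mask = self.y == 0
        self._lgamma_y1 = special.gammaln(self.y + 1.0)

    # -- helpers -------------------------------------------------------
    def _parts(self, params: np.ndarray):
        beta = params[: self.kc]
        gamma = params[self.kc : self.kc + self.kz] if self.kz else None
        log_theta = params[-1] if self.spec.dispersed else None
        eta = np.clip(self.Xc @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        zeta = (
            np.clip(self.Xz @ gamma, -_ETA_CLIP, _ETA_CLIP)
            if gamma is not None
            else None
        )
        # clamp so theta neither underflows to 0 nor overflows downstream sums
        theta = (
            math.exp(float(np.clip(log_theta, -25.0, 50.0)))
            if log_theta is not None
            else None
        )
        return eta, mu, zeta, theta

    def loglik(self, params: np.ndarray) -> float:
        eta, mu, zeta, theta = self._parts(params)
        y, z0 = self.y, self.zero_mask
        if self.spec.family == "poisson":
            ll = y * eta - mu - self._lgamma_y1
        elif self.spec.family == "negbin":
            ll = self._nb_ll(eta, mu, theta)
        else:
            log_pi = -np.logaddexp(0.0, -zeta)
            log_1mpi = -np.logaddexp(0.0, zeta)
            if self.spec.family == "zip":
                base0 = -mu
                ll_pos = y * eta - mu - self._lgamma_y1
            else:
                base0 = theta * (math.log(theta) - np.log(theta + mu))
                ll_pos = self._nb_ll(eta, mu, theta)
            ll = np.where(
                z0,
                np.logaddexp(log_pi, log_1mpi + base0),
                log_1mpi + ll_pos,
            )
        return float(np.sum(ll))

    def _nb_ll(self, eta, mu, theta):
        y = self.y
        log_t_mu = np.log(theta + mu)
        return (
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - self._lgamma_y1
            + theta * (math.log(theta) - log_t_mu)
            + y * (eta - log_t_mu)
        )

    def nll(self, params: np.ndarray) -> float:
        return -self.loglik(params)

    def grad_nll(self, params: np.ndarray) -> np.ndarray:
        eta, mu, zeta, theta = self._parts(params)
        y, z0 = self.y, self.zero_mask
        d_eta = np.zeros_like(y)
        d_zeta = None
        d_log_theta = 0.0

        if self.spec.family == "poisson":
            d_eta = y - mu
        elif self.spec.family == "negbin":
            d_eta = (y - mu) * theta / (theta + mu)
            d_log_theta = theta * float(np.sum(self._nb_dtheta(mu, theta)))
        else:
            pi = special.expit(zeta)
            log_pi = -np.logaddexp(0.0, -zeta)
            log_1mpi = -np.logaddexp(0.0, zeta)
            if self.spec.family == "zip":
                base0 = -mu
            else:
                base0 = theta * (math.log(theta) - np.log(theta + mu))
            ll0 = np.logaddexp(log_pi, log_1mpi + base0)
            # (1-pi) f(0) / P(0), computed in log space
            w0 = np.exp(log_1mpi + base0 - ll0)
            # pi (1-pi) (1 - f(0)) / P(0)
            dz0 = np.exp(log_pi + log_1mpi - ll0) * (-np.expm1(base0))
            d_zeta = np.where(z0, dz0, -pi)
            if self.spec.family == "zip":
                d_eta = np.where(z0, -mu * w0, y - mu)
            else:
                d_eta = np.where(
                    z0,
                    w0 * (-theta * mu / (theta + mu)),
                    (y - mu) * theta / (theta + mu),
                )
                dth_pos = self._nb_dtheta(mu, theta)
                dth0 = w0 * (math.log(theta) - np.log(theta + mu) + mu / (theta + mu))
                d_log_theta = theta * float(np.sum(np.where(z0, dth0, dth_pos)))

        grad = [-(self.Xc.T @ d_eta)]
        if d_zeta is not None:
            grad.append(-(self.Xz.T @ d_zeta))
        if self.spec.dispersed:
            grad.append(np.array([-d_log_theta]))
        return np.concatenate(grad)

    def _nb_dtheta(self, mu, theta):
        """d loglik_i / d theta for the plain NB part (per observation)."""
        y = self.y
        return (
            special.digamma(y + theta)
            - special.digamma(theta)
            + math.log(theta)
            - np.log(theta + mu)
            + 1.0
            - (theta + y) / (theta + mu)
        )


@dataclass
class FittedCountModel:
    """ML fit of one :class:`CountModelSpec`."""

    spec: CountModelSpec
    params: np.ndarray
    count_coef: dict[str, float]
    zero_coef: dict[str, float]
    theta: float | None
    count_se: dict[str, float]
    zero_se: dict[str, float]
    theta_se: float | None
    count_p: dict[str, float]
    zero_p: dict[str, float]
    log_likelihood: float
    df: int
    n: int
    converged: bool
    boundary: bool = False
    message: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.df - 2.0 * self.log_likelihood

    def aicc(self, n: int | None = None) -> float:
        n = self.n if n is None else n
        if n <= self.df + 1:
            return math.nan
        return self.aic + 2.0 * self.df * (self.df + 1) / (n - self.df - 1)

    # -- prediction ----------------------------------------------------
    def _mu(self, table: pd.DataFrame) -> np.ndarray:
        X = _design(table, self.spec.count_predictors)
        beta = np.array(
            [self.count_coef[INTERCEPT]]
            + [self.count_coef[p] for p in self.spec.count_predictors]
        )
        return np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))

    def _pi(self, table: pd.DataFrame) -> np.ndarray | None:
        if not self.spec.zero_inflated:
            return None
        X = _design(table, self.spec.zero_predictors or ())
        gamma = np.array(
            [self.zero_coef[INTERCEPT]]
            + [self.zero_coef[p] for p in self.spec.zero_predictors or ()]
        )
        return special.expit(np.clip(X @ gamma, -_ETA_CLIP, _ETA_CLIP))

    def predict_mean(self, table: pd.DataFrame) -> np.ndarray:
        """Expected count per row: mu, times (1 - pi) when zero-inflated."""
        mu = self._mu(table)
        pi = self._pi(table)
        return mu if pi is None else (1.0 - pi) * mu

    def pmf(self, y: np.ndarray, table: pd.DataFrame) -> np.ndarray:
        """Predicted probability of the observed counts, per row."""
        y = np.asarray(y)
        mu = self._mu(table)
        if self.spec.family == "poisson":
            base = stats.poisson.pmf(y, mu)
        elif self.spec.family in {"negbin", "zinb"}:
            base = stats.nbinom.pmf(y, self.theta, self.theta / (self.theta + mu))
        else:
            base = stats.poisson.pmf(y, mu)
        pi = self._pi(table)
        if pi is None:
            return base
        return np.where(y == 0, pi + (1 - pi) * base, (1 - pi) * base)

    def prob_zero(self, table: pd.DataFrame) -> np.ndarray:
        return self.pmf(np.zeros(len(table), dtype=int), table)

    def coefficients(self) -> pd.DataFrame:
        """Tidy coefficient table (part, name, estimate, se, p)."""
        rows = []
        for name in [INTERCEPT, *self.spec.count_predictors]:
            rows.append(
                {
                    "part": "count",
                    "name": name,
                    "estimate": self.count_coef[name],
                    "se": self.count_se.get(name, math.nan),
                    "p": self.count_p.get(name, math.nan),
                }
            )
        if self.spec.zero_inflated:
            for name in [INTERCEPT, *(self.spec.zero_predictors or ())]:
                rows.append(
                    {
                        "part": "zero",
                        "name": name,
                        "estimate": self.zero_coef[name],
                        "se": self.zero_se.get(name, math.nan),
                        "p": self.zero_p.get(name, math.nan),
                    }
                )
        if self.theta is not None:
            rows.append(
                {
                    "part": "dispersion",
                    "name": "theta",
                    "estimate": self.theta,
                    "se": self.theta_se if self.theta_se is not None else math.nan,
                    "p": math.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "count_predictors": list(self.spec.count_predictors),
            "zero_predictors": (
                list(self.spec.zero_predictors)
                if self.spec.zero_predictors is not None
                else None
            ),
            "count_coef": self.count_coef,
            "zero_coef": self.zero_coef,
            "theta": self.theta,
            "log_likelihood": self.log_likelihood,
            "df": self.df,
            "n": self.n,
            "aic": self.aic,
            "aicc": self.aicc(),
            "converged": self.converged,
            "boundary": self.boundary,
        }


def _minimize(lik: _Likelihood, start: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            lik.nll,
            start,
            jac=lik.grad_nll,
            method="BFGS",
            options={"maxiter": 300, "gtol": 1e-7},
        )
        if not res.success:
            res2 = optimize.minimize(
                lik.nll,
                res.x,
                jac=lik.grad_nll,
                method="L-BFGS-B",
                options={"maxiter": 500},
            )
            if res2.fun <= res.fun:
                res = res2
    return res


def _poisson_start(lik: _Likelihood) -> np.ndarray:
    beta = np.zeros(lik.kc)
    beta[0] = math.log(max(lik.y.mean(), 1e-3))
    return beta


def _fit_internal(spec: CountModelSpec, y: np.ndarray, table: pd.DataFrame):
    """Fit and return (likelihood object, best optimizer result)."""
    lik = _Likelihood(spec, y, table)
    starts: list[np.ndarray] = []
    ybar = max(float(lik.y.mean()), 1e-3)
    yvar = float(lik.y.var(ddof=1)) if len(lik.y) > 1 else ybar
    zero_frac = float(np.mean(lik.zero_mask))

    if spec.family == "poisson":
        starts.append(_poisson_start(lik))
    elif spec.family == "negbin":
        base = _fit_internal(
            CountModelSpec("poisson", spec.count_predictors), y, table
        )[1].x
        excess = max(yvar - ybar, 1e-6)
        theta_mom = np.clip(ybar**2 / excess, 1e-3, 1e8)
        starts.append(np.concatenate([base, [math.log(theta_mom)]]))
        # near-Poisson limit: guarantees ll(NB) >= ll(Poisson) - eps
        starts.append(np.concatenate([base, [_NEAR_LIMIT_LOG_THETA]]))
    elif spec.family == "zip":
        base = _fit_internal(
            CountModelSpec("poisson", spec.count_predictors), y, table
        )[1].x
        gamma = np.zeros(lik.kz)
        p0 = math.exp(-ybar)
        pi0 = np.clip((zero_frac - p0) / max(1.0 - p0, 1e-6), 0.02, 0.95)
        gamma[0] = special.logit(pi0)
        adj = base.copy()
        adj[0] -= math.log(1.0 - pi0)
        starts.append(np.concatenate([adj, gamma]))
        near = np.zeros(lik.kz)
        near[0] = _NEAR_LIMIT_LOGIT
        starts.append(np.concatenate([base, near]))
    else:  # zinb
        nb_lik, nb_res = _fit_internal(
            CountModelSpec("negbin", spec.count_predictors), y, table
        )
        zip_lik, zip_res = _fit_internal(
            CountModelSpec("zip", spec.count_predictors, spec.zero_predictors),
            y,
            table,
        )
        near = np.zeros(lik.kz)
        near[0] = _NEAR_LIMIT_LOGIT
        # from the NB optimum with a negligible zero-inflation part
        starts.append(
            np.concatenate([nb_res.x[:-1], near, [nb_res.x[-1]]])
        )
        # from the ZIP optimum in the near-Poisson dispersion limit
        starts.append(np.concatenate([zip_res.x, [_NEAR_LIMIT_LOG_THETA]]))
        # moment start
        excess = max(yvar - ybar, 1e-6)
        theta_mom = np.clip(ybar**2 / excess, 1e-3, 1e8)
        gamma = np.zeros(lik.kz)
        gamma[0] = special.logit(np.clip(zero_frac, 0.02, 0.95))
        beta = np.zeros(lik.kc)
        beta[0] = math.log(ybar / max(1.0 - zero_frac, 0.05))
        starts.append(np.concatenate([beta, gamma, [math.log(theta_mom)]]))

    best = None
    for start in starts:
        res = _minimize(lik, start)
        if best is None or res.fun < best.fun:
            best = res
    return lik, best


def fit(spec: CountModelSpec, data: CountDataset) -> FittedCountModel:
    """Fit one count model by maximum likelihood.

    ``data.predictors`` must contain every predictor named in the spec
    (normally already standardized).  Non-convergence is reported via
    ``converged=False`` rather than raised; boundary solutions (dispersion at
    the Poisson limit, zero-inflation probability at 0/1, e.g. for an all-zero
    response) are flagged.
    """
    y = np.asarray(data.counts)
    table = data.predictors
    n = len(y)
    if n < spec.df + 1:
        raise ValueError(f"need at least {spec.df + 1} rows to fit {spec.df} parameters")

    lik, res = _fit_internal(spec, y, table)
    params = res.x
    ll = -float(res.fun)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            hess = numdiff.approx_hess(params, lik.nll)
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            se[np.diag(cov) <= 0] = np.nan
        except np.linalg.LinAlgError:
            se = np.full(lik.n_params, np.nan)

    zvals = np.abs(params) / np.where(se > 0, se, np.nan)
    pvals = 2.0 * stats.norm.sf(zvals)

    count_names = [INTERCEPT, *spec.count_predictors]
    zero_names = [INTERCEPT, *(spec.zero_predictors or ())] if spec.zero_inflated else []
    kc, kz = lik.kc, lik.kz
    count_coef = dict(zip(count_names, params[:kc].tolist()))
    count_se = dict(zip(count_names, se[:kc].tolist()))
    count_p = dict(zip(count_names, pvals[:kc].tolist()))
    zero_coef = dict(zip(zero_names, params[kc : kc + kz].tolist()))
    zero_se = dict(zip(zero_names, se[kc : kc + kz].tolist()))
    zero_p = dict(zip(zero_names, pvals[kc : kc + kz].tolist()))

    theta = theta_se = None
    boundary = False
    if spec.dispersed:
        log_theta = float(np.clip(params[-1], -25.0, 50.0))
        theta = math.exp(log_theta)
        if np.isfinite(se[-1]):
            theta_se = theta * float(se[-1])  # delta method from log scale
        boundary = boundary or log_theta > _NEAR_LIMIT_LOG_THETA - 2
    if spec.zero_inflated:
        boundary = boundary or max(abs(v) for v in zero_coef.values()) > 12

    return FittedCountModel(
        spec=spec,
        params=params,
        count_coef=count_coef,
        zero_coef=zero_coef,
        theta=theta,
        count_se=count_se,
        zero_se=zero_se,
        theta_se=theta_se,
        count_p=count_p,
        zero_p=zero_p,
        log_likelihood=ll,
        df=spec.df,
        n=n,
        converged=bool(res.success or np.linalg.norm(lik.grad_nll(params)) < 1e-3 * n),
        boundary=boundary,
        message=str(res.message),
    )


@dataclass(frozen=True)
class InformationCriteria:
    aic: float
    aicc: float
    aicc_defined: bool


def information_criteria(
    log_likelihood: float, df: int, n: int | None = None
) -> InformationCriteria:
    """AIC = 2 df - 2 l; AICc adds the small-sample correction 2 df (df+1)/(n-df-1).

    With ``n`` omitted or ``n <= df + 1`` the AICc is undefined and flagged
    (NaN) rather than raised.
    """
    aic = 2.0 * df - 2.0 * log_likelihood
    if n is None or n <= df + 1:
        return InformationCriteria(aic=aic, aicc=math.nan, aicc_defined=False)
    aicc = aic + 2.0 * df * (df + 1) / (n - df - 1)
    return InformationCriteria(aic=aic, aicc=aicc, aicc_defined=True)


def predicted_zeros(model: FittedCountModel, data: CountDataset) -> int:
    """Expected number of zero counts under the fitted model, rounded."""
    if not model.converged:
        raise ValueError("predicted_zeros requires a converged model")
    if data.n == 0:
        return 0
    return int(round(float(np.sum(model.prob_zero(data.predictors)))))
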