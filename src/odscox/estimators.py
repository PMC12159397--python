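"""Scikit-learn style estimators for (weighted) Cox regression under
outcome-dependent sampling.

Three estimators are provided, all ``sklearn.base.BaseEstimator`` subclasses
with ``fit`` / ``predict`` (linear predictor) and trailing-underscore fitted
attributes, so they compose with sklearn pipelines and model selection:

``WeightedCoxPH``
    Cox proportional hazards by (weighted) partial likelihood; per-subject
    selection weights go in through ``fit(..., sample_weight=)``.  Reports both
    the model-based SE (observed information; the right choice for unit
    weights) and the Huber–White sandwich SE (the right choice for weighted
    fits).

``IPSWeightedCoxPH``
    The full inverse-probability-of-selection pipeline: given an external
    incidence-rate table, it aggregates the sample into interval counts,
    computes traditional or generalized weights, and fits the weighted model
    with robust SEs.  Refuses invalid traditional weight sets.

``SharedFrailtyCoxPH``
    Unweighted Cox model with a family-shared gamma frailty, used as a
    sensitivity analysis for unobserved within-family heterogeneity.

The survival outcome ``y`` is a structured array with fields ``"event"``
(bool/int) and ``"time"`` (float), as in scikit-survival; :func:`surv_array`
builds one.  Module-level helpers ``fit_cox`` / ``fit_weighted_cox`` /
``fit_shared_frailty`` wrap the estimators for subject DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from . import weights as _weights
from .cox import cox_newton
from .frailty import fit_gamma_frailty
from .intervals import IntervalTable, aggregate_counts

__all__ = [
    "FitResult",
    "surv_array",
    "WeightedCoxPH",
    "IPSWeightedCoxPH",
    "SharedFrailtyCoxPH",
    "fit_cox",
    "fit_weighted_cox",
    "fit_shared_frailty",
]


def surv_array(status, time) -> np.ndarray:
    """Pack event indicators and times into a structured survival outcome."""
    status = np.asarray(status)
    time = np.asarray(time, float)
    y = np.empty(time.size, dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = status.astype(bool)
    y["time"] = time
    return y


def _unpack_y(y):
    if isinstance(y, tuple):
        status, time = y
        return np.asarray(status).astype(bool), np.asarray(time, float)
    y = np.asarray(y)
    if y.dtype.names and {"event", "time"} <= set(y.dtype.names):
        return y["event"].astype(bool), y["time"].astype(float)
    raise ValueError(
        "y must be a structured array with fields 'event' and 'time' "
        "(see surv_array) or an (status, time) tuple"
    )


@dataclass
class FitResult:
    """Summary of one Cox fit: the log-hazard ratio, its SEs and 95% CI."""

    beta_hat: float
    se_model: float | None
    se_robust: float | None
    ci_low: float
    ci_high: float
    method: str
    converged: bool
    n_iter: int
    frailty_var: float | None = None

    @property
    def se(self) -> float:
        """The SE the method reports on: robust if available, else model-based."""
        return self.se_robust if self.se_robust is not None else self.se_model

    def to_dict(self) -> dict:
        return asdict(self)


class WeightedCoxPH(BaseEstimator):
    """Cox proportional hazards model fitted by weighted partial likelihood.

    Parameters
    ----------
    alpha : float
        Two-sided level for the confidence interval (default 0.05 → 95% CI).
    weight_events : bool
        Carry the selection weight on the event terms of the score (the
        weighted-partial-likelihood convention, default) or only on the
        risk-set sums.
    cluster_by : {"subject", "group"}
        Aggregation unit of the sandwich middle term; "group" sums score
        residuals within the families passed as ``groups`` to :meth:`fit`.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        weight_events: bool = True,
        cluster_by: str = "subject",
        max_iter: int = 50,
        tol: float = 1e-9,
    ):
        self.alpha = alpha
        self.weight_events = weight_events
        self.cluster_by = cluster_by
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, sample_weight=None, groups=None):
        status, time = _unpack_y(y)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        cluster = None
        if self.cluster_by == "group":
            if groups is None:
                raise ValueError("cluster_by='group' requires groups in fit()")
            cluster = groups
        res = cox_newton(
            X,
            time,
            status,
            weights=sample_weight,
            cluster=cluster,
            weight_events=self.weight_events,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.coef_ = res.beta
        self.se_model_ = np.sqrt(np.diag(res.var_model))
        self.se_robust_ = np.sqrt(np.diag(res.var_robust))
        self.loglik_ = res.loglik
        self.score_residual_norm_ = float(np.max(np.abs(res.score)))
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.separated_ = res.separated
        self.weighted_ = sample_weight is not None
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard)."""
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def result(self, index: int = 0) -> FitResult:
        se = self.se_robust_[index] if self.weighted_ else self.se_model_[index]
        z = norm.ppf(1 - self.alpha / 2)
        b = float(self.coef_[index])
        return FitResult(
            beta_hat=b,
            se_model=float(self.se_model_[index]),
            se_robust=float(self.se_robust_[index]) if self.weighted_ else None,
            ci_low=b - z * se,
            ci_high=b + z * se,
            method="weighted" if self.weighted_ else "unweighted",
            converged=self.converged_,
            n_iter=self.n_iter_,
        )


class IPSWeightedCoxPH(BaseEstimator):
    """Inverse-probability-of-selection weighted Cox model.

    Builds per-interval weights from an external incidence-rate grid
    (``scheme="generalized"`` or ``"traditional"``), assigns per-subject
    weights, and fits the weighted partial likelihood with sandwich SEs.

    Parameters
    ----------
    intervals : IntervalTable or (breaks, rates) tuple
    scheme : {"generalized", "traditional"}
    right_closed_last : bool
        Allow observed times exactly at the last break (administrative end of
        follow-up) into the final interval.
    """

    def __init__(
        self,
        intervals=None,
        scheme: str = "generalized",
        alpha: float = 0.05,
        weight_events: bool = True,
        cluster_by: str = "subject",
        right_closed_last: bool = False,
    ):
        self.intervals = intervals
        self.scheme = scheme
        self.alpha = alpha
        self.weight_events = weight_events
        self.cluster_by = cluster_by
        self.right_closed_last = right_closed_last

    def _table(self) -> IntervalTable:
        if isinstance(self.intervals, IntervalTable):
            return self.intervals
        if self.intervals is None:
            raise ValueError("intervals must be provided")
        breaks, rates = self.intervals
        return IntervalTable(np.asarray(breaks, float), np.asarray(rates, float))

    def fit(self, X, y, groups=None):
        status, time = _unpack_y(y)
        table = self._table()
        counts = aggregate_counts(
            time, status, table, right_closed_last=self.right_closed_last
        )
        if self.scheme == "generalized":
            ws = _weights.generalized_weights(counts, table)
        elif self.scheme == "traditional":
            ws = _weights.weighted_cohort_weights(counts, table)
            if not ws.valid:
                conds = sorted({(k, c) for k, c, _ in ws.violations})
                raise _weights.WeightValidityError(
                    f"traditional weighted-cohort weights are invalid (negative "
                    f"or undefined weights); violations: {conds}"
                )
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        w_subj = _weights.subject_weights(
            ws, table, time, status, right_closed_last=self.right_closed_last
        )
        self.weight_set_ = ws
        self.counts_ = counts
        self.sample_weight_ = w_subj
        self._inner = WeightedCoxPH(
            alpha=self.alpha,
            weight_events=self.weight_events,
            cluster_by=self.cluster_by,
        ).fit(X, y, sample_weight=w_subj, groups=groups)
        self.coef_ = self._inner.coef_
        self.se_model_ = self._inner.se_model_
        self.se_robust_ = self._inner.se_robust_
        self.converged_ = self._inner.converged_
        self.n_iter_ = self._inner.n_iter_
        self.n_features_in_ = self._inner.n_features_in_
        return self

    def predict(self, X):
        return self._inner.predict(X)

    def result(self, index: int = 0) -> FitResult:
        res = self._inner.result(index)
        res.method = self.scheme
        return res


class SharedFrailtyCoxPH(BaseEstimator):
    """Unweighted Cox model with a family-shared gamma frailty (mean 1,
    variance ``theta``), profiled out by EM unless ``theta`` is fixed."""

    def __init__(self, alpha: float = 0.05, theta=None, theta_max: float = 20.0):
        self.alpha = alpha
        self.theta = theta
        self.theta_max = theta_max

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("SharedFrailtyCoxPH requires family labels via groups=")
        status, time = _unpack_y(y)
        res = fit_gamma_frailty(
            X, time, status, groups, theta=self.theta, theta_max=self.theta_max
        )
        self.coef_ = res.beta
        self.frailty_variance_ = res.theta
        self.se_model_ = np.sqrt(np.diag(res.var_model))
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.boundary_ = res.boundary
        self.identifiable_ = res.identifiable
        self.n_iter_ = res.n_iter
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def result(self, index: int = 0) -> FitResult:
        z = norm.ppf(1 - self.alpha / 2)
        b = float(self.coef_[index])
        se = float(self.se_model_[index])
        return FitResult(
            beta_hat=b,
            se_model=se,
            se_robust=None,
            ci_low=b - z * se,
            ci_high=b + z * se,
            method="frailty",
            converged=self.converged_,
            n_iter=self.n_iter_,
            frailty_var=float(self.frailty_variance_),
        )


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators, for subject DataFrames
# ---------------------------------------------------------------------------

_COVARIATE_COLS = ("covariate",)


def _xy_from_frame(subjects: pd.DataFrame):
    cov_cols = [c for c in subjects.columns if c == "covariate" or c.startswith("covariate")]
    if not cov_cols:
        raise ValueError("subject table has no 'covariate' column")
    X = subjects[cov_cols].to_numpy(float)
    y = surv_array(subjects["status"].to_numpy(), subjects["time"].to_numpy(float))
    return X, y


def fit_cox(subjects: pd.DataFrame) -> FitResult:
    """Unweighted Cox fit (model-based SE) on a subject table."""
    X, y = _xy_from_frame(subjects)
    return WeightedCoxPH().fit(X, y).result()


def fit_weighted_cox(subjects: pd.DataFrame, sample_weight) -> FitResult:
    """Weighted Cox fit with sandwich SE, given per-subject weights."""
    X, y = _xy_from_frame(subjects)
    return WeightedCoxPH().fit(X, y, sample_weight=sample_weight).result()


def fit_shared_frailty(subjects: pd.DataFrame) -> FitResult:
    """Shared gamma frailty fit using the ``family_id`` column."""
    X, y = _xy_from_frame(subjects)
    return SharedFrailtyCoxPH().fit(X, y, groups=subjects["family_id"].to_numpy()).result()
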