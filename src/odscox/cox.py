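"""Weighted Cox partial-likelihood estimation with robust (sandwich) variance.

The estimator solves the weighted score equation

.. math::

    U(\\beta) = \\sum_{ij:\\,\\delta_{ij}=1} W_{ij}\\Bigl[ z_{ij}
        - \\frac{\\sum_{l \\in R(t_{ij})} W_l z_l e^{\\beta' z_l}}
               {\\sum_{l \\in R(t_{ij})} W_l e^{\\beta' z_l}} \\Bigr] = 0,
    \\qquad R(t) = \\{l : t \\le t_l\\},

i.e. the score of the Breslow-ties weighted partial likelihood with externally
supplied, fixed selection weights ``W``.  Setting ``weight_events=False`` drops
the leading ``W_ij`` so that only the risk-set sums are weighted; both variants
are consistent under selection that is conditionally independent of the
covariate given the observed time, and the weighted-event form is the
convention of the weighted-cohort literature (and of ``coxph`` with case
weights), so it is the default.

Everything is vectorized: risk-set sums are suffix cumsums over the
time-ordered sample, so one Newton iteration costs O(n) after an O(n log n)
sort.  This keeps Monte Carlo studies with tens of thousands of fits cheap.

Standard errors: ``se_model`` is the inverse observed information (appropriate
for unit weights); ``se_robust`` is the Huber–White sandwich
:math:`A^{-1} B A^{-1}` built from per-subject weighted score residuals,
optionally summed within clusters (families) first.  The weights are treated as
fixed in the variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxNewtonResult", "cox_newton", "ConvergenceError"]

_SEPARATION_BOUND = 50.0  # |beta| beyond this on a standardized covariate means separation


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxNewtonResult:
    beta: np.ndarray
    var_model: np.ndarray       # inverse observed information A^{-1}
    var_robust: np.ndarray      # sandwich A^{-1} B A^{-1}
    loglik: float
    score: np.ndarray           # U(beta) at the solution
    n_iter: int
    converged: bool
    separated: bool


def _prepare(x, time, status, weights):
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1 and x.shape[1] != 1:
        x = x.T
    t = np.asarray(time, float).ravel()
    d = np.asarray(status).ravel().astype(bool)
    n = t.size
    if x.shape[0] != n:
        x = x.reshape(n, -1)
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float).ravel()
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be strictly positive and finite")
    if not d.any():
        raise ValueError("no events in the sample; the partial likelihood is empty")
    order = np.argsort(t, kind="stable")
    return x[order], t[order], d[order], w[order], order


def _risk_boundaries(t_sorted):
    """For each subject i (ascending time), the first index of its own risk set
    R(t_i) = {l : t_l >= t_i}, i.e. the first index with equal time."""
    return np.searchsorted(t_sorted, t_sorted, side="left")


def _suffix_cumsum(a):
    return np.cumsum(a[::-1], axis=0)[::-1]


def cox_newton(
    x,
    time,
    status,
    weights=None,
    *,
    cluster=None,
    weight_events: bool = True,
    max_iter: int = 50,
    tol: float = 1e-9,
    init=None,
    offset=None,
):
    """Solve the weighted Cox score equation by Newton–Raphson with step-halving.

    Parameters
    ----------
    x : array-like, shape (n,) or (n, p)
        Covariates.
    time, status : array-like, shape (n,)
        Observed times and event indicators (1 = event).
    weights : array-like, shape (n,), optional
        Strictly positive per-subject selection weights ``W_ij``; default 1.
    cluster : array-like, shape (n,), optional
        Cluster (e.g. family) labels; score residuals are summed within
        clusters before forming the sandwich middle term.
    weight_events : bool
        Weight the event terms of the score (standard weighted partial
        likelihood) or only the risk-set sums (the literal estimating-equation
        form).
    offset : array-like, shape (n,), optional
        Known additive term on the log-risk scale (e.g. log-frailty).
    """
    x_s, t_s, d_s, w_s, order = _prepare(x, time, status, weights)
    n, p = x_s.shape
    start = _risk_boundaries(t_s)
    ew = w_s if weight_events else np.ones(n)  # event-term weights
    off_s = np.zeros(n) if offset is None else np.asarray(offset, float).ravel()[order]

    beta = np.zeros(p) if init is None else np.asarray(init, float).ravel().copy()

    def loglik_score_info(beta):
        eta = x_s @ beta + off_s
        eta = eta - eta.max()  # guard overflow; constants cancel in the ratios
        rw = w_s * np.exp(eta)
        S0 = _suffix_cumsum(rw)                      # shape (n,)
        S1 = _suffix_cumsum(rw[:, None] * x_s)       # (n, p)
        S2 = _suffix_cumsum(rw[:, None, None] * (x_s[:, :, None] * x_s[:, None, :]))
        s0 = S0[start][d_s]
        s1 = S1[start][d_s]
        s2 = S2[start][d_s]
        we = ew[d_s]
        zbar = s1 / s0[:, None]
        ll = float(np.sum(we * (eta[d_s] - np.log(s0))))
        U = (we[:, None] * (x_s[d_s] - zbar)).sum(axis=0)
        A = np.einsum("e,eij->ij", we, s2 / s0[:, None, None]) - np.einsum(
            "e,ei,ej->ij", we, zbar, zbar
        )
        return ll, U, A

    ll, U, A = loglik_score_info(beta)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(A, U)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halving on the log partial likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, U_new, A_new = loglik_score_info(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, U, A = cand, ll_new, U_new, A_new
        if np.max(np.abs(factor * step)) < tol:
            converged = True
            break
    sd_x = np.std(x_s, axis=0)
    if np.any(np.abs(beta) * np.maximum(sd_x, 1e-12) > _SEPARATION_BOUND):
        separated = True
        converged = False

    try:
        var_model = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        var_model = np.full((p, p), np.nan)
        separated = True

    var_robust = _sandwich(x_s, t_s, d_s, w_s, ew, beta, var_model, start, cluster, order, off_s)
    return CoxNewtonResult(
        beta=beta,
        var_model=var_model,
        var_robust=var_robust,
        loglik=ll,
        score=U,
        n_iter=it,
        converged=converged and not separated,
        separated=separated,
    )


def _sandwich(x_s, t_s, d_s, w_s, ew, beta, var_model, start, cluster, order, off_s):
    """Huber–White middle term from per-subject weighted score residuals.

    With ``dLambda(t_j) = ew_j / S0(t_j)`` at each event time, subject i's
    residual is

        U_i = W_i [ delta_i (x_i - zbar(t_i)) ] * (ew_i/W_i)
              - W_i e^{x_i beta} sum_{t_j <= t_i, delta_j=1} (ew_j / S0(t_j)) (x_i - zbar(t_j))

    (with weight_events the first factor is W_i itself).  Residuals are summed
    within clusters if given.
    """
    n, p = x_s.shape
    eta = x_s @ beta + off_s
    eta = eta - eta.max()
    rw = w_s * np.exp(eta)
    S0 = _suffix_cumsum(rw)
    S1 = _suffix_cumsum(rw[:, None] * x_s)
    s0_all = S0[start]
    zbar_all = S1[start] / s0_all[:, None]
    # prefix sums over event times <= t_i (ties included: subject i belongs to
    # the risk set of an event at its own time)
    incr0 = np.where(d_s, ew / s0_all, 0.0)
    incr1 = np.where(d_s[:, None], (ew / s0_all)[:, None] * zbar_all, 0.0)
    # events share the value at the last index of a tie block
    G0 = np.cumsum(incr0)
    G1 = np.cumsum(incr1, axis=0)
    # map each subject to the last index with time <= t_i
    last = np.searchsorted(t_s, t_s, side="right") - 1
    G0_i = G0[last]
    G1_i = G1[last]
    resid = (
        np.where(d_s, ew, 0.0)[:, None] * (x_s - zbar_all)
        - rw[:, None] * (x_s * G0_i[:, None] - G1_i)
    )
    if cluster is not None:
        cl = np.asarray(cluster).ravel()[order]
        _, inv = np.unique(cl, return_inverse=True)
        agg = np.zeros((inv.max() + 1, p))
        np.add.at(agg, inv, resid)
        resid = agg
    B = resid.T @ resid
    return var_model @ B @ var_model
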