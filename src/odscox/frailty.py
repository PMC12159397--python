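"""Semiparametric shared gamma frailty Cox model via EM / profile likelihood.

The model is ``lambda_ij(t) = u_j lambda_0(t) exp(beta' z_ij)`` with family
frailties ``u_j ~ Gamma(shape 1/theta, scale theta)`` (mean 1, variance
``theta``), shared by all members of family ``j``.  For fixed ``theta`` the
classical EM iteration applies: given the current ``(beta, Lambda_0)``, the
posterior frailty means are

    E[u_j | data] = (1/theta + D_j) / (1/theta + Lambda_j),

with ``D_j`` the family's event count and ``Lambda_j = sum_i Lambda_0(t_ij)
exp(beta' z_ij)`` its accumulated hazard; the M-step refits the Cox model with
``log E[u_j]`` as an offset and updates the Breslow baseline.  ``theta`` is
estimated by maximizing the profile of the marginal log-likelihood

    l(theta) = sum_j [ log G(1/theta + D_j) - log G(1/theta) + D_j log theta
               - (1/theta + D_j) log(1 + theta Lambda_j)
               + sum_{i in j: event} (log dLambda_0(t_ij) + beta' z_ij) ],

which is the target of penalized-likelihood implementations of the gamma
frailty Cox model as well.  ``theta`` estimates squeezed against the lower
search bound are flagged as boundary solutions (no within-family
heterogeneity); samples in which every family contributes a single member
cannot identify ``theta`` and are flagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .cox import cox_newton

__all__ = ["FrailtyFitResult", "fit_gamma_frailty"]

_THETA_FLOOR = 1e-5


@dataclass
class FrailtyFitResult:
    beta: np.ndarray
    theta: float
    var_model: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool          # theta squeezed against zero
    identifiable: bool      # False when every family has a single member


def _breslow(x, t, d, beta, u_subject):
    """Breslow baseline under risk multipliers ``u``; returns per-subject
    ``Lambda_0(t_i)`` and the baseline jump at each event (nan elsewhere)."""
    order = np.argsort(t, kind="stable")
    xs, ts, ds, us = x[order], t[order], d[order], u_subject[order]
    risk = us * np.exp(xs @ beta)
    S0 = np.cumsum(risk[::-1])[::-1]
    start = np.searchsorted(ts, ts, side="left")
    incr = np.where(ds, 1.0 / S0[start], 0.0)
    cum = np.cumsum(incr)
    last = np.searchsorted(ts, ts, side="right") - 1
    Lam0 = cum[last]
    jump = np.where(ds, incr, np.nan)
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return Lam0[inv], jump[inv]


def _em_at_theta(x, t, d, ginv, n_g, theta, *, max_iter=100, tol=1e-7, beta0=None):
    """EM for fixed theta.  Returns (beta, profile marginal loglik, n_iter, converged)."""
    a = 1.0 / theta
    D = np.bincount(ginv, weights=d.astype(float), minlength=n_g)
    u = np.ones(n_g)
    beta = np.zeros(x.shape[1]) if beta0 is None else np.asarray(beta0, float).copy()
    ll_marg = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        res = cox_newton(x, t, d, offset=np.log(u)[ginv], init=beta)
        beta = res.beta
        Lam0, jump = _breslow(x, t, d, beta, u[ginv])
        Lam_g = np.bincount(ginv, weights=Lam0 * np.exp(x @ beta), minlength=n_g)
        u_new = (a + D) / (a + Lam_g)
        ll_new = float(
            np.sum(
                gammaln(a + D) - gammaln(a) + D * np.log(theta)
                - (a + D) * np.log1p(theta * Lam_g)
            )
            + np.sum(np.log(jump[d.astype(bool)]))
            + np.sum((x @ beta)[d.astype(bool)])
        )
        if abs(ll_new - ll_marg) < tol and np.max(np.abs(u_new - u)) < 1e-6:
            u, ll_marg = u_new, ll_new
            converged = True
            break
        u, ll_marg = u_new, ll_new
    return beta, ll_marg, it, converged


def fit_gamma_frailty(
    x,
    time,
    status,
    groups,
    *,
    theta=None,
    theta_max: float = 20.0,
    max_iter: int = 100,
    tol: float = 1e-7,
):
    """Fit the shared gamma frailty Cox model.

    Parameters
    ----------
    x : array-like, shape (n,) or (n, p)
    time, status : array-like, shape (n,)
    groups : array-like, shape (n,)
        Family labels.
    theta : float, optional
        Fix the frailty variance instead of profiling it out.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1 and x.shape[1] != 1:
        x = x.T
    t = np.asarray(time, float).ravel()
    d = np.asarray(status).ravel().astype(float)
    labels, ginv = np.unique(np.asarray(groups).ravel(), return_inverse=True)
    n_g = labels.size
    if n_g < 2:
        raise ValueError("at least two families are required")
    sizes = np.bincount(ginv, minlength=n_g)
    identifiable = bool(np.any(sizes > 1))

    if theta is not None:
        beta, ll, it, conv = _em_at_theta(x, t, d, ginv, n_g, theta, max_iter=max_iter, tol=tol)
        theta_hat = float(theta)
    else:
        cache: dict[float, tuple] = {}

        def neg_profile(log_theta):
            th = float(np.exp(log_theta))
            beta, ll, it, conv = _em_at_theta(x, t, d, ginv, n_g, th, max_iter=max_iter, tol=tol)
            cache[th] = (beta, ll, it, conv)
            return -ll

        opt = minimize_scalar(
            neg_profile,
            bounds=(np.log(_THETA_FLOOR), np.log(theta_max)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        theta_hat = float(np.exp(opt.x))
        beta, ll, it, conv = cache[theta_hat]

    boundary = theta_hat <= _THETA_FLOOR * 3
    # conditional information for beta at the converged offsets
    a = 1.0 / theta_hat
    D = np.bincount(ginv, weights=d, minlength=n_g)
    Lam0, _ = _breslow(x, t, d, beta, np.ones(x.shape[0]))
    u = np.ones(n_g)
    for _ in range(50):
        Lam0, _ = _breslow(x, t, d, beta, u[ginv])
        Lam_g = np.bincount(ginv, weights=Lam0 * np.exp(x @ beta), minlength=n_g)
        u_next = (a + D) / (a + Lam_g)
        if np.max(np.abs(u_next - u)) < 1e-9:
            u = u_next
            break
        u = u_next
    res = cox_newton(x, t, d, offset=np.log(u)[ginv], init=beta)
    return FrailtyFitResult(
        beta=beta,
        theta=theta_hat,
        var_model=res.var_model,
        loglik=ll,
        n_iter=it,
        converged=conv and (theta is not None or opt.success),
        boundary=boundary,
        identifiable=identifiable,
    )
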