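"""Synthetic data generation: reference populations and family-based
outcome-dependently sampled studies.

Event times follow a proportional-hazards model with constant baseline hazard,

    lambda_ij(t) = u_j * lambda0 * exp(beta * z_ij),

with ``z_ij ~ N(0,1)`` iid, ``lambda0 = 1/60`` per year by default (mean time
to event 60 years at the baseline covariate), an optional family-shared gamma
frailty ``u_j`` (mean 1, variance ``frailty_var``), optional random censoring
``C ~ Exponential(mean censor_mean)``, and administrative censoring at
``admin_age`` (100 years).

The *reference population* is a large sample of singletons drawn without any
selection; it stands in for the population registry from which the age-interval
incidence rates are estimated (events divided by person-years within each
interval — the piecewise-constant-hazard MLE).

The *ascertained sample* mimics recruitment through clinical genetic testing:
families of fixed size are generated, and a family enters the study only if at
least ``n_affected_required`` members have an observed event and at least one
affected member is "young" — diagnosed before the first quartile of the
observed-time distribution.  That cutoff is computed from the trial's own
pre-selection sample by default (``young_cutoff="observed"``); a variant using
the first quartile of the latent event times of a reference population is
available (``young_cutoff="latent"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalTable

__all__ = [
    "SimConfig",
    "SCENARIOS",
    "simulate_reference_population",
    "estimate_reference_rates",
    "simulate_ascertained_sample",
]

#: ascertainment scenarios: (family size n_j, required affected n_A), in
#: increasing order of selection strength
SCENARIOS = {"A1": (5, 1), "A2": (5, 3), "A3": (2, 1)}


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario.

    ``censor_mean`` is the mean (years) of the exponential random-censoring
    time, or ``None`` for administrative censoring only.  ``frailty_var`` is
    the variance of the family-shared gamma frailty (0 disables it).
    """

    n_families: int
    family_size: int = 5
    n_affected_required: int = 1
    beta: float = 0.0
    lambda0: float = 1.0 / 60.0
    admin_age: float = 100.0
    censor_mean: float | None = None
    frailty_var: float = 0.0
    young_quantile: float = 0.25
    young_cutoff: str = "observed"
    seed: int | None = None

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if not 1 <= self.n_affected_required <= self.family_size:
            raise ValueError("need 1 <= n_affected_required <= family_size")
        if self.frailty_var < 0:
            raise ValueError("frailty_var must be nonnegative")
        if self.young_cutoff not in ("observed", "latent"):
            raise ValueError("young_cutoff must be 'observed' or 'latent'")

    @classmethod
    def from_scenario(cls, scenario: str, **kwargs) -> "SimConfig":
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; valid: {sorted(SCENARIOS)}")
        nj, na = SCENARIOS[scenario]
        return cls(family_size=nj, n_affected_required=na, **kwargs)


def _draw_families(rng, n_fam, nj, beta, lambda0, theta):
    """Latent event times and covariates for ``n_fam`` families of size ``nj``."""
    z = rng.standard_normal((n_fam, nj))
    if theta > 0:
        u = rng.gamma(shape=1.0 / theta, scale=theta, size=n_fam)[:, None]
    else:
        u = 1.0
    rate = u * lambda0 * np.exp(beta * z)
    T = rng.exponential(1.0, (n_fam, nj)) / rate
    return z, T


def _observe(rng, T, admin_age, censor_mean):
    """Apply random then administrative censoring; returns (t, delta)."""
    cap = np.minimum(T, admin_age)
    if censor_mean is not None:
        C = rng.exponential(censor_mean, T.shape)
        t = np.minimum(cap, C)
        delta = T <= np.minimum(C, admin_age)
    else:
        t = cap
        delta = T <= admin_age
    return t, delta


def simulate_reference_population(
    n: int,
    beta: float,
    lambda0: float = 1.0 / 60.0,
    admin_age: float = 100.0,
    frailty_var: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """A large un-ascertained sample of singleton families (no random censoring)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z, T = _draw_families(rng, n, 1, beta, lambda0, frailty_var)
    t, delta = _observe(rng, T, admin_age, None)
    return pd.DataFrame(
        {
            "family_id": np.arange(n),
            "time": t.ravel(),
            "status": delta.ravel().astype(int),
            "covariate": z.ravel(),
        }
    )


def estimate_reference_rates(reference: pd.DataFrame, breaks) -> IntervalTable:
    """Piecewise-constant hazard MLE: events / person-years per interval."""
    breaks = np.asarray(breaks, float)
    t = reference["time"].to_numpy(float)
    d = reference["status"].to_numpy() == 1
    lo, hi = breaks[:-1], breaks[1:]
    # exposure of each subject inside [lo, hi): clip(t, lo, hi) - lo
    exposure = (np.clip(t[:, None], lo, hi) - lo).sum(axis=0)
    if np.any(exposure <= 0):
        k = int(np.flatnonzero(exposure <= 0)[0])
        raise ValueError(f"no person-time accrued in interval [{lo[k]}, {hi[k]})")
    idx = np.searchsorted(breaks, t[d], side="right") - 1
    idx = np.clip(idx, 0, breaks.size - 2)
    events = np.bincount(idx, minlength=breaks.size - 1).astype(float)
    return IntervalTable(breaks=breaks, rates=events / exposure)


def simulate_ascertained_sample(config: SimConfig, rng=None):
    """Generate one family-based outcome-dependently sampled study.

    Returns ``(subjects, n_included)`` where ``subjects`` contains all members
    of the included families.  An empty frame (``n_included == 0``) is
    possible and left to the caller to handle.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, nj = config.n_families, config.family_size
    z, T = _draw_families(rng, N, nj, config.beta, config.lambda0, config.frailty_var)
    t, delta = _observe(rng, T, config.admin_age, config.censor_mean)

    if config.young_cutoff == "observed":
        cutoff = np.quantile(t, config.young_quantile)
    else:
        cutoff = _latent_quartile(config)
    young = delta & (t < cutoff)
    include = (delta.sum(axis=1) >= config.n_affected_required) & young.any(axis=1)
    n_inc = int(include.sum())

    fam = np.repeat(np.arange(N)[include], nj)
    subjects = pd.DataFrame(
        {
            "family_id": fam,
            "time": t[include].ravel(),
            "status": delta[include].ravel().astype(int),
            "covariate": z[include].ravel(),
        }
    )
    return subjects, n_inc


_LATENT_CACHE: dict[tuple, float] = {}


def _latent_quartile(config: SimConfig, n_ref: int = 200_000) -> float:
    """First quartile of the latent event-time distribution, from a reference
    sample of the same (beta, lambda0, frailty) configuration; cached."""
    key = (config.beta, config.lambda0, config.frailty_var, config.young_quantile)
    if key not in _LATENT_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([12897, abs(hash(key)) % 2**31]))
        _, T = _draw_families(rng, n_ref, 1, config.beta, config.lambda0, config.frailty_var)
        _LATENT_CACHE[key] = float(np.quantile(T, config.young_quantile))
    return _LATENT_CACHE[key]
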