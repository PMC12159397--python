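"""Inverse-probability-of-selection weights for outcome-dependent survival samples.

Two per-interval weighting schemes are implemented.  Both reweight the sample so
that its age-specific composition matches an external reference population whose
incidence rates ``mu_k`` are known on an age-interval grid.

*Traditional weighted-cohort* (Antoniou-style): events in interval ``I_k`` get
weight ``w_k`` and censored subjects weight ``v_k``, chosen so the weighted
sample incidence rate equals ``mu_k`` in every interval while each interval's
mean weight stays 1.  The closed form is

.. math::

    w_k = \\frac{\\mu_k\\,(q_k (r_k+s_k) + (a_k-a_{k-1})\\, s_k \\sum_{l>k}(r_l+s_l))}
               {r_k s_k + \\mu_k (q_k r_k - p_k s_k)},
    \\qquad v_k = \\frac{r_k + s_k - w_k r_k}{s_k},

valid only when every interval contains both events and censorings and the
oversampling of events is strong enough; the four validity conditions are
checked and reported rather than repaired.

*Generalized weighted-cohort*: censored subjects are left unweighted
(``v_k = 1``) and events get

.. math:: w_k = \\frac{1-S_k}{S_k} \\cdot \\frac{S_k^o}{1-S_k^o},

which rescales the event/non-event ratio of each interval's risk set to the
population ratio ``(1-S_k)/S_k``.  These weights are strictly positive whenever
events are seen in every interval, with no requirement on censoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalCounts, IntervalTable, interval_index

__all__ = [
    "WeightSet",
    "WeightValidityError",
    "weighted_cohort_weights",
    "generalized_weights",
    "subject_weights",
    "verify_rate_reconstruction",
    "verify_ratio_restoration",
]

logger = logging.getLogger(__name__)

#: human-readable descriptions of the traditional scheme's validity conditions
_CONDITIONS = {
    7: "no events in interval (r_k = 0)",
    8: "no censored observations in interval (s_k = 0)",
    9: "insufficient oversampling of events: r_k <= mu_k p_k s_k / (s_k + mu_k q_k)",
    10: "case weight too large: w_k >= 1 + s_k / r_k (censored weight v_k <= 0)",
}


class WeightValidityError(ValueError):
    """Raised when a weighting scheme's validity conditions fail."""


@dataclass
class WeightSet:
    """Per-interval case weights ``w_k`` and censored-subject weights ``v_k``.

    ``violations`` lists ``(interval, condition, message)`` triples, with
    0-based interval indices and the condition identifiers 7–10 of the
    traditional scheme (the generalized scheme uses the pseudo-identifiers
    ``"no-events"`` and ``"last-interval"``).  Invalid weights are reported, not
    repaired: the fitting layer refuses invalid sets, while Monte Carlo drivers
    count them.
    """

    w: np.ndarray
    v: np.ndarray
    scheme: str
    valid: bool = True
    violations: list = field(default_factory=list)
    per_subject: np.ndarray | None = None

    def to_frame(self, table: IntervalTable) -> pd.DataFrame:
        viol = {k: [] for k in range(table.n_intervals)}
        for k, cond, _ in self.violations:
            viol[k].append(str(cond))
        return pd.DataFrame(
            {
                "interval": np.arange(table.n_intervals),
                "age_low": table.breaks[:-1],
                "age_high": table.breaks[1:],
                "w": self.w,
                "v": self.v,
                "valid": [not viol[k] for k in range(table.n_intervals)],
                "violated_conditions": [";".join(viol[k]) for k in range(table.n_intervals)],
            }
        )


def _check_shapes(counts: IntervalCounts, table: IntervalTable) -> None:
    if counts.n_intervals != table.n_intervals:
        raise ValueError(
            f"counts have {counts.n_intervals} intervals but table has {table.n_intervals}"
        )


def weighted_cohort_weights(
    counts: IntervalCounts,
    table: IntervalTable,
    *,
    require_all_intervals: bool = False,
) -> WeightSet:
    """Traditional weighted-cohort weights with validity conditions 7–10.

    Weights are computed interval by interval from the closed form above; the
    tail sums use unweighted counts (justified by the mean-one constraint).
    Conditions are enforced only where a weight is actually needed: ``w_k``
    requires events in ``I_k`` (``r_k > 0``), ``v_k`` requires censorings
    (``s_k > 0``).  An event-free interval needs no case weight, and its
    ``v_k = 1`` is the exact solution of the mean-one constraint, so such
    intervals are not failures.  An interval *with* events but no censorings
    leaves ``w_k`` undetermined (condition 8) — this is why the scheme breaks
    down on samples without right-censoring.  Failing conditions are recorded
    in ``violations`` and ``valid`` is set False, but whatever weights are
    computable are still returned so that diagnostics (e.g. the proportion of
    negative weights across Monte Carlo trials) can be collected.

    With ``require_all_intervals`` the textbook preconditions are enforced for
    *every* interval: an event-free interval violates condition 7 and a
    censoring-free one condition 8 regardless of whether the corresponding
    weight would be used — the reading under which the scheme can fully
    reproduce the population rate in every age group.
    """
    _check_shapes(counts, table)
    r, s, p, q = counts.r, counts.s, counts.p, counts.q
    mu, width = table.rates, table.widths
    tail = counts.tail_counts()

    violations: list[tuple[int, int, str]] = []
    K = table.n_intervals
    w = np.ones(K)
    v = np.ones(K)
    for k in range(K):
        if r[k] == 0:
            # no case weight needed; v_k = 1 satisfies the mean-one constraint
            if require_all_intervals:
                violations.append((k, 7, _CONDITIONS[7]))
            if s[k] == 0 and require_all_intervals:
                violations.append((k, 8, _CONDITIONS[8]))
            continue
        if s[k] == 0:
            violations.append((k, 8, _CONDITIONS[8]))
            w[k] = np.nan
            continue
        denom = r[k] * s[k] + mu[k] * (q[k] * r[k] - p[k] * s[k])
        # condition (9) <=> positive denominator <=> w_k > 0
        if denom <= 0:
            violations.append((k, 9, _CONDITIONS[9]))
            w[k] = np.nan if denom == 0 else (
                mu[k] * (q[k] * (r[k] + s[k]) + width[k] * s[k] * tail[k]) / denom
            )
            v[k] = np.nan if denom == 0 else (r[k] + s[k] - w[k] * r[k]) / s[k]
            continue
        w[k] = mu[k] * (q[k] * (r[k] + s[k]) + width[k] * s[k] * tail[k]) / denom
        v[k] = (r[k] + s[k] - w[k] * r[k]) / s[k]
        if w[k] >= 1.0 + s[k] / r[k]:
            violations.append((k, 10, _CONDITIONS[10]))

    return WeightSet(w=w, v=v, scheme="traditional", valid=not violations, violations=violations)


def generalized_weights(
    counts: IntervalCounts,
    table: IntervalTable,
    *,
    strict: bool = False,
    ratio_cap: float = 1e6,
) -> WeightSet:
    """Generalized weighted-cohort weights: ``v_k = 1``,
    ``w_k = [(1-S_k)/S_k] * [S_k^o/(1-S_k^o)]``.

    An interval without events (``S_k^o = 1``) has no case to weight; its
    ``w_k`` is set to 1 (unused) and the fit proceeds — the sample simply
    carries no information to recalibrate in that age group.  With ``strict``
    such intervals raise instead, enforcing the textbook requirement that
    events be observed in every age group.  The weights are strictly positive
    whenever defined; no censoring is required anywhere.

    Raises
    ------
    WeightValidityError
        If ``S_K = 0`` (last interval certain to produce the event), if some
        interval has events but no survivors (``S_k^o = 0`` gives a zero
        weight), or — under ``strict`` — if an interval contains no events.
    """
    _check_shapes(counts, table)
    s_obs = counts.s_obs
    S = table.surv
    no_events = np.flatnonzero(counts.r == 0)
    if strict and no_events.size:
        raise WeightValidityError(
            "no events observed in interval(s) "
            f"{no_events.tolist()}; the generalized scheme requires events in every age group"
        )
    if table.last_surv <= 0.0:
        raise WeightValidityError(
            "S_K = 0 in the last interval; choose a grid whose last interval "
            "is not certain to produce the event"
        )
    pop_ratio = (1.0 - S) / S
    if np.any(pop_ratio > ratio_cap):
        logger.warning(
            "population event/non-event ratio exceeds %.0e in interval(s) %s; "
            "the grid is near-degenerate",
            ratio_cap,
            np.flatnonzero(pop_ratio > ratio_cap).tolist(),
        )
    small = np.flatnonzero((counts.n_at_risk <= 1) & (counts.r > 0))
    if small.size:
        logger.warning("risk set of size <= 1 in interval(s) %s", small.tolist())
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(counts.r > 0, pop_ratio * s_obs / (1.0 - s_obs), 1.0)
    bad = np.flatnonzero((counts.r > 0) & ~(w > 0))
    if bad.size:
        raise WeightValidityError(
            f"nonpositive case weight in interval(s) {bad.tolist()} "
            "(no observed survivors of the interval)"
        )
    return WeightSet(w=w, v=np.ones_like(w), scheme="generalized")


def subject_weights(
    weight_set: WeightSet,
    table: IntervalTable,
    time,
    status,
    *,
    right_closed_last: bool = False,
) -> np.ndarray:
    """Per-subject weights ``W_ij``: ``w_k`` for an event in ``I_k``, ``v_k``
    for a censored subject in ``I_k``."""
    t = np.asarray(time, float)
    d = np.asarray(status).astype(bool)
    idx = interval_index(t, table, right_closed_last=right_closed_last)
    return np.where(d, weight_set.w[idx], weight_set.v[idx])


def _require_valid(weight_set: WeightSet) -> None:
    if not weight_set.valid:
        conds = sorted({(k, c) for k, c, _ in weight_set.violations})
        raise WeightValidityError(f"weight set is invalid; violations: {conds}")


def verify_rate_reconstruction(
    weight_set: WeightSet, counts: IntervalCounts, table: IntervalTable
) -> np.ndarray:
    """Reconstruct each interval's incidence rate from a traditional weight set.

    Returns ``w_k r_k / (w_k p_k + v_k q_k + (a_k - a_{k-1}) sum_{l>k}(v_l s_l +
    w_l r_l))`` which must equal ``mu_k`` — the defining property of the
    traditional scheme.
    """
    _require_valid(weight_set)
    _check_shapes(counts, table)
    w, v = weight_set.w, weight_set.v
    r, s, p, q = counts.r, counts.s, counts.p, counts.q
    contrib = v * s + w * r
    tail = np.concatenate([np.cumsum(contrib[::-1])[::-1][1:], [0.0]])
    return w * r / (w * p + v * q + table.widths * tail)


def verify_ratio_restoration(
    weight_set: WeightSet, counts: IntervalCounts, table: IntervalTable
) -> np.ndarray:
    """Event/non-event ratio of each weighted risk set, ``w_k r_k / (N_k - r_k)``.

    For a generalized weight set this equals the population ratio
    ``(1 - S_k)/S_k`` by construction.
    """
    _check_shapes(counts, table)
    survivors = counts.n_at_risk - counts.r
    if np.any(survivors <= 0):
        raise WeightValidityError(
            "no survivors at the end of interval(s) "
            f"{np.flatnonzero(survivors <= 0).tolist()}; ratio undefined"
        )
    return weight_set.w * counts.r / survivors
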