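"""Age-interval grids of population incidence rates and per-interval sample counts.

External registry information about the age at onset of a disease is typically
published as incidence rates :math:`\\mu_k` (events per person-year) on a grid of
age intervals :math:`I_k = [a_{k-1}, a_k)`.  Under a constant hazard within each
interval, the conditional probability of passing through interval ``k`` event-free
is ``S_k = exp(-mu_k * (a_k - a_{k-1}))``.  Both weighting schemes in this package
consume (a) such an :class:`IntervalTable` and (b) the per-interval aggregates of
the observed sample collected in :class:`IntervalCounts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntervalTable",
    "IntervalCounts",
    "make_interval_table",
    "aggregate_counts",
    "interval_index",
]


@dataclass(frozen=True)
class IntervalTable:
    """A grid of ``K`` age intervals with population incidence rates.

    Parameters
    ----------
    breaks : ndarray, shape (K+1,)
        Strictly increasing interval endpoints ``a_0 < a_1 < ... < a_K`` in years.
    rates : ndarray, shape (K,)
        Nonnegative incidence rates ``mu_k`` (events per person-year) for each
        interval ``I_k = [a_{k-1}, a_k)``.
    """

    breaks: np.ndarray
    rates: np.ndarray
    surv: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        breaks = np.asarray(self.breaks, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if breaks.ndim != 1 or breaks.size < 2:
            raise ValueError("breaks must be a 1-d vector with at least two entries")
        if np.any(np.diff(breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        if rates.ndim != 1 or rates.size != breaks.size - 1:
            raise ValueError(
                f"expected {breaks.size - 1} rates for {breaks.size} breaks, "
                f"got {rates.size}"
            )
        if np.any(rates < 0):
            raise ValueError("incidence rates must be nonnegative")
        object.__setattr__(self, "breaks", breaks)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "surv", np.exp(-rates * np.diff(breaks)))

    @property
    def n_intervals(self) -> int:
        return self.rates.size

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.breaks)

    @property
    def last_surv(self) -> float:
        """``S_K``; must be positive for the generalized weighting scheme."""
        return float(self.surv[-1])

    @classmethod
    def from_csv(cls, path) -> "IntervalTable":
        """Read a rate table with columns ``age_low, age_high, rate``."""
        df = pd.read_csv(path)
        missing = {"age_low", "age_high", "rate"} - set(df.columns)
        if missing:
            raise ValueError(f"incidence table missing column(s): {sorted(missing)}")
        df = df.sort_values("age_low").reset_index(drop=True)
        if not np.allclose(df["age_high"].to_numpy()[:-1], df["age_low"].to_numpy()[1:]):
            raise ValueError("incidence intervals must be contiguous")
        breaks = np.append(df["age_low"].to_numpy(float), df["age_high"].iloc[-1])
        return cls(breaks=breaks, rates=df["rate"].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_low": self.breaks[:-1],
                "age_high": self.breaks[1:],
                "rate": self.rates,
                "surv": self.surv,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_interval_table(breaks, rates) -> IntervalTable:
    """Build an :class:`IntervalTable`, deriving the interval survival ``S_k``."""
    return IntervalTable(breaks=np.asarray(breaks, float), rates=np.asarray(rates, float))


@dataclass(frozen=True)
class IntervalCounts:
    """Per-interval aggregates of an observed sample.

    Fields follow the usual notation: ``r_k``/``s_k`` are the numbers of events
    and censorings in interval ``I_k``; ``p_k``/``q_k`` the follow-up time those
    events and censorings accrue in the interval; ``n_at_risk[k]`` = ``N_k`` the
    number of subjects still event-free and uncensored at the start of ``I_k``;
    ``s_obs[k]`` = ``S_k^o`` the observed conditional survival through ``I_k``
    (equal to ``(N_k - r_k)/N_k`` when censoring respects interval endpoints).
    """

    r: np.ndarray
    s: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_at_risk: np.ndarray
    s_obs: np.ndarray

    @property
    def n(self) -> int:
        """Total sample size."""
        return int(self.r.sum() + self.s.sum())

    @property
    def n_intervals(self) -> int:
        return self.r.size

    def tail_counts(self) -> np.ndarray:
        """:math:`\\sum_{l>k} (r_l + s_l)` for every interval ``k``."""
        total = self.r + self.s
        return np.concatenate([np.cumsum(total[::-1])[::-1][1:], [0.0]])


def interval_index(time, table: IntervalTable, *, right_closed_last: bool = False) -> np.ndarray:
    """Map observed times to 0-based interval indices under ``[a_{k-1}, a_k)``.

    A time equal to an interior break belongs to the next interval.  A time equal
    to the final break ``a_K`` is rejected unless ``right_closed_last`` is set, in
    which case the last interval is treated as closed on the right (useful when
    follow-up is administratively terminated exactly at ``a_K``).
    """
    t = np.asarray(time, dtype=float)
    lo, hi = table.breaks[0], table.breaks[-1]
    bad_low = t < lo
    bad_high = (t > hi) | ((t == hi) & (not right_closed_last))
    if np.any(bad_low | bad_high):
        offender = t[bad_low | bad_high].ravel()[0]
        raise ValueError(
            f"observed time {offender!r} outside the interval grid [{lo}, {hi})"
        )
    idx = np.searchsorted(table.breaks, t, side="right") - 1
    return np.minimum(idx, table.n_intervals - 1)


def aggregate_counts(
    time,
    status,
    table: IntervalTable,
    *,
    right_closed_last: bool = False,
    person_time: str = "within",
    s_obs_method: str = "km",
) -> IntervalCounts:
    """Aggregate a sample into the per-interval counts used by both weighting schemes.

    Parameters
    ----------
    time, status : array-like
        Observed ages ``t_ij`` and event indicators ``delta_ij`` (1 = event).
    table : IntervalTable
        The interval grid (only its breaks are used here).
    right_closed_last : bool
        Accept ``t == a_K`` into the last interval (see :func:`interval_index`).
    person_time : {"within", "age"}
        How ``p_k`` / ``q_k`` accumulate follow-up.  ``"within"`` (default) sums
        the follow-up accrued *inside* the interval, ``t_ij - a_{k-1}``, which
        is the person-time that pairs with the interval incidence rate (subjects
        surviving the whole interval contribute the full width through the tail
        term of the rate equation).  ``"age"`` sums the raw observed ages.
    s_obs_method : {"km", "endpoint", "actuarial"}
        Estimator of the observed conditional interval survival ``S_k^o``.
        ``"km"`` (default) is the Kaplan–Meier estimate over the interval,
        which stays consistent when random censoring occurs inside intervals;
        ``"endpoint"`` is ``(N_k - r_k) / N_k``, exact when censoring respects
        interval endpoints (the model's discrete-censoring assumption);
        ``"actuarial"`` is the life-table variant ``1 - r_k / (N_k - s_k/2)``.
        All three coincide when no censoring occurs inside an interval.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(status)
    if t.shape != d.shape or t.ndim != 1:
        raise ValueError("time and status must be 1-d arrays of equal length")
    if not np.all((d == 0) | (d == 1)):
        raise ValueError("status must contain only 0 and 1")
    if np.any(t <= 0):
        raise ValueError("observed times must be positive")
    if person_time not in ("within", "age"):
        raise ValueError("person_time must be 'within' or 'age'")
    if s_obs_method not in ("km", "endpoint", "actuarial"):
        raise ValueError("s_obs_method must be 'km', 'endpoint' or 'actuarial'")
    d = d.astype(bool)

    K = table.n_intervals
    idx = interval_index(t, table, right_closed_last=right_closed_last)
    r = np.bincount(idx[d], minlength=K).astype(float)
    s = np.bincount(idx[~d], minlength=K).astype(float)
    exposure = t - table.breaks[idx] if person_time == "within" else t
    p = np.bincount(idx[d], weights=exposure[d], minlength=K)
    q = np.bincount(idx[~d], weights=exposure[~d], minlength=K)

    out = r + s  # subjects leaving observation in each interval
    n_at_risk = t.size - np.concatenate([[0.0], np.cumsum(out)[:-1]])
    if np.any((n_at_risk <= 0) & (out > 0)):
        raise ValueError("internal inconsistency: observations in an interval with empty risk set")

    with np.errstate(invalid="ignore", divide="ignore"):
        if s_obs_method == "endpoint":
            s_obs = np.where(n_at_risk > 0, (n_at_risk - r) / n_at_risk, 1.0)
        elif s_obs_method == "actuarial":
            denom = n_at_risk - s / 2.0
            s_obs = np.where(denom > 0, 1.0 - r / denom, 1.0)
        else:
            s_obs = _km_interval_survival(t, d, idx, K)
    return IntervalCounts(r=r, s=s, p=p, q=q, n_at_risk=n_at_risk, s_obs=s_obs)


def _km_interval_survival(t, d, idx, K):
    """Kaplan–Meier conditional survival through each interval.

    Censored subjects leave the risk set at their censoring time; at tied
    times events are taken to precede censorings, the usual convention.
    """
    order = np.lexsort((~d, t))  # events first within ties
    ts, ds, ik = t[order], d[order], idx[order]
    at_risk = t.size - np.arange(t.size, dtype=float)
    s_obs = np.ones(K)
    factors = 1.0 - 1.0 / at_risk
    for k in range(K):
        m = (ik == k) & ds
        if m.any():
            s_obs[k] = np.prod(factors[m])
    return s_obs
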