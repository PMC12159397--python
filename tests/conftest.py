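import numpy as np
import pytest

from odscox import IntervalTable, aggregate_counts


@pytest.fixture
def oversampled_sample():
    """A censoring-rich sample with clear oversampling of events everywhere:
    valid under the traditional weighting scheme."""
    rng = np.random.default_rng(3)
    t = np.concatenate(
        [
            rng.uniform(1, 49, 80),     # early events
            rng.uniform(50, 99, 40),    # late events
            rng.uniform(1, 49, 60),     # early censored
            rng.uniform(50, 99, 70),    # late censored
            [49.9, 99.9],               # censored at the interval ends
        ]
    )
    d = np.concatenate([np.ones(120), np.zeros(132)]).astype(int)
    z = rng.standard_normal(t.size)
    return t, d, z


@pytest.fixture
def low_rate_table():
    """Population rates low enough that the oversampled fixture is valid."""
    return IntervalTable(np.array([0.0, 50.0, 100.0]), np.array([0.005, 0.008]))


@pytest.fixture
def oversampled_counts(oversampled_sample, low_rate_table):
    t, d, _ = oversampled_sample
    return aggregate_counts(t, d, low_rate_table)


def exact_match_sample(n1=100, r1=20, r2=16, breaks=(0.0, 50.0, 100.0), seed=0):
    """A sample whose observed conditional interval survival matches, exactly,
    the interval survival implied by the returned rate table: events at
    distinct times inside each interval, all censoring at the follow-up end.

    S_1^o = (n1-r1)/n1, S_2^o = (n2-r2)/n2 with n2 = n1 - r1; rates are chosen
    as mu_k = -log(S_k^o)/width so that S_k = S_k^o.
    """
    rng = np.random.default_rng(seed)
    n2 = n1 - r1
    t = np.concatenate(
        [
            np.linspace(5, 45, r1),           # events in I_1
            np.linspace(55, 95, r2),          # events in I_2
            np.full(n2 - r2, breaks[-1]),     # administratively censored at a_K
        ]
    )
    d = np.concatenate([np.ones(r1 + r2), np.zeros(n2 - r2)]).astype(int)
    z = rng.standard_normal(t.size)
    widths = np.diff(np.asarray(breaks))
    s_obs = np.array([(n1 - r1) / n1, (n2 - r2) / n2])
    rates = -np.log(s_obs) / widths
    table = IntervalTable(np.asarray(breaks, float), rates)
    return t, d, z, table
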