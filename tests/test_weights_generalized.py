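import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odscox import (
    WeightedCoxPH,
    aggregate_counts,
    generalized_weights,
    make_interval_table,
    subject_weights,
    surv_array,
    verify_ratio_restoration,
)
from odscox.intervals import IntervalCounts
from odscox.weights import WeightValidityError

from conftest import exact_match_sample


def counts_with_s_obs(r, s, s_obs):
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    total = r + s
    n_at_risk = total.sum() - np.concatenate([[0.0], np.cumsum(total)[:-1]])
    return IntervalCounts(
        r=r, s=s, p=np.zeros_like(r), q=np.zeros_like(r),
        n_at_risk=n_at_risk, s_obs=np.asarray(s_obs, float),
    )


class TestWeightFormula:
    def test_oversampled_direct_substitution(self):
        """Population survival 0.9 but only half the risk set survives the
        interval in the sample: events are downweighted to 1/9."""
        tab = make_interval_table([0.0, 10.0], [-np.log(0.9) / 10.0])
        c = counts_with_s_obs(r=[5], s=[5], s_obs=[0.5])
        ws = generalized_weights(c, tab)
        assert ws.w[0] == pytest.approx((0.1 / 0.9) * (0.5 / 0.5), rel=1e-12)
        assert ws.w[0] < 1

    def test_undersampled_direct_substitution(self):
        tab = make_interval_table([0.0, 10.0], [-np.log(0.5) / 10.0])
        c = counts_with_s_obs(r=[1], s=[9], s_obs=[0.9])
        ws = generalized_weights(c, tab)
        assert ws.w[0] == pytest.approx((0.5 / 0.5) * (0.9 / 0.1), rel=1e-12)
        assert ws.w[0] > 1

    def test_censored_always_unweighted(self, oversampled_counts, low_rate_table):
        ws = generalized_weights(oversampled_counts, low_rate_table)
        np.testing.assert_array_equal(ws.v, 1.0)
        assert ws.scheme == "generalized"

    def test_ratio_restoration_identity(self):
        """w_k r_k / (N_k - r_k) equals the population event/non-event ratio:
        the weighted risk set has the reference composition."""
        rng = np.random.default_rng(11)
        breaks = np.arange(0.0, 120.0, 20.0)
        tab = make_interval_table(breaks, rng.uniform(0.005, 0.03, 5))
        t = rng.uniform(0.5, 99.5, 400)
        d = rng.integers(0, 2, 400)
        c = aggregate_counts(t, d, tab, s_obs_method="endpoint")
        assert np.all(c.r > 0)
        ws = generalized_weights(c, tab)
        np.testing.assert_allclose(
            verify_ratio_restoration(ws, c, tab),
            (1 - tab.surv) / tab.surv,
            rtol=1e-12,
        )

    def test_two_part_decomposition_brute_force(self):
        """The weighted decomposition of each risk set into within-interval
        events and later survivors matches the reference decomposition."""
        rng = np.random.default_rng(7)
        tab = make_interval_table(np.arange(0, 60.0, 10.0), rng.uniform(0.01, 0.05, 5))
        t = rng.uniform(0.5, 49.5, 300)
        d = rng.integers(0, 2, 300)
        c = aggregate_counts(t, d, tab, s_obs_method="endpoint")
        ws = generalized_weights(c, tab)
        for k in range(5):
            weighted_events = ws.w[k] * c.r[k]
            survivors = c.n_at_risk[k] - c.r[k]
            pseudo_n = weighted_events + survivors
            # event share of the weighted risk set = 1 - S_k of the reference
            assert weighted_events / pseudo_n == pytest.approx(
                1 - tab.surv[k], rel=1e-10
            )


class TestValidity:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_positivity_over_random_counts(self, seed):
        """Whenever every interval contains events and S_K > 0, the weights
        are strictly positive — no censoring required anywhere."""
        rng = np.random.default_rng(seed)
        K = rng.integers(1, 6)
        breaks = np.cumsum(np.r_[0.0, rng.uniform(1, 30, K)])
        tab = make_interval_table(breaks, rng.uniform(1e-4, 0.1, K))
        r = rng.integers(1, 50, K)
        s = rng.integers(0, 50, K)
        s[-1] += 1  # someone must outlive the grid for S_K^o < 1 everywhere
        c = counts_with_s_obs(r, s, s_obs=1 - r / (np.cumsum((r + s)[::-1])[::-1]))
        ws = generalized_weights(c, tab)
        assert np.all(ws.w > 0)
        assert np.all(ws.v == 1)

    def test_no_censoring_at_all_is_fine(self):
        """Unlike the traditional scheme, censoring-free samples are valid."""
        tab = make_interval_table([0.0, 10.0, 20.0], [0.02, 0.02])
        c = counts_with_s_obs(r=[6, 4], s=[0, 0], s_obs=[0.4, 0.0])
        # all remaining subjects have the event in the last interval: S_2^o = 0
        with pytest.raises(WeightValidityError, match="survivors"):
            generalized_weights(c, tab)
        c = counts_with_s_obs(r=[6, 3], s=[0, 1], s_obs=[0.4, 0.25])
        ws = generalized_weights(c, tab)
        assert np.all(ws.w > 0)

    def test_event_free_interval_unused_by_default_strict_raises(self):
        tab = make_interval_table([0.0, 10.0, 20.0], [0.02, 0.02])
        c = counts_with_s_obs(r=[5, 0], s=[3, 4], s_obs=[0.5, 1.0])
        ws = generalized_weights(c, tab)
        assert ws.w[1] == 1.0  # placeholder, no event to weight
        with pytest.raises(WeightValidityError, match="interval"):
            generalized_weights(c, tab, strict=True)

    def test_vanishing_last_interval_survival_rejected(self):
        tab = make_interval_table([0.0, 10.0], [100.0])  # S_1 = e^-1000 -> underflows to 0
        assert tab.last_surv == 0.0
        c = counts_with_s_obs(r=[5], s=[5], s_obs=[0.5])
        with pytest.raises(WeightValidityError, match="S_K"):
            generalized_weights(c, tab)


class TestDegeneracy:
    def test_matching_sample_gives_unit_weights_and_unweighted_fit(self):
        """When the sample's interval survival equals the reference's, all
        weights are 1 and the weighted fit coincides with plain Cox."""
        t, d, z, table = exact_match_sample()
        c = aggregate_counts(t, d, table, right_closed_last=True)
        ws = generalized_weights(c, table)
        np.testing.assert_allclose(ws.w, 1.0, atol=1e-12)

        y = surv_array(d, t)
        W = subject_weights(ws, table, t, d, right_closed_last=True)
        beta_w = WeightedCoxPH().fit(z, y, sample_weight=W).coef_[0]
        beta_u = WeightedCoxPH().fit(z, y).coef_[0]
        assert beta_w == pytest.approx(beta_u, abs=1e-10)
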