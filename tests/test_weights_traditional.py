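import numpy as np
import pytest
from scipy.optimize import fsolve

from odscox import (
    aggregate_counts,
    make_interval_table,
    subject_weights,
    verify_rate_reconstruction,
    weighted_cohort_weights,
)
from odscox.intervals import IntervalCounts
from odscox.weights import WeightValidityError


def counts_from(r, s, p, q):
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    total = r + s
    n_at_risk = total.sum() - np.concatenate([[0.0], np.cumsum(total)[:-1]])
    s_obs = np.where(n_at_risk > 0, (n_at_risk - r) / n_at_risk, 1.0)
    return IntervalCounts(
        r=r, s=s, p=np.asarray(p, float), q=np.asarray(q, float),
        n_at_risk=n_at_risk, s_obs=s_obs,
    )


class TestClosedForm:
    def test_matches_numeric_solve_of_defining_system(self):
        """The closed form solves the rate equation + mean-one constraint:
        cross-checked with a generic nonlinear root-finder on the K=2 system."""
        tab = make_interval_table([0.0, 50.0, 100.0], [0.004, 0.006])
        c = counts_from(r=[30, 12], s=[20, 25], p=[700, 300], q=[600, 650])
        ws = weighted_cohort_weights(c, tab)
        assert ws.valid

        widths = tab.widths
        def system(x):
            w1, v1, w2, v2 = x
            eq1 = tab.rates[0] - w1 * 30 / (
                w1 * 700 + v1 * 600 + widths[0] * (v2 * 25 + w2 * 12)
            )
            eq2 = tab.rates[1] - w2 * 12 / (w2 * 300 + v2 * 650)
            eq3 = (w1 * 30 + v1 * 20) / 50 - 1
            eq4 = (w2 * 12 + v2 * 25) / 37 - 1
            return [eq1, eq2, eq3, eq4]

        sol = fsolve(system, np.ones(4), full_output=False, xtol=1e-13)
        np.testing.assert_allclose(ws.w, sol[[0, 2]], rtol=1e-9)
        np.testing.assert_allclose(ws.v, sol[[1, 3]], rtol=1e-9)

    def test_mean_one_constraint_exact(self, oversampled_counts, low_rate_table):
        ws = weighted_cohort_weights(oversampled_counts, low_rate_table)
        assert ws.valid
        c = oversampled_counts
        np.testing.assert_allclose(
            (ws.w * c.r + ws.v * c.s) / (c.r + c.s), 1.0, atol=1e-14
        )

    def test_rate_reconstruction(self, oversampled_counts, low_rate_table):
        ws = weighted_cohort_weights(oversampled_counts, low_rate_table)
        rec = verify_rate_reconstruction(ws, oversampled_counts, low_rate_table)
        np.testing.assert_allclose(rec, low_rate_table.rates, rtol=1e-10)

    def test_weighted_tail_equals_unweighted_tail(self, oversampled_counts, low_rate_table):
        """The mean-one constraint makes the weighted count of older subjects
        equal the raw count, so weights are computable interval by interval."""
        c = oversampled_counts
        ws = weighted_cohort_weights(c, low_rate_table)
        contrib = ws.v * c.s + ws.w * c.r
        np.testing.assert_allclose(contrib, c.r + c.s, atol=1e-10)

    def test_single_interval_reconstruction(self):
        tab = make_interval_table([0.0, 60.0], [0.003])
        c = counts_from(r=[25], s=[30], p=[600], q=[800])
        ws = weighted_cohort_weights(c, tab)
        assert ws.valid
        rec = verify_rate_reconstruction(ws, c, tab)
        assert rec[0] == pytest.approx(0.003, rel=1e-12)

    def test_oversampling_monotonicity(self):
        """Raising the number of observed events (stronger oversampling)
        lowers the case weight in that interval."""
        tab = make_interval_table([0.0, 50.0, 100.0], [0.004, 0.006])
        w_prev = np.inf
        for r1 in (10, 20, 40, 80):
            c = counts_from(r=[r1, 12], s=[20, 25], p=[r1 * 22.0, 300], q=[600, 650])
            ws = weighted_cohort_weights(c, tab)
            assert ws.w[0] < w_prev
            w_prev = ws.w[0]


class TestValidityConditions:
    def test_censoring_free_interval_is_invalid(self):
        """Events with no censored subjects leave the case weight undetermined
        (condition 8): the scheme cannot be used on samples without censoring."""
        tab = make_interval_table([0.0, 50.0, 100.0], [0.004, 0.006])
        c = counts_from(r=[30, 12], s=[0, 25], p=[700, 300], q=[0, 650])
        ws = weighted_cohort_weights(c, tab)
        assert not ws.valid
        assert (0, 8) in {(k, cond) for k, cond, _ in ws.violations}

    def test_event_free_interval_needs_no_case_weight(self):
        """With no events in an interval there is nobody to assign w_k to and
        v_k = 1 solves the mean-one constraint exactly: not a failure."""
        tab = make_interval_table([0.0, 50.0, 100.0], [0.004, 0.006])
        c = counts_from(r=[30, 0], s=[20, 25], p=[700, 0], q=[600, 650])
        ws = weighted_cohort_weights(c, tab)
        assert ws.valid
        assert ws.v[1] == 1.0

    def test_event_free_interval_flagged_when_all_intervals_required(self):
        tab = make_interval_table([0.0, 50.0, 100.0], [0.004, 0.006])
        c = counts_from(r=[30, 0], s=[20, 25], p=[700, 0], q=[600, 650])
        ws = weighted_cohort_weights(c, tab, require_all_intervals=True)
        assert not ws.valid
        assert (1, 7) in {(k, cond) for k, cond, _ in ws.violations}

    def test_undersampling_violates_condition_ten(self):
        """Too few events relative to the population rate drives w_k above
        1 + s_k/r_k, i.e. a negative weight for the censored."""
        tab = make_interval_table([0.0, 50.0, 100.0], [0.02, 0.02])
        c = counts_from(r=[3, 3], s=[50, 40], p=[70, 60], q=[1300, 1000])
        ws = weighted_cohort_weights(c, tab)
        assert not ws.valid
        conds = {cond for _, cond, _ in ws.violations}
        assert 10 in conds
        assert np.nanmin(ws.v) < 0  # the offending censored weight is negative

    def test_reconstruction_refuses_invalid_sets(self):
        tab = make_interval_table([0.0, 50.0, 100.0], [0.02, 0.02])
        c = counts_from(r=[3, 3], s=[50, 40], p=[70, 60], q=[1300, 1000])
        ws = weighted_cohort_weights(c, tab)
        with pytest.raises(WeightValidityError):
            verify_rate_reconstruction(ws, c, tab)


class TestPerSubjectAssignment:
    def test_events_get_w_censored_get_v(self, oversampled_sample, low_rate_table):
        t, d, _ = oversampled_sample
        c = aggregate_counts(t, d, low_rate_table)
        ws = weighted_cohort_weights(c, low_rate_table)
        W = subject_weights(ws, low_rate_table, t, d)
        events_first = (t < 50) & (d == 1)
        assert np.all(W[events_first] == ws.w[0])
        cens_second = (t >= 50) & (d == 0)
        assert np.all(W[cens_second] == ws.v[1])

    def test_export_frame_schema(self, oversampled_counts, low_rate_table):
        ws = weighted_cohort_weights(oversampled_counts, low_rate_table)
        df = ws.to_frame(low_rate_table)
        assert list(df.columns) == [
            "interval", "age_low", "age_high", "w", "v", "valid", "violated_conditions",
        ]
        assert df["valid"].all()
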