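import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dormsig.survival import (
    CoxConvergenceError,
    CoxFit,
    cox_binary,
    cox_partial_loglik,
    forest_table,
    landmark_late,
    meta_analyze,
    select_endpoint,
    truncate_5y,
)
from tests.conftest import make_cohort


class TestSelectEndpoint:
    def test_rfs_first(self):
        assert select_endpoint({"RFS", "DMFS"}) == "RFS"

    def test_dmfs_fallback(self):
        assert select_endpoint({"DMFS", "DSS"}) == "DMFS"

    def test_dss_only(self):
        assert select_endpoint({"DSS"}) == "DSS"

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no endpoint"):
            select_endpoint(set())

    def test_unknown_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            select_endpoint({"OS"})


class TestTruncate5y:
    def test_event_beyond_horizon_censored(self):
        c = make_cohort([80.0], [1])
        out = truncate_5y(c)
        assert out.time_months[0] == 60.0
        assert out.event[0] == 0

    def test_event_before_horizon_unchanged(self):
        c = make_cohort([30.0], [1])
        out = truncate_5y(c)
        assert out.time_months[0] == 30.0 and out.event[0] == 1

    def test_event_exactly_at_horizon_retained(self):
        c = make_cohort([60.0], [1])
        out = truncate_5y(c)
        assert out.time_months[0] == 60.0 and out.event[0] == 1

    def test_bad_horizon(self):
        with pytest.raises(ValueError, match="positive"):
            truncate_5y(make_cohort([10.0], [1]), horizon=0)


class TestLandmarkLate:
    def test_early_relapse_excluded(self):
        c = make_cohort([40.0, 100.0, 90.0], [1, 1, 0])
        out = landmark_late(c)
        assert len(out) == 2

    def test_origin_shift(self):
        c = make_cohort([100.0, 70.0], [1, 1])
        out = landmark_late(c)
        np.testing.assert_allclose(out.time_months, [40.0, 10.0])
        np.testing.assert_array_equal(out.event, [1, 1])

    def test_exactly_at_landmark_excluded(self):
        c = make_cohort([60.0, 100.0, 80.0], [0, 1, 0])
        out = landmark_late(c)
        assert len(out) == 2
        assert "c_p0" not in out.patient_ids

    def test_non_analyzable_cohort_errors(self):
        c = make_cohort([40.0, 50.0, 100.0], [1, 1, 0])  # no late events
        with pytest.raises(ValueError, match="not analyzable"):
            landmark_late(c)


class TestCoxBinary:
    def test_toy_cohort_matches_grid_search(self, toy_cohort):
        labels = np.array(
            ["high", "low", "high", "low", "high", "low"], dtype=object
        )
        fit = cox_binary(toy_cohort, labels)
        x = (labels == "high").astype(float)
        grid = np.linspace(-4, 4, 800001)
        ll = [
            cox_partial_loglik(b, toy_cohort.time_months, toy_cohort.event, x)
            for b in grid
        ]
        best = grid[int(np.argmax(ll))]
        assert fit.log_hr == pytest.approx(best, abs=1e-5)

    def test_matches_lifelines_with_ties(self):
        # independent implementation oracle (Efron ties by default)
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        n = 250
        x = rng.integers(0, 2, n).astype(float)
        t = np.ceil(rng.exponential(1.0 / (0.03 * np.exp(0.8 * x))))
        e = (t < 50).astype(int)
        t = np.minimum(t, 50)
        cohort = make_cohort(t, e)
        fit = cox_binary(cohort, np.where(x == 1, "high", "low"))
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": t, "E": e, "x": x}), "T", "E"
        )
        assert fit.log_hr == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_adjustment_covariate_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        z = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.5 * x + 0.3 * z)))
        e = np.ones(n, dtype=int)
        cohort = make_cohort(t, e)
        fit = cox_binary(cohort, np.where(x == 1, "high", "low"), adjustment=z)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": t, "E": e, "x": x, "z": z}), "T", "E"
        )
        assert fit.log_hr == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.extra_coefs["adjustment"][0] == pytest.approx(
            cph.params_["z"], abs=1e-6
        )

    def test_null_invariance_under_permutation(self):
        rng = np.random.default_rng(3)
        n = 400
        t = rng.exponential(50.0, n)
        e = np.ones(n, dtype=int)
        cohort = make_cohort(t, e)
        zs = []
        for _ in range(50):
            labels = rng.permutation(
                np.array(["high"] * (n // 2) + ["low"] * (n // 2), dtype=object)
            )
            fit = cox_binary(cohort, labels)
            zs.append(fit.log_hr / fit.se)
        zs = np.array(zs)
        assert abs(np.mean(zs)) < 0.5
        assert np.mean(np.abs(zs) > 2.5) < 0.1

    def test_recovers_planted_hr(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1.0 / (0.01 * np.where(x == 1, 0.5, 1.0)))
        cohort = make_cohort(t, np.ones(n, dtype=int))
        fit = cox_binary(cohort, np.where(x == 1, "high", "low"))
        assert 0.45 <= fit.hr <= 0.56

    def test_invariant_to_patient_relabeling_and_time_shift(self):
        rng = np.random.default_rng(9)
        n = 100
        t = rng.exponential(30.0, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        labels = np.array(["high", "low"] * (n // 2), dtype=object)
        c1 = make_cohort(t, e)
        fit1 = cox_binary(c1, labels)
        perm = rng.permutation(n)
        c2 = make_cohort(t[perm], e[perm])
        fit2 = cox_binary(c2, labels[perm])
        assert fit1.log_hr == pytest.approx(fit2.log_hr, abs=1e-8)
        c3 = make_cohort(t + 17.5, e)
        fit3 = cox_binary(c3, labels)
        assert fit1.log_hr == pytest.approx(fit3.log_hr, abs=1e-8)

    def test_labels_by_patient_id_mapping(self, toy_cohort):
        labels = pd.Series(
            ["high", "low", "high", "low", "high", "low"],
            index=[f"p{i}" for i in range(6)],
        )
        fit = cox_binary(toy_cohort, labels)
        assert np.isfinite(fit.log_hr)

    def test_no_events_errors(self):
        c = make_cohort([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        labels = np.array(["high", "low", "high", "low"], dtype=object)
        with pytest.raises(ValueError, match="events"):
            cox_binary(c, labels)

    def test_single_group_errors(self):
        c = make_cohort([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="both label groups"):
            cox_binary(c, np.array(["high", "high"], dtype=object))

    def test_monotone_likelihood_reported(self):
        # high group all censored, late: likelihood increases as beta -> -inf
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 50.0, 51.0, 52.0, 53.0, 54.0])
        e = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        labels = np.array(["low"] * 5 + ["high"] * 5, dtype=object)
        with pytest.raises(CoxConvergenceError):
            cox_binary(make_cohort(t, e), labels)


def dl_oracle(theta, se):
    """Independent DerSimonian-Laird implementation for cross-checking."""
    theta, se = np.asarray(theta, float), np.asarray(se, float)
    w = se**-2
    tf = (w * theta).sum() / w.sum()
    q = (w * (theta - tf) ** 2).sum()
    k = len(theta)
    tau2 = max(0.0, (q - (k - 1)) / (w.sum() - (w**2).sum() / w.sum()))
    ws = 1.0 / (se**2 + tau2)
    return q, tau2, (ws * theta).sum() / ws.sum(), (ws.sum()) ** -0.5


def fit(cid, theta, se):
    return CoxFit(cohort_id=cid, log_hr=theta, se=se, n=100, n_events=40)


class TestMetaAnalyze:
    def test_identical_fits_closed_form(self):
        k = 5
        m = meta_analyze([fit(f"c{i}", 0.4, 0.2) for i in range(k)])
        assert m.Q == pytest.approx(0.0, abs=1e-12)
        assert m.combined_log_hr == pytest.approx(0.4)
        assert m.combined_se == pytest.approx(0.2 / np.sqrt(k))
        assert m.model == "fixed" and m.tau2 == 0.0

    def test_two_study_heterogeneous_matches_dl_oracle(self):
        m = meta_analyze([fit("a", 0.0, 1.0), fit("b", 10.0, 1.0)])
        q, tau2, comb, se = dl_oracle([0.0, 10.0], [1.0, 1.0])
        assert m.Q == pytest.approx(50.0)
        assert m.q_pvalue < 0.05 and m.model == "random"
        assert m.tau2 == pytest.approx(tau2) == pytest.approx(49.0)
        assert m.combined_log_hr == pytest.approx(comb)
        assert m.combined_se == pytest.approx(se)

    def test_random_effects_match_dl_oracle_generic(self):
        rng = np.random.default_rng(5)
        theta = rng.normal(0, 2.0, 8)
        se = rng.uniform(0.1, 0.3, 8)
        m = meta_analyze([fit(f"c{i}", t, s) for i, (t, s) in
                          enumerate(zip(theta, se))])
        q, tau2, comb, cse = dl_oracle(theta, se)
        assert m.Q == pytest.approx(q)
        if m.model == "random":
            assert m.tau2 == pytest.approx(tau2)
            assert m.combined_log_hr == pytest.approx(comb)
            assert m.combined_se == pytest.approx(cse)

    def test_combined_within_range_and_random_se_wider(self):
        rng = np.random.default_rng(11)
        theta = rng.normal(0, 1.5, 10)
        se = rng.uniform(0.1, 0.4, 10)
        fits = [fit(f"c{i}", t, s) for i, (t, s) in enumerate(zip(theta, se))]
        m = meta_analyze(fits)
        assert theta.min() <= m.combined_log_hr <= theta.max()
        m_fixed = meta_analyze(fits, het_alpha=0.0)  # q_pvalue < 0 impossible
        assert m_fixed.model == "fixed"
        assert m.combined_se >= m_fixed.combined_se - 1e-15

    def test_ci_definition(self):
        m = meta_analyze([fit(f"c{i}", 0.3, 0.1) for i in range(3)])
        lo, hi = m.ci95
        assert lo == pytest.approx(np.exp(m.combined_log_hr - 1.96 * m.combined_se))
        assert hi == pytest.approx(np.exp(m.combined_log_hr + 1.96 * m.combined_se))
        z = m.combined_log_hr / m.combined_se
        assert m.p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_single_fit_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            meta_analyze([fit("a", 0.1, 0.2)])

    def test_nonpositive_se_rejected_at_construction(self):
        with pytest.raises(ValueError, match="positive"):
            fit("a", 0.1, 0.0)

    def test_forest_table_weights_sum_to_100(self):
        m = meta_analyze([fit(f"c{i}", 0.2 * i, 0.1 + 0.05 * i)
                          for i in range(4)])
        table = forest_table(m)
        assert table["weight_pct"].sum() == pytest.approx(100.0)
        assert list(table["cohort_id"]) == [f"c{i}" for i in range(4)]
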