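import numpy as np
import pandas as pd
import pytest

from polarspec import survival as surv
from polarspec import synthetic
from polarspec.data_io import GeneSet, SurvivalCohort, ValidationError
from polarspec.survival import (
    ConvergenceError,
    cox_fit,
    cox_hr_binary,
    km_curve,
    logrank_test,
    mean_signature_score,
    median_split,
    per_gene_survival_z,
    select_tumor_gene_set,
    survival_by_signature,
)

from _oracles import km_by_hand, logrank_by_hand

GENES = [f"g{i:04d}" for i in range(1, 201)]


class TestKMCurve:
    def test_all_censored_flat_at_one(self):
        with pytest.warns(UserWarning, match="no events"):
            curve = km_curve(np.array([1.0, 2.0, 3.0]), np.zeros(3, dtype=int))
        assert curve.survival.size == 0

    def test_two_events_hand_product_limit(self):
        curve = km_curve(np.array([1.0, 2.0]), np.array([1, 1]))
        np.testing.assert_allclose(curve.event_times, [1.0, 2.0])
        np.testing.assert_allclose(curve.survival, [0.5, 0.0])

    def test_censoring_between_events_hand_product_limit(self):
        # event at 1 (3 at risk), censor at 2, event at 3 (1 at risk)
        curve = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    def test_matches_brute_force_on_random_cohorts(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            times = np.round(rng.exponential(5, n), 1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            curve = km_curve(times, events)
            ref = km_by_hand(list(times), list(events))
            np.testing.assert_allclose(curve.survival, [ref[t] for t in curve.event_times], atol=1e-12)

    def test_monotone_within_unit_interval(self, rng):
        times = rng.exponential(3, 50)
        events = rng.integers(0, 2, 50)
        events[0] = 1
        curve = km_curve(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival.min() >= 0 and curve.survival.max() <= 1


class TestLogrank:
    def test_identical_groups_give_zero_chi2(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_risk_tables(self):
        # A events at (1,2), B events at (3,4): chi2 = (7/6)^2 / (17/36) = 49/17
        ta, ea = np.array([1.0, 2.0]), np.array([1, 1])
        tb, eb = np.array([3.0, 4.0]), np.array([1, 1])
        chi2, _ = logrank_test(ta, ea, tb, eb)
        np.testing.assert_allclose(chi2, 49 / 17, atol=1e-10)
        np.testing.assert_allclose(chi2, logrank_by_hand(ta, ea, tb, eb), atol=1e-10)

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.exponential(3, 20), rng.exponential(5, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        ea[0] = eb[0] = 1
        c1, p1 = logrank_test(ta, ea, tb, eb)
        c2, p2 = logrank_test(tb, eb, ta, ea)
        np.testing.assert_allclose(c1, c2, atol=1e-12)
        assert p1 == p2

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(np.ones(3), np.zeros(3, int), np.ones(3), np.zeros(3, int))

    def test_matches_lifelines_on_random_cohorts(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(25):
            na, nb = int(rng.integers(10, 40)), int(rng.integers(10, 40))
            ta, tb = rng.exponential(3, na), rng.exponential(4, nb)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            ea[0] = eb[0] = 1
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            np.testing.assert_allclose(chi2, ref.test_statistic, atol=1e-6)
            np.testing.assert_allclose(p, ref.p_value, atol=1e-6)

    def test_agrees_with_cox_score_test_without_ties(self, rng):
        """Log-rank chi2 equals the Cox score statistic U^2/I at beta=0."""
        for _ in range(10):
            n = 60
            t = rng.exponential(3, n)
            e = rng.integers(0, 2, n)
            e[:5] = 1
            x = rng.integers(0, 2, n).astype(float)
            if x.sum() in (0, n):
                x[0] = 1 - x[0]
            chi2, _ = logrank_test(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
            # score statistic computed directly from the partial likelihood
            order = np.argsort(t)
            ts, es, xs = t[order], e[order], x[order]
            u = info = 0.0
            for et in np.unique(ts[es == 1]):
                risk = ts >= et
                d = int(np.sum((ts == et) & (es == 1)))
                xbar = xs[risk].mean()
                u += xs[(ts == et) & (es == 1)].sum() - d * xbar
                info += d * xbar * (1 - xbar)
            np.testing.assert_allclose(chi2, u**2 / info, rtol=0.01)


class TestCox:
    def test_duplicated_cohort_gives_unit_hazard_ratio(self, rng):
        t = rng.exponential(3, 40)
        e = rng.integers(0, 2, 40)
        e[:5] = 1
        labels = np.array(["high"] * 40 + ["low"] * 40)
        hr, ci, _ = cox_hr_binary(labels, np.concatenate([t, t]), np.concatenate([e, e]))
        np.testing.assert_allclose(hr, 1.0, atol=1e-9)
        assert ci[0] <= hr <= ci[1]

    def test_relabel_inverts_hazard_ratio(self, rng):
        t = rng.exponential(3, 60)
        e = np.ones(60, dtype=int)
        labels = np.array(["high"] * 30 + ["low"] * 30)
        t[:30] *= 0.5
        hr1, _, _ = cox_hr_binary(labels, t, e)
        hr2, _, _ = cox_hr_binary(labels[::-1], t, e)
        np.testing.assert_allclose(hr1, 1.0 / hr2, atol=1e-9)

    def test_matches_lifelines_on_random_cohorts(self, rng):
        from lifelines import CoxPHFitter

        for _ in range(25):
            n = int(rng.integers(30, 80))
            x = rng.integers(0, 2, n).astype(float)
            if x.sum() in (0, n):
                x[0] = 1 - x[0]
            t = rng.exponential(np.exp(-0.5 * x))  # continuous: no ties
            e = (rng.uniform(size=n) < 0.8).astype(int)
            if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
                continue
            beta, se = cox_fit(x, t, e)
            cph = CoxPHFitter().fit(
                pd.DataFrame({"x": x, "T": t, "E": e}),
                duration_col="T",
                event_col="E",
                fit_options={"precision": 1e-12},
            )
            np.testing.assert_allclose(beta, cph.params_["x"], rtol=0, atol=1e-6)
            np.testing.assert_allclose(se, cph.standard_errors_["x"], rtol=0, atol=1e-6)

    def test_monotone_likelihood_reported(self):
        # all events in the high group: likelihood diverges
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        labels = np.array(["high"] * 3 + ["low"] * 3)
        with pytest.raises((ConvergenceError, ValidationError)):
            cox_hr_binary(labels, t, e)

    def test_continuous_fit_recovers_planted_effect(self, rng):
        betas = []
        for seed in range(5):
            cohort, truth = synthetic.generate_survival_cohort(
                400, GENES[:20], 0.7, censor_frac=0.2, seed=seed, n_genes=100
            )
            z = truth.responsiveness.to_numpy()
            betas.append(cox_fit(z, cohort.time, cohort.event)[0])
        assert abs(np.mean(betas) - 0.7) < 0.1


class TestPerGeneSurvivalZ:
    def test_null_z_scores_standard_normal(self):
        cohort, _ = synthetic.generate_survival_cohort(
            150, GENES[:5], 0.0, censor_frac=0.2, seed=3, n_genes=200
        )
        z = per_gene_survival_z(cohort)
        assert 0.9 < z.std() < 1.1
        assert abs(z.mean()) < 0.2

    def test_planted_gene_scores_positive(self):
        cohort, _ = synthetic.generate_survival_cohort(
            200, GENES[:10], 0.7, censor_frac=0.2, seed=4, n_genes=100
        )
        z = per_gene_survival_z(cohort)
        assert all(z[g] > 0 for g in GENES[:10])
        # planted genes should dominate the top of the ranking
        assert len(set(z.index[:10]) & set(GENES[:10])) >= 5

    def test_identical_expression_identical_z(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(3, 40)
        e = np.ones(40, dtype=int)
        v = rng.normal(8, 1, 40)
        expr = pd.DataFrame([v, v, rng.normal(8, 1, 40)], index=["gA", "gB", "gC"],
                            columns=[f"s{i}" for i in range(40)])
        cohort = SurvivalCohort(tuple(expr.columns), t, e, expression=expr)
        z = per_gene_survival_z(cohort)
        np.testing.assert_allclose(z["gA"], z["gB"], atol=1e-12)


class TestScoringAndSplit:
    def test_single_gene_score_equals_its_values(self):
        expr = pd.DataFrame({"s1": [4.0], "s2": [6.0]}, index=["gA"])
        score = mean_signature_score(expr, GeneSet("s", "", ("gA",)))
        np.testing.assert_allclose(score, [4.0, 6.0])

    def test_two_gene_mean(self):
        expr = pd.DataFrame({"s1": [4.0, 6.0]}, index=["gA", "gB"])
        assert mean_signature_score(expr, GeneSet("s", "", ("gA", "gB")))["s1"] == 5.0

    def test_constant_shift_linearity(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, (5, 6)), index=[f"g{i}" for i in range(5)])
        gs = GeneSet("s", "", ("g0", "g3"))
        s1 = mean_signature_score(expr, gs)
        s2 = mean_signature_score(expr + 2.5, gs)
        np.testing.assert_allclose(s2 - s1, 2.5, atol=1e-12)

    def test_no_matching_genes_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["gA"])
        with pytest.raises(ValidationError, match="no gene"):
            mean_signature_score(expr, GeneSet("s", "", ("zzz",)))

    def test_median_split_even(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert set(labels[labels == "low"].index) == {"a", "b"}

    def test_median_ties_go_low(self):
        labels = median_split(pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd")))
        assert list(labels) == ["low", "low", "low", "high"]

    def test_odd_cohort(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde")))
        assert (labels == "high").sum() == 2

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError):
            median_split(pd.Series([2.0] * 6))


class TestTumorGeneSet:
    def _ranked(self):
        scores = np.arange(100, 0, -1.0)
        return pd.Series(scores, index=GENES[:100])

    def test_small_leading_edge_returned_whole_with_warning(self):
        ranked = self._ranked()
        sig = GeneSet("s", "", tuple(GENES[:5]))
        with pytest.warns(UserWarning, match="only 5"):
            out = select_tumor_gene_set(ranked, sig, k=10)
        assert set(out.members) == set(GENES[:5])

    def test_large_leading_edge_truncated_by_rank(self):
        ranked = self._ranked()
        sig = GeneSet("s", "", tuple(GENES[:40]))
        out = select_tumor_gene_set(ranked, sig, k=30)
        assert out.members == tuple(GENES[:30])

    def test_planted_signature_selected_from_survival_ranking(self):
        hits = 0
        for seed in range(5):
            cohort, _ = synthetic.generate_survival_cohort(
                200, GENES[:20], 0.8, censor_frac=0.2, seed=seed, n_genes=150
            )
            z = per_gene_survival_z(cohort)
            out = select_tumor_gene_set(z, GeneSet("sig", "", tuple(GENES[:20])), k=10)
            hits += set(out.members) <= set(GENES[:20])
        assert hits >= 4


class TestSurvivalBySignature:
    def test_planted_hazard_gives_hr_above_one(self):
        cohort, _ = synthetic.generate_survival_cohort(
            200, GENES[:20], 0.7, censor_frac=0.3, seed=6, n_genes=100
        )
        comp = survival_by_signature(cohort, GeneSet("sig", "", tuple(GENES[:20])))
        assert comp.hr > 1
        assert comp.hr_ci[0] < comp.hr < comp.hr_ci[1]
        assert comp.n_high + comp.n_low == 200

    def test_deterministic_on_fixed_input(self):
        cohort, _ = synthetic.generate_survival_cohort(
            100, GENES[:10], 0.5, censor_frac=0.2, seed=7, n_genes=60
        )
        gs = GeneSet("sig", "", tuple(GENES[:10]))
        c1, c2 = survival_by_signature(cohort, gs), survival_by_signature(cohort, gs)
        assert (c1.hr, c1.chi2, c1.p_logrank) == (c2.hr, c2.chi2, c2.p_logrank)


def test_stouffer_meta_z_combines_cohort_scores():
    zs = pd.DataFrame({"c1": [1.0, -1.0], "c2": [1.0, np.nan]}, index=["gA", "gB"])
    meta = surv.stouffer_meta_z(zs)
    np.testing.assert_allclose(meta["gA"], 2 / np.sqrt(2))
    np.testing.assert_allclose(meta["gB"], -1.0)
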