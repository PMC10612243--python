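"""KM curves, log-rank, responder mapping, Fisher's test and the pipelines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tcellstrat as ts
from tcellstrat.errors import ConfigurationError, DegenerateStatisticError

from oracles import (
    fisher_two_sided_oracle,
    km_oracle,
    logrank_chi2_oracle,
)


class TestKMEstimate:
    def test_no_censoring_is_empirical_survival(self):
        curve = ts.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.at_risk.tolist() == [3, 2, 1]

    def test_hand_product_limit_with_censoring(self):
        """One censoring at t=2: S(1+) = 2/3, then the last patient's event
        at t=3 has n=1 at risk, so S drops to 0."""
        curve = ts.km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        curve = ts.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.allclose(curve.survival, 1.0)

    def test_starts_at_one_non_increasing(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        curve = ts.km_estimate(t, e)
        assert curve.survival_at(min(t) / 2) == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    @pytest.mark.parametrize("n", [1, 3, 7, 10])
    def test_matches_hand_product_limit_on_random_fixtures(self, n):
        rng = np.random.default_rng(n)
        # ties included on purpose: integer-valued times
        t = rng.integers(1, 5, size=n).astype(float)
        e = rng.integers(0, 2, size=n)
        curve = ts.km_estimate(t, e)
        for time, at_risk, d, surv in km_oracle(t, e):
            i = np.where(curve.times == time)[0][0]
            assert curve.at_risk[i] == at_risk
            assert curve.events[i] == d
            assert curve.survival[i] == pytest.approx(surv)

    @pytest.mark.parametrize(
        "times,events",
        [([1.0, -2.0], [1, 1]), ([1.0, 2.0], [1, 2]), ([], [])],
    )
    def test_invalid_inputs_error(self, times, events):
        with pytest.raises(ValueError):
            ts.km_estimate(times, events)


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 1, 1, 1, 1]
        g = ["High"] * 3 + ["Low"] * 3
        res = ts.logrank_test(t, e, g)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, size=20)
        e = rng.integers(0, 2, size=20)
        e[:2] = 1
        g = np.array(["High"] * 10 + ["Low"] * 10)
        a = ts.logrank_test(t, e, g)
        swapped = np.where(g == "High", "Low", "High")
        b = ts.logrank_test(t, e, swapped)
        assert a.logrank_chi2 == pytest.approx(b.logrank_chi2)
        assert a.p_value == pytest.approx(b.p_value)

    def test_p_consistent_with_chi2_tail(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, size=30)
        e = np.ones(30, dtype=int)
        g = ["High"] * 15 + ["Low"] * 15
        res = ts.logrank_test(t, e, g)
        assert res.p_value == pytest.approx(stats.chi2.sf(res.logrank_chi2, 1), abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_hypergeometric_sums(self, seed):
        """Exhaustive sweep of small instances (<= 20 patients, ties and
        censoring included) against the per-event-time brute force."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        t = rng.integers(1, 8, size=n).astype(float)
        e = rng.integers(0, 2, size=n)
        g = np.array(["High", "Low"])[rng.integers(0, 2, size=n)]
        if len(set(g)) < 2 or e.sum() == 0:
            return
        try:
            expected = logrank_chi2_oracle(t, e, g)
        except ZeroDivisionError:
            with pytest.raises(DegenerateStatisticError):
                ts.logrank_test(t, e, g)
            return
        res = ts.logrank_test(t, e, g)
        assert res.logrank_chi2 == pytest.approx(expected, rel=1e-9)

    def test_one_group_empty_errors(self):
        with pytest.raises(ValueError):
            ts.logrank_test([1.0, 2.0], [1, 1], ["High", "High"])

    def test_no_events_errors(self):
        with pytest.raises(DegenerateStatisticError):
            ts.logrank_test([1.0, 2.0], [0, 0], ["High", "Low"])

    def test_median_survival_ordering_with_strong_effect(self):
        rng = np.random.default_rng(5)
        t_hi = rng.exponential(20, size=50)
        t_lo = rng.exponential(2, size=50)
        t = np.concatenate([t_hi, t_lo])
        e = np.ones(100, dtype=int)
        g = ["High"] * 50 + ["Low"] * 50
        res = ts.logrank_test(t, e, g)
        assert res.median_survival("High") > res.median_survival("Low")
        assert res.p_value < 1e-6


class TestClassifyResponse:
    def test_mapping(self):
        assert [ts.classify_response(x) for x in ["PR", "CR", "PD", "SD"]] == [
            "R", "R", "NR", "excluded",
        ]

    def test_missing_is_excluded(self):
        assert ts.classify_response(None) == "excluded"
        assert ts.classify_response(float("nan")) == "excluded"

    @pytest.mark.parametrize("bad", ["pr", "Responder", "", "CRX"])
    def test_unknown_label_errors(self, bad):
        with pytest.raises(ValueError):
            ts.classify_response(bad)


class TestFisher:
    def test_diagonal_2x2_is_one_third(self):
        """Margins (2,2)/(2,2): the observed diagonal table and its mirror
        each have probability 1/6, so the two-sided p is 1/3."""
        odds, p, degenerate = ts.fisher_exact_2x2(np.array([[2, 0], [0, 2]]))
        assert not degenerate
        assert p == pytest.approx(1 / 3, rel=1e-12)
        assert odds == float("inf")

    def test_balanced_table_p_one(self):
        odds, p, degenerate = ts.fisher_exact_2x2(np.array([[5, 5], [5, 5]]))
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_row_transpose_symmetry(self):
        a = ts.fisher_exact_2x2(np.array([[7, 2], [3, 8]]))
        b = ts.fisher_exact_2x2(np.array([[3, 8], [7, 2]]))
        assert a[1] == pytest.approx(b[1], rel=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_enumeration_for_totals_up_to_30(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            table = rng.integers(0, 9, size=(2, 2))
            if table.sum() <= 30 and table.sum(0).all() and table.sum(1).all():
                break
        _, p, degenerate = ts.fisher_exact_2x2(table)
        assert not degenerate
        assert p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-10)

    def test_degenerate_margin_flagged_p_one(self):
        odds, p, degenerate = ts.fisher_exact_2x2(np.array([[0, 0], [3, 4]]))
        assert degenerate and p == 1.0

    def test_fisher_response_counts_and_exclusions(self):
        labels = pd.Series(
            ["High", "High", "High", "Low", "Low", "Low", "Excluded"],
            index=[f"P{i}" for i in range(7)],
        )
        labeling = ts.GroupLabeling(
            labels=labels, exclusion_fraction=0.0, lower_threshold=0, upper_threshold=1
        )
        responses = pd.Series(
            ["PR", "PD", "SD", "CR", "PD", None, "PR"],
            index=labels.index,
        )
        table = ts.fisher_response(labeling, responses)
        assert table.counts.tolist() == [[1, 1], [1, 1]]
        assert table.excluded_labels == 2  # one SD, one missing (Excluded not counted)


class TestPipelines:
    def test_planted_effect_orders_median_survival(self):
        """Planted negative log-HR: the High-score group survives longer in
        nearly every seed."""
        sig = ts.bundled_signatures()["C0"]
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = ts.SimulationConfig(
                seed=seed, n_patients=500, log_hr_beta=-0.8, censor_rate=0.2
            )
            cohort = ts.generate_survival_cohort(cfg)
            res = ts.score_split_logrank(cohort, sig)
            if res.median_survival("High") > res.median_survival("Low"):
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_survival_pipeline_reports_all_strata(self, survival_cohort):
        sig = ts.bundled_signatures()["C0"]
        reports = ts.run_survival_pipeline(survival_cohort, sig)
        assert set(reports) == {"dp", "dp_cd28neg", "dp_cd28pos"}
        for rep in reports.values():
            assert rep.labeling.n_high + rep.labeling.n_low <= rep.n_patients
            assert {"CD8A", "PDCD1", "CD28"} <= set(rep.thresholds)
            assert 0 <= rep.result.p_value <= 1

    def test_report_thresholds_reproduce_group_sizes(self, survival_cohort):
        sig = ts.bundled_signatures()["C0"]
        config = ts.PipelineConfig(exclusion_fraction=0.10, strata=("dp",))
        rep = ts.run_survival_pipeline(survival_cohort, sig, config)["dp"]
        # re-apply the recorded gate thresholds by hand
        filtered = ts.filter_min_survival(survival_cohort)
        expr = filtered.expression
        in_dp = (expr.loc["CD8A"] > rep.thresholds["CD8A"]) & (
            expr.loc["PDCD1"] > rep.thresholds["PDCD1"]
        )
        assert int(in_dp.sum()) == rep.n_patients
        scores = ts.score_signature_log2(filtered.subset(expr.columns[in_dp]), sig)
        labeling = ts.split_high_low(scores, 0.10)
        assert labeling.n_high == rep.labeling.n_high
        assert labeling.n_low == rep.labeling.n_low

    def test_response_pipeline_counts_match_totals(self):
        cohort = ts.generate_response_cohort(
            ts.SimulationConfig(seed=4, n_patients=400, logistic_beta=1.5)
        )
        sig = ts.bundled_signatures()["C0"]
        config = ts.PipelineConfig(score_method="zscore", exclusion_fraction=0.10)
        reports = ts.run_response_pipeline(cohort, sig, config)
        for rep in reports.values():
            table = rep.result
            included = table.n_included + table.excluded_labels
            assert included == rep.labeling.n_high + rep.labeling.n_low

    def test_planted_response_effect_detected(self):
        cohort = ts.generate_response_cohort(
            ts.SimulationConfig(seed=8, n_patients=500, logistic_beta=3.0, sd_fraction=0.1)
        )
        sig = ts.bundled_signatures()["C0"]
        reports = ts.run_response_pipeline(
            cohort, sig, ts.PipelineConfig(score_method="zscore", strata=("dp",))
        )
        assert reports["dp"].result.p_value < 0.05
        assert reports["dp"].result.odds_ratio > 1

    def test_power_monotone_in_effect_size(self):
        """Detection rate of the score-split-logrank chain increases with
        the magnitude of the planted log hazard ratio."""
        sig = ts.bundled_signatures()["C0"]
        rates = []
        for beta in (0.0, -0.4, -1.2):
            hits = 0
            for seed in range(25):
                cfg = ts.SimulationConfig(
                    seed=seed, n_patients=300, log_hr_beta=beta, censor_rate=0.2
                )
                cohort = ts.generate_survival_cohort(cfg)
                if ts.score_split_logrank(cohort, sig).p_value < 0.05:
                    hits += 1
            rates.append(hits / 25)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]
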