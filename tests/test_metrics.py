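import json
import math

import numpy as np
import pytest

import alertvalue as av
import _oracles as oracle
from conftest import make_cohort, random_cohort


@pytest.fixture
def designed(fixture20):
    rule = av.threshold_for_prevalence(fixture20, "score", 0.20)
    return fixture20, rule, av.apply_rule(fixture20, rule)


class TestStrategyOutcomes:
    @pytest.mark.parametrize("tree,strategy,expected", [
        ("tree1", "rule", (0.10, 0.10, 0.15, 0.65)),
        ("tree2", "rule", (0.20, 0.25, 0.05, 0.50)),
        ("tree1", "usual_care", (0.15, 0.20, 0.10, 0.55)),
        ("tree2", "usual_care", (0.15, 0.20, 0.10, 0.55)),
        ("tree1", "alerts_for_all", (0.25, 0.75, 0.0, 0.0)),
        ("tree1", "alerts_for_none", (0.0, 0.0, 0.25, 0.75)),
        ("tree2", "alerts_for_none", (0.15, 0.20, 0.10, 0.55)),
    ])
    def test_fixture_terminal_probabilities(self, designed, tree, strategy,
                                            expected):
        cohort, _, alerts = designed
        out = av.strategy_outcomes(cohort, alerts, tree=tree, strategy=strategy)
        assert (out.p_tp, out.p_fp, out.p_fn, out.p_tn) == \
            pytest.approx(expected)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            cohort = random_cohort(rng)
            rule = av.threshold_for_prevalence(cohort, "m", 0.2)
            alerts = av.apply_rule(cohort, rule)
            for tree in av.TREE1, av.TREE2:
                for strat in ("rule", "usual_care", "alerts_for_all",
                              "alerts_for_none"):
                    out = av.strategy_outcomes(cohort, alerts, tree=tree,
                                               strategy=strat)
                    assert out.total == pytest.approx(1.0, abs=1e-12)

    def test_tree2_tp_never_below_usual_care(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            cohort = random_cohort(rng)
            alerts = av.apply_rule(
                cohort, av.threshold_for_prevalence(cohort, "m", 0.1))
            uc = av.strategy_outcomes(cohort, strategy="usual_care")
            t2 = av.strategy_outcomes(cohort, alerts, tree="tree2")
            assert t2.p_tp >= uc.p_tp - 1e-15

    def test_tree2_reduces_to_tree1_without_csos(self):
        rng = np.random.default_rng(12)
        n = 100
        cohort = make_cohort((rng.random(n) < 0.3).astype(int), [0] * n,
                             rng.random(n))
        alerts = av.apply_rule(
            cohort, av.threshold_for_prevalence(cohort, "m", 0.15))
        t1 = av.strategy_outcomes(cohort, alerts, tree="tree1")
        t2 = av.strategy_outcomes(cohort, alerts, tree="tree2")
        assert (t1.p_tp, t1.p_fp, t1.p_fn, t1.p_tn) == \
            (t2.p_tp, t2.p_fp, t2.p_fn, t2.p_tn)

    def test_misaligned_alert_vector(self, fixture20):
        with pytest.raises(ValueError, match="align"):
            av.strategy_outcomes(fixture20, np.zeros(7))


class TestErdNnb:
    def test_fixture_erd(self, designed):
        cohort, _, alerts = designed
        assert av.expected_risk_difference(cohort, alerts) == pytest.approx(0.20)

    def test_all_zero_alerts_zero_erd(self, fixture20):
        assert av.expected_risk_difference(fixture20, np.zeros(20)) == 0.0

    def test_alerts_on_every_uncovered_eol(self, fixture20):
        alerts = (fixture20.eol & (1 - fixture20.cso))
        assert av.expected_risk_difference(fixture20, alerts) == \
            pytest.approx(0.40)

    def test_erd_without_eol_records_raises(self):
        cohort = make_cohort([0, 0], [1, 0], [0.1, 0.2])
        with pytest.raises(av.UndefinedMetricError):
            av.expected_risk_difference(cohort, [1, 0])

    def test_fixture_nnb(self, designed):
        cohort, _, alerts = designed
        assert av.number_needed_to_benefit(cohort, alerts) == pytest.approx(4.0)

    def test_nnb_times_erd_identity(self, designed):
        cohort, _, alerts = designed
        nnb = av.number_needed_to_benefit(cohort, alerts)
        erd = av.expected_risk_difference(cohort, alerts)
        prevalence = alerts.mean()
        p_eol = cohort.eol.mean()
        assert nnb * erd == pytest.approx(prevalence / p_eol)  # 0.20/0.25

    def test_nnb_undefined_when_no_new_beneficiaries(self, fixture20):
        # alert only records that are EOL-with-CSO: denominator is zero
        alerts = (fixture20.eol & fixture20.cso)
        assert math.isnan(av.number_needed_to_benefit(fixture20, alerts))

    def test_erd_monotone_in_alert_set(self):
        rng = np.random.default_rng(13)
        cohort = random_cohort(rng, n=200, allow_ties=False)
        erds = []
        for p in (0.05, 0.1, 0.2, 0.3, 0.5):
            alerts = av.apply_rule(
                cohort, av.threshold_for_prevalence(cohort, "m", p))
            erds.append(av.expected_risk_difference(cohort, alerts))
        assert all(b >= a for a, b in zip(erds, erds[1:]))


class TestExchangeRatesAndNetBenefit:
    def test_fixture_observed_rate(self, fixture20):
        assert av.observed_exchange_rate(fixture20) == pytest.approx(0.75)

    def test_printed_counts_rate(self):
        # a cohort whose usual-care TP/FP counts match the published table
        eol = [1] * 2599 + [0] * 5049
        cso = [1] * (2599 + 5049)
        cohort = make_cohort(eol, cso, [0.5] * len(eol))
        assert round(av.observed_exchange_rate(cohort), 3) == 0.515

    def test_rate_all_csos_at_eol_but_one(self):
        n_cso = 6
        eol = [1] * (n_cso - 1) + [0] + [0] * 4
        cso = [1] * n_cso + [0] * 4
        cohort = make_cohort(eol, cso, [0.1] * 10)
        assert av.observed_exchange_rate(cohort) == n_cso - 1

    def test_rate_undefined_without_fps(self):
        cohort = make_cohort([1, 1, 0], [1, 0, 0], [0.1, 0.2, 0.3])
        with pytest.raises(av.UndefinedMetricError):
            av.observed_exchange_rate(cohort)

    def test_usual_care_nb_zero_under_observed_rate(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            cohort = random_cohort(rng)
            uc = av.strategy_outcomes(cohort, strategy="usual_care")
            nb = av.net_benefit(uc, av.observed_exchange_rate(cohort))
            assert nb == pytest.approx(0.0, abs=1e-15)

    def test_fixture_rule_nb(self, designed):
        cohort, _, alerts = designed
        out = av.strategy_outcomes(cohort, alerts, tree="tree2")
        assert av.net_benefit(out, 0.75) == pytest.approx(0.0125)

    def test_zero_rate_nb_is_benefit(self, designed):
        cohort, _, alerts = designed
        out = av.strategy_outcomes(cohort, alerts, tree="tree2")
        assert av.net_benefit(out, 0.0) == out.p_tp

    @pytest.mark.parametrize("t,expected", [
        (0.5, 1.0), (0.0, 0.0), (0.478, 0.916)])
    def test_threshold_odds(self, t, expected):
        assert av.threshold_exchange_rate(t) == pytest.approx(expected,
                                                              abs=5e-4)

    def test_threshold_one_is_domain_error(self):
        with pytest.raises(ValueError):
            av.threshold_exchange_rate(1.0)


class TestAccuracyBattery:
    def test_fixture_values(self, designed):
        cohort, _, alerts = designed
        acc = av.accuracy_battery(cohort, alerts, "score")
        assert acc.ppv == pytest.approx(0.5)
        assert acc.sensitivity == pytest.approx(0.4)
        assert acc.specificity == pytest.approx(13 / 15)

    def test_perfect_risks(self):
        cohort = make_cohort([1, 0, 1, 0], [0] * 4, [1.0, 0.0, 1.0, 0.0])
        acc = av.accuracy_battery(cohort, [1, 0, 1, 0], "m")
        assert acc.c_statistic == 1.0
        assert acc.brier == 0.0

    def test_constant_risks_c_half(self):
        cohort = make_cohort([1, 0, 1, 0], [0] * 4, [0.4] * 4)
        assert av.c_statistic(cohort.risks("m"), cohort.eol) == 0.5

    def test_empty_class_gives_nan_not_failure(self):
        cohort = make_cohort([1, 1], [0, 0], [0.2, 0.8])
        acc = av.accuracy_battery(cohort, [1, 1], "m")
        assert math.isnan(acc.npv)  # no alert-negatives
        assert math.isnan(acc.specificity)  # no non-EOL
        assert acc.ppv == 1.0

    def test_c_statistic_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(15)
        for _ in range(10):
            n = 200
            eol = (rng.random(n) < 0.3).astype(int)
            if eol.sum() in (0, n):
                continue
            risks = np.round(rng.random(n), 1)
            assert av.c_statistic(risks, eol) == pytest.approx(
                roc_auc_score(eol, risks), abs=1e-12)


class TestUtilityReport:
    def test_fixture_composition(self, fixture20):
        rule = av.threshold_for_prevalence(fixture20, "score", 0.20)
        rep = av.utility_report(fixture20, rule, tree="tree2",
                                exchange_rate="observed")
        assert rep.erd == pytest.approx(0.20)
        assert rep.nnb == pytest.approx(4.0)
        assert rep.net_benefit == pytest.approx(0.0125)
        assert rep.benefit - rep.harm == pytest.approx(rep.net_benefit)
        assert rep.exchange_rate_mode == "observed"

    def test_usual_care_report_nb_zero(self):
        rng = np.random.default_rng(16)
        cohort = random_cohort(rng)
        uc = av.usual_care_report(cohort)
        assert uc["net_benefit"] == pytest.approx(0.0, abs=1e-15)

    def test_report_serializes(self, fixture20):
        rule = av.threshold_for_prevalence(fixture20, "score", 0.20)
        rep = av.utility_report(fixture20, rule)
        payload = json.loads(rep.to_json())
        assert payload["erd"] == pytest.approx(0.20)
        assert payload["rule"]["model_name"] == "score"

    def test_table_shape_and_duplicate_models(self, fixture20):
        dup = fixture20.with_risk_column("score2", fixture20.risks("score"))
        reports = [
            av.utility_report(
                dup, av.threshold_for_prevalence(dup, m, 0.2))
            for m in ("score", "score2")]
        table = av.reports_to_table(reports,
                                    usual_care=av.usual_care_report(dup))
        assert list(table.columns) == ["score", "score2", "usual_care"]
        # identical risk columns give identical report columns
        assert table["score"].equals(table["score2"])
        assert table.loc["net_benefit", "usual_care"] == \
            pytest.approx(0.0, abs=1e-15)


class TestOracleEquivalence:
    def test_metrics_match_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            cohort = random_cohort(rng)
            rule = av.threshold_for_prevalence(
                cohort, "m", float(rng.uniform(0.05, 0.6)))
            alerts = av.apply_rule(cohort, rule)
            eol, cso = cohort.eol, cohort.cso
            assert av.expected_risk_difference(cohort, alerts) == \
                pytest.approx(oracle.erd(eol, cso, alerts), abs=1e-12)
            got = av.number_needed_to_benefit(cohort, alerts)
            want = oracle.nnb(eol, cso, alerts)
            assert (math.isnan(got) and math.isnan(want)) or \
                got == pytest.approx(want, abs=1e-12)
            for tree in "tree1", "tree2":
                out = av.strategy_outcomes(cohort, alerts, tree=tree)
                assert (out.p_tp, out.p_fp, out.p_fn, out.p_tn) == \
                    pytest.approx(oracle.outcomes(eol, cso, alerts, tree,
                                                  "rule"), abs=1e-12)
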