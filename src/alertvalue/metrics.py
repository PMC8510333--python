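"""Decision-analytic utility metrics for alert rules.

The core quantities, all defined on the joint distribution of
(Alert, EOL, CSO) over a cohort of hospitalizations:

* expected risk difference
  ``eRD = P(Alert or CSO | EOL) - P(CSO | EOL)`` — the gain, among
  end-of-life hospitalizations, in code-status documentation if every alert
  led to a CSO, over the usual-care rate;
* number needed to benefit
  ``NNB = P(Alert) / (P(Alert & EOL) - P(Alert & EOL & CSO))`` — alerts per
  additional beneficial outcome beyond usual care;
* net benefit ``NB_S = P(TP | S) - P(FP | S) * exchange_rate`` for a
  strategy S, where the exchange rate weighs the harm of an unnecessary
  action (FP) against a missed one;
* the observed exchange rate
  ``P(TP | usual care) / P(FP | usual care)``, i.e. the TP:FP ratio
  revealed by clinicians' factual code-status documentation. Substituted
  into NB it sets usual care's net benefit to zero by construction.

Two decision trees translate alerts into actions. Tree 1 is the
conventional decision-curve model: an alert causes the action, no alert
means no action. Tree 2 augments usual care: an alert causes the action,
but without an alert the action still happens whenever it factually did.
A TP is an action (CSO) for an end-of-life hospitalization; an FP is an
action for a hospitalization not at the end of life.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .alerting import AlertRule, apply_rule
from .cohort import Cohort

TREE1 = "tree1"
TREE2 = "tree2"
TREES = (TREE1, TREE2)

RULE = "rule"
USUAL_CARE = "usual_care"
ALERTS_FOR_ALL = "alerts_for_all"
ALERTS_FOR_NONE = "alerts_for_none"
STRATEGIES = (RULE, USUAL_CARE, ALERTS_FOR_ALL, ALERTS_FOR_NONE)


class UndefinedMetricError(ValueError):
    """A metric's defining conditional has an empty denominator."""


@dataclass(frozen=True)
class StrategyOutcome:
    """Joint terminal-node probabilities of one strategy under one tree."""

    tree: str
    strategy: str
    p_tp: float
    p_fp: float
    p_fn: float
    p_tn: float

    @property
    def total(self) -> float:
        return self.p_tp + self.p_fp + self.p_fn + self.p_tn


def _check_alignment(cohort: Cohort, alerts) -> np.ndarray:
    a = np.asarray(alerts)
    if a.shape != (cohort.n,):
        raise ValueError(f"alert vector of length {a.shape} does not align "
                         f"with cohort of {cohort.n} records")
    return a.astype(bool)


def _effective_action(cohort: Cohort, alerts, tree: str,
                      strategy: str) -> np.ndarray:
    """The action indicator implied by a strategy under a decision tree."""
    cso = cohort.cso.astype(bool)
    if strategy == USUAL_CARE:
        return cso
    if strategy == ALERTS_FOR_ALL:
        a = np.ones(cohort.n, dtype=bool)
    elif strategy == ALERTS_FOR_NONE:
        a = np.zeros(cohort.n, dtype=bool)
    elif strategy == RULE:
        if alerts is None:
            raise ValueError("strategy 'rule' requires an alert vector")
        a = _check_alignment(cohort, alerts)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if tree == TREE1:
        return a
    if tree == TREE2:
        return a | cso
    raise ValueError(f"unknown tree {tree!r}")


def strategy_outcomes(cohort: Cohort, alerts=None, tree: str = TREE2,
                      strategy: str = RULE) -> StrategyOutcome:
    """TP/FP/FN/TN joint probabilities of a strategy under a decision tree."""
    if cohort.n == 0:
        raise ValueError("empty cohort")
    eol = cohort.eol.astype(bool)
    act = _effective_action(cohort, alerts, tree, strategy)
    n = float(cohort.n)
    return StrategyOutcome(
        tree=tree, strategy=strategy,
        p_tp=float((act & eol).sum()) / n,
        p_fp=float((act & ~eol).sum()) / n,
        p_fn=float((~act & eol).sum()) / n,
        p_tn=float((~act & ~eol).sum()) / n,
    )


def expected_risk_difference(cohort: Cohort, alerts) -> float:
    """eRD = P(Alert or CSO | EOL) - P(CSO | EOL); non-negative."""
    a = _check_alignment(cohort, alerts)
    eol = cohort.eol.astype(bool)
    cso = cohort.cso.astype(bool)
    n_eol = int(eol.sum())
    if n_eol == 0:
        raise UndefinedMetricError("eRD undefined: no EOL records")
    return float((a & ~cso & eol).sum()) / n_eol


def number_needed_to_benefit(cohort: Cohort, alerts) -> float:
    """NNB = P(Alert) / P(Alert & EOL & not CSO); NaN when no one newly benefits.

    The NaN (rather than an exception) lets sensitivity grids evaluate
    cells where a rule adds nothing over usual care.
    """
    a = _check_alignment(cohort, alerts)
    eol = cohort.eol.astype(bool)
    cso = cohort.cso.astype(bool)
    newly = int((a & eol & ~cso).sum())
    if newly == 0:
        return math.nan
    return float(a.sum()) / newly


def observed_exchange_rate(cohort: Cohort) -> float:
    """Usual-care TP:FP ratio — N(CSO & EOL) / N(CSO & not EOL)."""
    eol = cohort.eol.astype(bool)
    cso = cohort.cso.astype(bool)
    fp = int((cso & ~eol).sum())
    if fp == 0:
        raise UndefinedMetricError(
            "observed exchange rate undefined: no usual-care false positives")
    return float((cso & eol).sum()) / fp


def threshold_exchange_rate(threshold: float) -> float:
    """Conventional decision-curve odds at a risk threshold: t / (1 - t)."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    return threshold / (1.0 - threshold)


def net_benefit(outcome: StrategyOutcome, exchange_rate: float) -> float:
    """NB = P(TP) - P(FP) * exchange_rate."""
    if exchange_rate < 0:
        raise ValueError("exchange rate must be non-negative")
    return outcome.p_tp - outcome.p_fp * exchange_rate


@dataclass(frozen=True)
class AccuracyBattery:
    """Threshold-level accuracy of an alert rule for the EOL outcome.

    Conditionals with an empty class come back as NaN rather than failing
    the whole battery.
    """

    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    c_statistic: float
    brier: float


def c_statistic(risks: np.ndarray, eol: np.ndarray) -> float:
    """Rank-based C-statistic (ties credited 1/2); NaN if a class is empty."""
    risks = np.asarray(risks, dtype=float)
    eol = np.asarray(eol).astype(bool)
    n1 = int(eol.sum())
    n0 = eol.size - n1
    if n1 == 0 or n0 == 0:
        return math.nan
    ranks = rankdata(risks)
    u = ranks[eol].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def brier_score(risks: np.ndarray, eol: np.ndarray) -> float:
    """Mean squared difference between predicted risk and the EOL indicator."""
    risks = np.asarray(risks, dtype=float)
    eol = np.asarray(eol, dtype=float)
    return float(np.mean((risks - eol) ** 2))


def accuracy_battery(cohort: Cohort, alerts, model_name: str) -> AccuracyBattery:
    """PPV/NPV/sensitivity/specificity of the alert, plus C and Brier."""
    a = _check_alignment(cohort, alerts)
    eol = cohort.eol.astype(bool)
    risks = cohort.risks(model_name)

    def _cond(num: np.ndarray, den: np.ndarray) -> float:
        d = int(den.sum())
        return float(num.sum()) / d if d else math.nan

    return AccuracyBattery(
        ppv=_cond(a & eol, a),
        npv=_cond(~a & ~eol, ~a),
        sensitivity=_cond(a & eol, eol),
        specificity=_cond(~a & ~eol, ~eol),
        c_statistic=c_statistic(risks, eol),
        brier=brier_score(risks, eol),
    )


@dataclass(frozen=True)
class UtilityReport:
    """Everything a Table-4-style column reports for one alert rule.

    ``benefit`` is P(TP) of the rule's strategy and ``harm`` is already
    exchange-rate weighted (P(FP) * rate), so ``net_benefit`` reads off as
    benefit - harm.
    """

    rule: AlertRule
    tree: str
    n_alerts: int
    erd: float
    nnb: float
    benefit: float
    harm: float
    net_benefit: float
    exchange_rate: float
    exchange_rate_mode: str
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    c_statistic: float
    brier: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rule"] = asdict(self.rule)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def resolve_exchange_rate(cohort: Cohort, exchange_rate,
                          rule: AlertRule | None = None) -> tuple[float, str]:
    """Resolve an exchange-rate spec to (value, provenance).

    ``exchange_rate`` is ``"observed"`` (revealed-preference TP:FP ratio of
    usual care), ``"threshold"`` (odds at the rule's risk threshold), or a
    non-negative number taken as-is.
    """
    if exchange_rate == "observed":
        return observed_exchange_rate(cohort), "observed"
    if exchange_rate == "threshold":
        if rule is None:
            raise ValueError("threshold exchange rate needs a rule")
        return threshold_exchange_rate(rule.threshold), "threshold_odds"
    value = float(exchange_rate)
    if value < 0:
        raise ValueError("exchange rate must be non-negative")
    return value, "user_supplied"


def utility_report(cohort: Cohort, rule: AlertRule, tree: str = TREE2,
                   exchange_rate="observed") -> UtilityReport:
    """Bundle eRD, NNB, net benefit and the accuracy battery for one rule."""
    alerts = apply_rule(cohort, rule)
    rate, mode = resolve_exchange_rate(cohort, exchange_rate, rule)
    outcome = strategy_outcomes(cohort, alerts, tree=tree, strategy=RULE)
    acc = accuracy_battery(cohort, alerts, rule.model_name)
    harm = outcome.p_fp * rate
    return UtilityReport(
        rule=rule, tree=tree, n_alerts=int(alerts.sum()),
        erd=expected_risk_difference(cohort, alerts),
        nnb=number_needed_to_benefit(cohort, alerts),
        benefit=outcome.p_tp, harm=harm,
        net_benefit=outcome.p_tp - harm,
        exchange_rate=rate, exchange_rate_mode=mode,
        ppv=acc.ppv, npv=acc.npv,
        sensitivity=acc.sensitivity, specificity=acc.specificity,
        c_statistic=acc.c_statistic, brier=acc.brier,
    )


def usual_care_report(cohort: Cohort, exchange_rate="observed") -> dict:
    """The comparator column: usual care's benefit, harm and net benefit."""
    rate, mode = resolve_exchange_rate(cohort, exchange_rate)
    outcome = strategy_outcomes(cohort, tree=TREE2, strategy=USUAL_CARE)
    harm = outcome.p_fp * rate
    return {
        "strategy": USUAL_CARE,
        "benefit": outcome.p_tp,
        "harm": harm,
        "net_benefit": outcome.p_tp - harm,
        "exchange_rate": rate,
        "exchange_rate_mode": mode,
    }


_TABLE_ROWS = [
    ("alert_prevalence", lambda r: r.rule.achieved_prevalence),
    ("n_alerts", lambda r: r.n_alerts),
    ("risk_threshold", lambda r: r.rule.threshold),
    ("erd", lambda r: r.erd),
    ("nnb", lambda r: r.nnb),
    ("benefit", lambda r: r.benefit),
    ("harm", lambda r: r.harm),
    ("net_benefit", lambda r: r.net_benefit),
    ("ppv", lambda r: r.ppv),
    ("npv", lambda r: r.npv),
    ("sensitivity", lambda r: r.sensitivity),
    ("specificity", lambda r: r.specificity),
    ("c_statistic", lambda r: r.c_statistic),
    ("brier", lambda r: r.brier),
    ("exchange_rate", lambda r: r.exchange_rate),
]


def reports_to_table(reports: Sequence[UtilityReport],
                     usual_care: dict | None = None) -> pd.DataFrame:
    """Arrange reports as a metrics-by-strategies table (Table-4 shape)."""
    cols: dict = {}
    for r in reports:
        cols[r.rule.model_name] = {name: fn(r) for name, fn in _TABLE_ROWS}
    if usual_care is not None:
        uc = {name: math.nan for name, _ in _TABLE_ROWS}
        uc.update({k: v for k, v in usual_care.items()
                   if k in {n for n, _ in _TABLE_ROWS}})
        cols[USUAL_CARE] = uc
    table = pd.DataFrame(cols)
    table.index.name = "metric"
    return table.reindex([name for name, _ in _TABLE_ROWS])
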