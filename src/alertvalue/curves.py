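"""Decision curves: net benefit over grids of risk threshold or alert
prevalence, under either decision tree and either exchange-rate convention.

Prevalence-indexed curves recompute each model's threshold at every grid
point, so at the same x different models generally use different
thresholds — that is the point of comparing models at equal resource use.
The output is tidy/long tabular data; plotting is left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics
from .alerting import AlertRule, apply_rule, rule_at_threshold, threshold_for_prevalence
from .cohort import Cohort
from .metrics import (ALERTS_FOR_ALL, ALERTS_FOR_NONE, RULE, TREE2, USUAL_CARE,
                      net_benefit, strategy_outcomes)

RISK_THRESHOLD = "risk_threshold"
ALERT_PREVALENCE = "alert_prevalence"

THRESHOLD_ODDS = "threshold_odds"
OBSERVED = "observed"

REFERENCE_STRATEGIES = (USUAL_CARE, ALERTS_FOR_ALL, ALERTS_FOR_NONE)

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.01, 1.00, 0.01), 10))
DEFAULT_PREVALENCE_GRID = tuple(np.round(np.arange(0.05, 0.505, 0.01), 10))
REGION_OF_INTEREST = (0.05, 0.20)


@dataclass(frozen=True)
class CurveSpec:
    """What to compute: axis, tree, exchange-rate convention, grid, strategies.

    ``exchange_rate_mode`` is ``"threshold_odds"``, ``"observed"``, or a
    fixed non-negative number. ``strategies`` lists model names and/or the
    reference strategies; ``None`` means all cohort models plus the three
    references.
    """

    x_axis: str = ALERT_PREVALENCE
    tree: str = TREE2
    exchange_rate_mode: object = OBSERVED
    grid: tuple[float, ...] | None = None
    strategies: tuple[str, ...] | None = None
    region_of_interest: tuple[float, float] = REGION_OF_INTEREST

    def resolved_grid(self) -> tuple[float, ...]:
        g = self.grid
        if g is None:
            g = (DEFAULT_THRESHOLD_GRID if self.x_axis == RISK_THRESHOLD
                 else DEFAULT_PREVALENCE_GRID)
        g = tuple(float(v) for v in g)
        arr = np.asarray(g)
        if arr.size == 0 or (np.diff(arr) <= 0).any() or \
                arr[0] <= 0.0 or arr[-1] >= 1.0:
            raise ValueError("grid must be strictly increasing within (0, 1)")
        return g

    def resolved_strategies(self, cohort: Cohort) -> tuple[str, ...]:
        if self.strategies is not None:
            return tuple(self.strategies)
        return tuple(cohort.model_names) + REFERENCE_STRATEGIES


@dataclass
class DecisionCurve:
    """A computed curve family, one net-benefit series per strategy."""

    spec: CurveSpec
    table: pd.DataFrame  # columns: x_axis, x, tree, er_mode, strategy,
    #                      threshold, exchange_rate, net_benefit, degenerate

    def values(self, strategy: str) -> np.ndarray:
        sub = self.table[self.table["strategy"] == strategy]
        return sub.sort_values("x")["net_benefit"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _model_rules_at(cohort: Cohort, models: Sequence[str], x_axis: str,
                    x: float) -> dict[str, AlertRule]:
    if x_axis == RISK_THRESHOLD:
        return {m: rule_at_threshold(cohort, m, x) for m in models}
    return {m: threshold_for_prevalence(cohort, m, x) for m in models}


def compute_curve(cohort: Cohort, spec: CurveSpec) -> DecisionCurve:
    """Evaluate net benefit for every (grid point, strategy) pair.

    Exchange-rate resolution at a grid point x:

    * ``observed`` / fixed number — one rate for all strategies;
    * ``threshold_odds`` on a threshold axis — x / (1 - x) for all
      strategies (the conventional decision curve);
    * ``threshold_odds`` on a prevalence axis — each model uses the odds of
      its own prevalence-derived threshold; reference strategies, having no
      threshold of their own, use the mean of the model odds at that point.
    """
    grid = spec.resolved_grid()
    strategies = spec.resolved_strategies(cohort)
    models = [s for s in strategies if s not in REFERENCE_STRATEGIES]
    if spec.x_axis not in (RISK_THRESHOLD, ALERT_PREVALENCE):
        raise ValueError(f"unknown x_axis {spec.x_axis!r}")

    er_mode = spec.exchange_rate_mode
    fixed_rate: float | None = None
    if er_mode == OBSERVED:
        fixed_rate = metrics.observed_exchange_rate(cohort)
        mode_label = OBSERVED
    elif er_mode == THRESHOLD_ODDS:
        mode_label = THRESHOLD_ODDS
    else:
        fixed_rate = float(er_mode)
        if fixed_rate < 0:
            raise ValueError("fixed exchange rate must be non-negative")
        mode_label = "fixed"

    ref_outcomes = {s: strategy_outcomes(cohort, tree=spec.tree, strategy=s)
                    for s in strategies if s in REFERENCE_STRATEGIES}

    rows = []
    for x in grid:
        rules = _model_rules_at(cohort, models, spec.x_axis, x)
        if mode_label == THRESHOLD_ODDS:
            if spec.x_axis == RISK_THRESHOLD:
                model_rates = {m: metrics.threshold_exchange_rate(x)
                               for m in models}
            else:
                model_rates = {
                    m: metrics.threshold_exchange_rate(r.threshold)
                    if r.threshold < 1.0 else math.inf
                    for m, r in rules.items()}
            ref_rate = (float(np.mean(list(model_rates.values())))
                        if model_rates else math.nan)
        else:
            model_rates = {m: fixed_rate for m in models}
            ref_rate = fixed_rate

        for s in strategies:
            if s in REFERENCE_STRATEGIES:
                out = ref_outcomes[s]
                rate = ref_rate
                thr = math.nan
                degen = False
            else:
                rule = rules[s]
                out = strategy_outcomes(cohort, apply_rule(cohort, rule),
                                        tree=spec.tree, strategy=RULE)
                rate = model_rates[s]
                thr = rule.threshold
                degen = rule.degenerate
            nb = (out.p_tp - out.p_fp * rate if math.isfinite(rate)
                  else (out.p_tp if out.p_fp == 0.0 else -math.inf))
            rows.append({"x_axis": spec.x_axis, "x": x, "tree": spec.tree,
                         "er_mode": mode_label, "strategy": s,
                         "threshold": thr, "exchange_rate": rate,
                         "net_benefit": nb, "degenerate": degen})
    table = pd.DataFrame(rows)
    table.attrs["region_of_interest"] = spec.region_of_interest
    return DecisionCurve(spec=spec, table=table)


def best_strategy_over_grid(curve: DecisionCurve) -> pd.DataFrame:
    """Per-grid-point argmax strategy.

    Ties are broken toward usual care, then by the order the strategies
    appear in the curve.
    """
    table = curve.table
    if table.empty:
        raise ValueError("empty curve")
    order = list(dict.fromkeys(table["strategy"]))
    rows = []
    for x, sub in table.groupby("x", sort=True):
        nbs = {r.strategy: r.net_benefit for r in sub.itertuples()}
        best_nb = max(nbs.values())
        winners = [s for s, v in nbs.items() if v == best_nb]
        if USUAL_CARE in winners:
            best = USUAL_CARE
        else:
            best = min(winners, key=order.index)
        rows.append({"x": x, "best_strategy": best, "net_benefit": best_nb})
    return pd.DataFrame(rows)
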