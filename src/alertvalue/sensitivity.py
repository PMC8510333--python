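"""Two-way sensitivity analysis, subgroup effects, and 2x2 odds ratios.

The tile map asks, for every (alert prevalence, exchange rate) cell and
optionally within one subgroup: which strategy has the highest net benefit?
Thresholds are fixed on the full cohort by default — one institution-wide
rule, then each subgroup asks how it fares — with per-subgroup
re-thresholding available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alerting import apply_rule, threshold_for_prevalence
from .cohort import Cohort, EmptyCohortError
from .metrics import (RULE, TREE2, USUAL_CARE, UndefinedMetricError,
                      observed_exchange_rate, strategy_outcomes)


class EmptySubgroupError(EmptyCohortError):
    """The requested subgroup contains no records."""


DEFAULT_RATE_AXIS = tuple(np.round(np.arange(0.25, 2.01, 0.05), 10))
DEFAULT_PREVALENCE_AXIS = tuple(np.round(np.arange(0.05, 0.205, 0.01), 10))


@dataclass
class SensitivityGrid:
    """Best strategy per (prevalence, exchange rate) cell for one subgroup."""

    subgroup: tuple[str, object] | None
    prevalence_axis: tuple[float, ...]
    exchange_rate_axis: tuple[float, ...]
    tiles: pd.DataFrame  # prevalence, exchange_rate, best_strategy,
    #                      nb_best, nb_usual_care
    reference_rates: dict  # overall and (possibly NaN) subgroup observed rate

    def to_csv(self, path) -> None:
        out = self.tiles.copy()
        out.insert(0, "subgroup",
                   "overall" if self.subgroup is None
                   else f"{self.subgroup[0]}={self.subgroup[1]}")
        out.to_csv(path, index=False)


def sensitivity_grid(cohort: Cohort,
                     model_names: Sequence[str] | None = None,
                     prevalence_axis: Sequence[float] = DEFAULT_PREVALENCE_AXIS,
                     exchange_rate_axis: Sequence[float] = DEFAULT_RATE_AXIS,
                     tree: str = TREE2,
                     subgroup: tuple[str, object] | None = None,
                     rethreshold_within_subgroup: bool = False) -> SensitivityGrid:
    """Tile map of the best strategy over prevalence and exchange rate.

    Net benefit is linear in the exchange rate given a strategy's outcome
    probabilities, so outcomes are computed once per (prevalence, strategy)
    and swept across rates. Ties go to usual care, then to model order.
    """
    models = list(model_names) if model_names is not None \
        else list(cohort.model_names)
    prevalences = [float(p) for p in prevalence_axis]
    rates = [float(r) for r in exchange_rate_axis]
    if any(r < 0 for r in rates):
        raise ValueError("exchange rates must be non-negative")

    if subgroup is None:
        eval_cohort = cohort
    else:
        dim, label = subgroup
        eval_cohort = cohort.filter_subgroup(dim, label)
        if eval_cohort.n == 0:
            raise EmptySubgroupError(f"subgroup {dim}={label!r} is empty")
    threshold_cohort = eval_cohort if rethreshold_within_subgroup else cohort

    try:
        overall_rate = observed_exchange_rate(cohort)
    except UndefinedMetricError:
        overall_rate = math.nan
    try:
        subgroup_rate = observed_exchange_rate(eval_cohort)
    except UndefinedMetricError:
        subgroup_rate = math.nan

    uc = strategy_outcomes(eval_cohort, tree=tree, strategy=USUAL_CARE)
    rows = []
    for p in prevalences:
        outs = {}
        for m in models:
            rule = threshold_for_prevalence(threshold_cohort, m, p)
            alerts = apply_rule(eval_cohort, rule)
            outs[m] = strategy_outcomes(eval_cohort, alerts, tree=tree,
                                        strategy=RULE)
        for r in rates:
            nb_uc = uc.p_tp - uc.p_fp * r
            nbs = {USUAL_CARE: nb_uc}
            nbs.update({m: o.p_tp - o.p_fp * r for m, o in outs.items()})
            best_nb = max(nbs.values())
            if nbs[USUAL_CARE] == best_nb:
                best = USUAL_CARE
            else:
                best = next(m for m in models if nbs[m] == best_nb)
            rows.append({"prevalence": p, "exchange_rate": r,
                         "best_strategy": best, "nb_best": best_nb,
                         "nb_usual_care": nb_uc})
    return SensitivityGrid(
        subgroup=subgroup,
        prevalence_axis=tuple(prevalences),
        exchange_rate_axis=tuple(rates),
        tiles=pd.DataFrame(rows),
        reference_rates={"overall": overall_rate, "subgroup": subgroup_rate},
    )


@dataclass(frozen=True)
class SubgroupEffect:
    """Expected relative risk and risk difference of a rule in one subgroup.

    ERR = P(Alert or CSO | EOL) / P(CSO | EOL) within the subgroup: the
    ratio of the two terms whose difference is the eRD, so
    eRD = (ERR - 1) * P(CSO | EOL). NaN when the subgroup has no EOL
    records or no usual-care CSO at EOL (the denominators).
    """

    dimension: str
    label: object
    n: int
    n_eol: int
    expected_relative_risk: float
    erd: float
    counts: dict


def _one_effect(cohort: Cohort, alerts: np.ndarray, dimension: str,
                label: object, mask: np.ndarray) -> SubgroupEffect:
    eol = cohort.eol.astype(bool) & mask
    cso = cohort.cso.astype(bool)
    a = alerts.astype(bool)
    n_eol = int(eol.sum())
    n_cso_eol = int((cso & eol).sum())
    n_aoc_eol = int(((a | cso) & eol).sum())
    err = n_aoc_eol / n_cso_eol if n_cso_eol else math.nan
    erd = (n_aoc_eol - n_cso_eol) / n_eol if n_eol else math.nan
    return SubgroupEffect(
        dimension=dimension, label=label, n=int(mask.sum()), n_eol=n_eol,
        expected_relative_risk=err, erd=erd,
        counts={"n_eol": n_eol, "n_cso_and_eol": n_cso_eol,
                "n_alert_or_cso_and_eol": n_aoc_eol},
    )


def subgroup_effects(cohort: Cohort, alerts,
                     dimension: str) -> list[SubgroupEffect]:
    """Per-label ERR/eRD of a fixed alert vector, with the overall appended."""
    a = np.asarray(alerts)
    if a.shape != (cohort.n,):
        raise ValueError("alert vector does not align with cohort")
    labels = cohort.subgroup(dimension)
    effects = [
        _one_effect(cohort, a, dimension, lab, labels == lab)
        for lab in pd.unique(labels)
    ]
    effects.append(_one_effect(cohort, a, dimension, "overall",
                               np.ones(cohort.n, dtype=bool)))
    return effects


def effects_to_frame(effects: Sequence[SubgroupEffect]) -> pd.DataFrame:
    return pd.DataFrame([{
        "dimension": e.dimension, "subgroup": e.label, "n": e.n,
        "n_eol": e.n_eol, "err": e.expected_relative_risk, "erd": e.erd,
    } for e in effects])


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    defined: bool


def two_by_two_odds_ratio(a: int, b: int, c: int, d: int) -> OddsRatio:
    """OR = (a*d)/(b*c) with a 95% Wald (log-OR normal) interval.

    No continuity correction: a zero cell yields an infinite or undefined
    ratio, flagged via ``defined=False`` with NaN bounds.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    if b == 0 or c == 0:
        or_ = math.inf if (a > 0 and d > 0) else math.nan
        return OddsRatio(or_, math.nan, math.nan, defined=False)
    or_ = (a * d) / (b * c)
    if a == 0 or d == 0:
        return OddsRatio(or_, math.nan, math.nan, defined=False)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return OddsRatio(or_, math.exp(log_or - 1.96 * se),
                     math.exp(log_or + 1.96 * se), defined=True)
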