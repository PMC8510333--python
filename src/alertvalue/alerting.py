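"""Alert rules: prevalence-fixed risk thresholds and the random comparator.

A rule fires an alert for every admission whose predicted risk is greater
than or equal to its threshold. Thresholds are usually chosen indirectly,
by fixing the fraction of admissions that should alert (the *alert
prevalence*), which is the resource-use dial of an alerting CDSS: a target
prevalence p maps to the empirical (1 - p) quantile of the risk column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .cohort import Cohort


@dataclass(frozen=True)
class AlertRule:
    """A named risk column plus a threshold; alert fires iff risk >= threshold.

    ``achieved_prevalence`` is the fraction of the thresholding cohort at or
    above the threshold; ties can push it above ``target_prevalence``, so
    both are carried. ``degenerate`` marks an all-ties risk column, where
    the prevalence dial has no resolution.
    """

    model_name: str
    threshold: float
    target_prevalence: float | None = None
    achieved_prevalence: float | None = None
    degenerate: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "AlertRule":
        return cls(**json.loads(s))


def threshold_for_prevalence(cohort: Cohort, model_name: str,
                             target_prevalence: float) -> AlertRule:
    """Fix a rule's threshold so that ~``target_prevalence`` of records alert.

    The threshold is the k-th largest observed risk with k = ceil(p * N):
    on a tie-free cohort exactly k records sit at or above it, matching the
    percentile-of-predicted-risk construction (e.g. the 90th percentile for
    a 10% alert prevalence). Ties at the threshold all alert, which can push
    the achieved prevalence above the target; both values are reported.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError(f"target_prevalence must lie in (0, 1), got {target_prevalence}")
    risks = cohort.risks(model_name)
    n = risks.size
    if n == 0:
        raise ValueError("cannot threshold an empty cohort")
    # guard against float fuzz when p * n is integral (e.g. 0.2 * 20)
    k = int(np.ceil(target_prevalence * n - 1e-9))
    k = min(max(k, 1), n)
    order = np.sort(risks)[::-1]
    threshold = float(order[k - 1])
    achieved = float(np.mean(risks >= threshold))
    degenerate = bool(order[0] == order[-1])
    return AlertRule(model_name=model_name, threshold=threshold,
                     target_prevalence=float(target_prevalence),
                     achieved_prevalence=achieved, degenerate=degenerate)


def rule_at_threshold(cohort: Cohort, model_name: str,
                      threshold: float) -> AlertRule:
    """A rule at an explicitly chosen threshold, with achieved prevalence."""
    risks = cohort.risks(model_name)
    achieved = float(np.mean(risks >= threshold)) if risks.size else None
    return AlertRule(model_name=model_name, threshold=float(threshold),
                     achieved_prevalence=achieved)


def apply_rule(cohort: Cohort, rule: AlertRule) -> np.ndarray:
    """Alert indicator per admission: 1 iff risk >= rule.threshold."""
    risks = cohort.risks(rule.model_name)
    return (risks >= rule.threshold).astype(np.int64)


def random_model(cohort: Cohort, seed: int, name: str = "random") -> Cohort:
    """Add a comparator risk column of uniform draws on [0, 1].

    Alerts from this column are independent of outcome and usual care; it
    makes explicit the consequences of assuming that every alert causes the
    desired action regardless of the prediction behind it.
    """
    rng = np.random.default_rng(seed)
    return cohort.with_risk_column(name, rng.random(cohort.n))
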