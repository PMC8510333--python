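"""Cluster-aware uncertainty: two-stage bootstrap and per-patient sampling.

Repeated admissions of the same patient are not independent, so replicates
resample *patients* with replacement (stage 1) and then draw one random
admission per sampled patient copy (stage 2). A patient drawn k times
contributes k (possibly different) admissions. Metrics are evaluated on
each replicate; percentile 95% intervals are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError
from .metrics import UndefinedMetricError


class MissingOrderingKeyError(CohortError):
    """first/last per-patient sampling requested without an ordering column."""


def _patient_blocks(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row positions grouped by patient: (flat rows, offsets, counts)."""
    codes, _ = pd.factorize(cohort.df["patient_id"], sort=False)
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes)
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return order, offsets, counts


@dataclass
class BootstrapResult:
    metric: str
    estimate: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    n_replicates: int
    n_dropped: int
    unreliable: bool
    seed: int

    def to_dict(self) -> dict:
        return {"metric": self.metric, "estimate": self.estimate,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_replicates": self.n_replicates,
                "n_dropped": self.n_dropped, "seed": self.seed}


def two_stage_bootstrap(cohort: Cohort, metric: Callable[[Cohort], float],
                        n_replicates: int = 1000, seed: int = 0,
                        name: str | None = None) -> BootstrapResult:
    """Percentile bootstrap CI of ``metric`` under two-stage resampling.

    A replicate on which the metric is undefined (raises
    :class:`UndefinedMetricError` or returns NaN) is dropped and counted;
    if more than 10% of replicates are dropped the interval is flagged
    unreliable. Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    flat, offsets, counts = _patient_blocks(cohort)
    n_pat = counts.size

    values = []
    n_dropped = 0
    for _ in range(n_replicates):
        chosen = rng.integers(0, n_pat, n_pat)
        within = (rng.random(n_pat) * counts[chosen]).astype(np.int64)
        rows = flat[offsets[chosen] + within]
        try:
            v = float(metric(cohort.take(rows)))
        except UndefinedMetricError:
            n_dropped += 1
            continue
        if math.isnan(v):
            n_dropped += 1
            continue
        values.append(v)

    reps = np.asarray(values, dtype=float)
    if reps.size == 0:
        ci_low = ci_high = math.nan
    else:
        ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
    try:
        estimate = float(metric(cohort))
    except UndefinedMetricError:
        estimate = math.nan
    return BootstrapResult(
        metric=name or getattr(metric, "__name__", "metric"),
        estimate=estimate, replicates=reps,
        ci_low=float(ci_low), ci_high=float(ci_high),
        n_replicates=n_replicates, n_dropped=n_dropped,
        unreliable=n_dropped > 0.1 * n_replicates, seed=seed,
    )


def per_patient_sampling(cohort: Cohort, mode: str, seed: int | None = None,
                         order_key: str = "admission_seq") -> Cohort:
    """Keep one hospitalization per patient: first, last, or random.

    ``first``/``last`` order admissions by ``order_key`` (an admission
    sequence column) and need it present; ``random`` needs a seed. The
    patient set is unchanged.
    """
    if mode not in ("first", "last", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    flat, offsets, counts = _patient_blocks(cohort)
    if mode == "random":
        if seed is None:
            raise ValueError("mode 'random' requires a seed")
        rng = np.random.default_rng(seed)
        within = (rng.random(counts.size) * counts).astype(np.int64)
        rows = flat[offsets + within]
    else:
        if order_key not in cohort.df.columns:
            raise MissingOrderingKeyError(
                f"mode {mode!r} needs ordering column {order_key!r}")
        order_vals = cohort.df[order_key].to_numpy()
        rows = np.empty(counts.size, dtype=np.int64)
        for i in range(counts.size):
            block = flat[offsets[i]:offsets[i] + counts[i]]
            vals = order_vals[block]
            rows[i] = block[np.argmin(vals) if mode == "first"
                            else np.argmax(vals)]
    rows = np.sort(rows)  # preserve original record order
    return Cohort(cohort.df.take(rows).reset_index(drop=True),
                  cohort.model_names, cohort.subgroup_dimensions)
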