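from __future__ import annotations

import numpy as np
import pytest

from alertvalue import Cohort, fixture_cohort


@pytest.fixture
def fixture20() -> Cohort:
    return fixture_cohort()


def make_cohort(eol, cso, risks, patient_id=None, subgroups=None,
                model="m") -> Cohort:
    """Assemble a cohort from parallel arrays with generated identifiers."""
    n = len(eol)
    if patient_id is None:
        patient_id = [f"p{i}" for i in range(n)]
    risk_map = risks if isinstance(risks, dict) else {model: risks}
    return Cohort.from_arrays(
        patient_id=patient_id,
        admission_id=[f"a{i}" for i in range(n)],
        eol=eol, cso=cso, risks=risk_map, subgroups=subgroups,
    )


def random_cohort(rng: np.random.Generator, n: int | None = None,
                  allow_ties: bool = True, model="m") -> Cohort:
    """A random cohort guaranteed to have both EOL classes, CSOs and
    usual-care FPs, so every metric is defined."""
    if n is None:
        n = int(rng.integers(30, 400))
    while True:
        eol = (rng.random(n) < rng.uniform(0.05, 0.5)).astype(int)
        cso = (rng.random(n) < rng.uniform(0.1, 0.6)).astype(int)
        has_fp = bool(np.any(cso & (1 - eol)))
        has_tp = bool(np.any(cso & eol))
        if 0 < eol.sum() < n and has_fp and has_tp:
            break
    if allow_ties and rng.random() < 0.5:
        risks = np.round(rng.random(n), 1)  # heavy ties
    else:
        risks = rng.random(n)
    return make_cohort(eol, cso, risks, model=model)
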