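"""Small hand-enumerable cohorts used as shared oracles in tests and docs."""

from __future__ import annotations

from typing import Sequence

from .cohort import Cohort

# 20 distinct patients, one admission each.
# 5 EOL records (3 with a usual-care CSO), 15 non-EOL (4 with a CSO).
# The four highest risks belong to exactly one record of each joint
# (eol, cso) class, so that at a target alert prevalence of 0.20 the alert
# set contains one EOL+CSO, one EOL-only, one CSO-only and one plain record.
_ROWS = [
    # (eol, cso, risk)
    (1, 1, 0.96),  # alerts
    (1, 1, 0.52),
    (1, 1, 0.48),
    (1, 0, 0.93),  # alerts
    (1, 0, 0.44),
    (0, 1, 0.91),  # alerts
    (0, 1, 0.40),
    (0, 1, 0.36),
    (0, 1, 0.32),
    (0, 0, 0.90),  # alerts
    (0, 0, 0.28),
    (0, 0, 0.26),
    (0, 0, 0.24),
    (0, 0, 0.22),
    (0, 0, 0.20),
    (0, 0, 0.18),
    (0, 0, 0.16),
    (0, 0, 0.14),
    (0, 0, 0.12),
    (0, 0, 0.10),
]

FIXTURE_MODEL = "score"


def fixture_cohort(site_labels: Sequence | None = None) -> Cohort:
    """The canonical 20-record cohort with one risk column ``score``.

    All 20 risks are distinct; the empirical quantile rule at target alert
    prevalence 0.20 selects exactly the four designed records (threshold
    0.90). ``site_labels``, when given, attaches a ``site`` subgroup
    dimension (one label per record).
    """
    eol = [r[0] for r in _ROWS]
    cso = [r[1] for r in _ROWS]
    risk = [r[2] for r in _ROWS]
    subgroups = None
    if site_labels is not None:
        if len(site_labels) != len(_ROWS):
            raise ValueError("site_labels must have 20 entries")
        subgroups = {"site": list(site_labels)}
    return Cohort.from_arrays(
        patient_id=[f"p{i:02d}" for i in range(1, 21)],
        admission_id=[f"a{i:02d}" for i in range(1, 21)],
        eol=eol, cso=cso,
        risks={FIXTURE_MODEL: risk},
        subgroups=subgroups,
        admission_seq=[1] * len(_ROWS),
    )
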