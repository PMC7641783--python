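"""Bundled example score tables.

:func:`inpatient_mortality_example` returns a published nine-variable
integer point score for ICU inpatient mortality (first-day vitals, labs
and age), in exactly the representation this package derives.  It is
useful as a worked example of the :class:`~pointscore.score.ScoreTable`
container — interval lookups, total-score range, rendering — without
fitting anything.
"""

from __future__ import annotations

from .score import ScoreTable
from .transform import bin_labels

# variable -> (cutoffs, points per left-closed bin "<c1", "c1-c2", ..., ">=cj")
_INPATIENT_MORTALITY = {
    "age": ((30, 48, 78, 85), (0, 5, 14, 22, 24)),
    "heart_rate": ((62, 72, 98, 112), (1, 0, 1, 8, 13)),
    "resp_rate": ((12, 16, 22), (3, 0, 4, 12)),
    "sbp": ((90, 100, 130, 150), (15, 8, 0, 1, 3)),
    "temperature": ((36, 36.5, 37.5, 38), (12, 3, 0, 5, 9)),
    "spo2": ((85, 90, 95), (25, 13, 4, 0)),
    "platelet": ((80, 150, 300, 450), (17, 3, 0, 3, 5)),
    "bun": ((7.5, 12, 35, 70), (0, 2, 9, 19, 23)),
    "lactate": ((1, 2.5, 4), (0, 2, 8, 21)),
}


def inpatient_mortality_example() -> tuple[ScoreTable, dict[str, tuple[float, ...]]]:
    """A published nine-variable ICU mortality score and its cutoffs.

    Returns the score table and the per-variable cutoff vectors (bins
    are left-closed: a value equal to a cutoff falls in the bin above).
    """
    points: dict[str, dict[str, int]] = {}
    references: dict[str, str] = {}
    order: dict[str, list[str]] = {}
    for var, (cutoffs, pts) in _INPATIENT_MORTALITY.items():
        labels = bin_labels(cutoffs)
        points[var] = {lab: p for lab, p in zip(labels, pts)}
        references[var] = labels[pts.index(0)]
        order[var] = labels
    table = ScoreTable(points=points, references=references, category_order=order)
    cutoffs = {var: tuple(float(c) for c in cu) for var, (cu, _) in _INPATIENT_MORTALITY.items()}
    return table, cutoffs
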