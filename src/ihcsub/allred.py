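"""Allred-style scoring of IHC stains and the 4-grade collapse.

A stain is scored by intensity (0-3) and proportion of stained cells
(0-5); the total (0-8) is their sum.  Totals collapse to four grades
rendered externally as ``0 / 1+ / 2+ / 3+``:

===========  =====
total score  grade
===========  =====
0-2          0
3-5          1+
6-7          2+
8            3+
===========  =====
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import FieldRangeError, InconsistentStainError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort

#: Fixed marker column order used everywhere a grade matrix appears.
MARKER_ORDER = ("CK56", "P63", "GATA6", "HNF4A")

GRADE_LABELS = {0: "0", 1: "1+", 2: "2+", 3: "3+"}
_LABEL_TO_GRADE = {v: k for k, v in GRADE_LABELS.items()}

#: Canonical (intensity, proportion) pair for each grade, used when only
#: pre-collapsed grades are available (grade-only ingestion, simulation
#: shortcuts).  Each pair maps back to the same grade under
#: :func:`grade_of_total`.
CANONICAL_SCORE_OF_GRADE = {0: (0, 0), 1: (1, 3), 2: (2, 4), 3: (3, 5)}


def allred_total(intensity: int, proportion: int) -> int:
    """Total Allred score = intensity + proportion.

    Raises
    ------
    FieldRangeError
        If either score is outside its range.
    InconsistentStainError
        If exactly one of intensity/proportion is zero: a stain is
        either entirely negative (0, 0) or has both a positive
        intensity and a positive proportion.
    """
    if not (0 <= intensity <= 3):
        raise FieldRangeError(
            f"intensity {intensity} outside 0-3", field="intensity"
        )
    if not (0 <= proportion <= 5):
        raise FieldRangeError(
            f"proportion {proportion} outside 0-5", field="proportion"
        )
    if (intensity == 0) != (proportion == 0):
        raise InconsistentStainError(
            f"intensity={intensity}, proportion={proportion}: "
            "zero intensity requires zero proportion and vice versa"
        )
    return intensity + proportion


def grade_of_total(total: int) -> int:
    """Collapse a total score 0-8 onto the 4-grade scale 0-3."""
    if not (0 <= total <= 8):
        raise FieldRangeError(f"total {total} outside 0-8", field="total")
    if total <= 2:
        return 0
    if total <= 5:
        return 1
    if total <= 7:
        return 2
    return 3


def grade_label(grade: int) -> str:
    """Render an integer grade as its external token (``"2+"`` etc.)."""
    try:
        return GRADE_LABELS[grade]
    except KeyError:
        raise FieldRangeError(f"grade {grade} outside 0-3", field="grade") from None


def parse_grade_label(token: str) -> int:
    """Inverse of :func:`grade_label`."""
    try:
        return _LABEL_TO_GRADE[token.strip()]
    except KeyError:
        raise FieldRangeError(
            f"unrecognized grade token {token!r}", field="grade"
        ) from None


@dataclass(frozen=True)
class GradeMatrix:
    """Per-case grades of the four markers in fixed column order.

    ``values[i, j]`` is the grade (0-3) of case ``case_ids[i]`` for
    marker ``MARKER_ORDER[j]``.
    """

    case_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=int)
        if values.ndim != 2 or values.shape != (len(self.case_ids), 4):
            raise FieldRangeError(
                f"grade matrix shape {values.shape} does not match "
                f"{len(self.case_ids)} cases x 4 markers"
            )
        if values.size and (values.min() < 0 or values.max() > 3):
            raise FieldRangeError("grade matrix entries must lie in 0-3")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.case_ids)

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, MARKER_ORDER.index(marker)]


def grade_matrix(cohort: "Cohort") -> GradeMatrix:
    """Assemble the n x 4 grade matrix of a cohort.

    Raises an error on an empty cohort: every downstream consumer
    (clustering, rules) requires at least one case.
    """
    if len(cohort.cases) == 0:
        raise FieldRangeError("cannot build a grade matrix from an empty cohort")
    rows = []
    ids = []
    for case in cohort.cases:
        rows.append([case.stains[m].grade for m in MARKER_ORDER])
        ids.append(case.case_id)
    return GradeMatrix(case_ids=tuple(ids), values=np.array(rows, dtype=int))


def ihc_composite_score(row) -> int:
    """Basal-minus-classical composite of one grade row.

    (CK5/6 + p63) - (GATA6 + HNF4a); range -6..+6.  Used only to order
    clusters deterministically when naming the three patterns.
    """
    ck56, p63, gata6, hnf4a = (int(g) for g in row)
    return (ck56 + p63) - (gata6 + hnf4a)


def composite_scores(matrix: GradeMatrix) -> np.ndarray:
    """Vectorized :func:`ihc_composite_score` over a grade matrix."""
    v = matrix.values
    return (v[:, 0] + v[:, 1]) - (v[:, 2] + v[:, 3])
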