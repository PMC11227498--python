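"""Fixed decision rules predicting IHC pattern from marker grades and
histology, and sensitivity/specificity evaluation.

Three rules operate on the 4-grade scale (CK5/6, p63, GATA6, HNF4a) and
the histology label:

* basal:      CK5/6 = 3+, or CK5/6 >= 2+ and p63 >= 2+, or
              CK5/6 >= 2+ and squamous-differentiation histology
* classical:  GATA6 = 3+ and HNF4a = 3+
* not-basal:  CK5/6 = 0 or p63 = 0

Precedence is basal > not-basal > classical: a decisive basal call
suppresses the other flags.  "CK5/6 2+ with poorly differentiated
component" with no decisive rule is an explicit equivocal state, never
silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort import Cohort, Histology
from .errors import FieldRangeError


@dataclass(frozen=True)
class RulePrediction:
    case_id: str
    basal_pred: bool
    classical_pred: bool
    not_basal_pred: bool
    equivocal: bool

    def __post_init__(self) -> None:
        if self.basal_pred and self.not_basal_pred:
            raise FieldRangeError(
                f"case {self.case_id}: basal and not-basal cannot both be "
                "decided (precedence violated)"
            )


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None


def _check_grades(grades: Sequence[int]) -> tuple[int, int, int, int]:
    if len(grades) != 4:
        raise FieldRangeError("expected 4 grades (CK56, P63, GATA6, HNF4A)")
    g = tuple(int(v) for v in grades)
    if any(v < 0 or v > 3 for v in g):
        raise FieldRangeError("grades must lie in 0-3")
    return g


def predict_basal(grades: Sequence[int], histology: Histology) -> bool:
    ck56, p63, _gata6, _hnf4a = _check_grades(grades)
    return (
        ck56 == 3
        or (ck56 >= 2 and p63 >= 2)
        or (ck56 >= 2 and histology is Histology.SQ_DIFF)
    )


def predict_classical(grades: Sequence[int]) -> bool:
    _ck56, _p63, gata6, hnf4a = _check_grades(grades)
    return gata6 == 3 and hnf4a == 3


def predict_not_basal(grades: Sequence[int]) -> bool:
    ck56, p63, _gata6, _hnf4a = _check_grades(grades)
    return ck56 == 0 or p63 == 0


def classify_case(grades: Sequence[int], histology: Histology,
                  case_id: str = "") -> RulePrediction:
    """Apply all three rules with basal > not-basal > classical
    precedence and flag the equivocal combination."""
    ck56 = _check_grades(grades)[0]
    basal = predict_basal(grades, histology)
    not_basal = (not basal) and predict_not_basal(grades)
    classical = (not basal) and predict_classical(grades)
    decisive = basal or not_basal or classical
    equivocal = (ck56 == 2 and histology is Histology.POR_COMP and not decisive)
    return RulePrediction(
        case_id=case_id,
        basal_pred=basal,
        classical_pred=classical,
        not_basal_pred=not_basal,
        equivocal=equivocal,
    )


def classify_cohort(cohort: Cohort) -> list[RulePrediction]:
    return [classify_case(c.grades(), c.histology, c.case_id) for c in cohort]


def sens_spec(predictions: Sequence[bool], truth: Sequence[bool]) -> ConfusionSummary:
    """Confusion counts and rates.

    A degenerate truth vector (all positive or all negative) leaves the
    corresponding rate undefined; it is reported as None, never as 0.
    """
    if len(predictions) != len(truth):
        raise FieldRangeError("prediction and truth vectors differ in length")
    tp = fp = tn = fn = 0
    for pred, true in zip(predictions, truth):
        if true:
            tp += bool(pred)
            fn += not pred
        else:
            fp += bool(pred)
            tn += not pred
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn,
                            sensitivity=sens, specificity=spec)


def evaluate_basal_rule(cohort: Cohort, truth: Sequence[bool]) -> dict:
    """Basal-rule performance against a truth vector, reported both with
    equivocal cases counted as negative predictions and with them
    excluded (the printed rates do not state which convention was
    used)."""
    preds = classify_cohort(cohort)
    basal = [p.basal_pred for p in preds]
    keep = [not p.equivocal for p in preds]
    included = sens_spec(basal, truth)
    excluded = sens_spec(
        [b for b, k in zip(basal, keep) if k],
        [t for t, k in zip(truth, keep) if k],
    )
    return {
        "equivocal_n": sum(not k for k in keep),
        "equivocal_as_negative": included,
        "equivocal_excluded": excluded,
    }
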