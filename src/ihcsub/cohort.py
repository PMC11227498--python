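"""Cohort data model, delimited-file I/O, cross-tabulation, and packaged
reference-table fixtures.

The on-disk cohort format is a UTF-8 comma-separated file with header::

    case_id, ck56_intensity, ck56_proportion, p63_intensity, p63_proportion,
    gata6_intensity, gata6_proportion, hnf4a_intensity, hnf4a_proportion,
    histology{glandular|por_comp|sq_diff}, stage{I|II|III|IV|NA},
    sex{M|F}, age, time_days, event{0|1}[, latent_pattern]

Grades are derived on load; :func:`write_cohort` additionally renders the
four derived grade columns with ``0/1+/2+/3+`` tokens.  A grade-only
ingestion mode (``ck56_grade`` ... columns instead of the eight score
columns) accepts pre-collapsed grades from external users and maps each
grade onto a canonical (intensity, proportion) pair.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import allred
from .errors import (
    DegenerateTableError,
    DuplicateCaseIdError,
    FieldRangeError,
    MissingFileError,
    SchemaError,
    UnknownTokenError,
)


class Marker(str, enum.Enum):
    CK56 = "CK56"
    P63 = "P63"
    GATA6 = "GATA6"
    HNF4A = "HNF4A"


class Histology(str, enum.Enum):
    GLANDULAR = "glandular"
    POR_COMP = "por_comp"
    SQ_DIFF = "sq_diff"


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "NA"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Pattern(str, enum.Enum):
    CLASSICAL = "classical"
    TRANSITIONAL = "transitional"
    BASAL_LIKE = "basal_like"


@dataclass(frozen=True)
class MarkerStain:
    """One marker's Allred scores for one case.

    ``total`` and ``grade`` are always derived from intensity and
    proportion; they are stored for convenience but never trusted from
    external input.
    """

    marker: Marker
    intensity: int
    proportion: int
    total: int = field(init=False)
    grade: int = field(init=False)

    def __post_init__(self) -> None:
        total = allred.allred_total(self.intensity, self.proportion)
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "grade", allred.grade_of_total(total))

    @classmethod
    def from_grade(cls, marker: Marker, grade: int) -> "MarkerStain":
        """Build a stain from a pre-collapsed grade via the canonical
        (intensity, proportion) pair for that grade."""
        if grade not in allred.CANONICAL_SCORE_OF_GRADE:
            raise FieldRangeError(f"grade {grade} outside 0-3", field="grade")
        intensity, proportion = allred.CANONICAL_SCORE_OF_GRADE[grade]
        return cls(marker=marker, intensity=intensity, proportion=proportion)


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    stains: Mapping[str, MarkerStain]
    histology: Histology
    stage: Stage
    sex: Sex
    age_years: int
    time_days: float
    event: bool
    latent_pattern: Pattern | None = None

    def __post_init__(self) -> None:
        expected = set(allred.MARKER_ORDER)
        got = set(self.stains)
        if got != expected:
            raise SchemaError(
                f"case {self.case_id}: stains for {sorted(got)} but "
                f"expected exactly {sorted(expected)}"
            )
        if self.age_years < 0:
            raise FieldRangeError(
                f"case {self.case_id}: negative age", row=self.case_id, field="age"
            )
        if self.time_days < 0:
            raise FieldRangeError(
                f"case {self.case_id}: negative time_days",
                row=self.case_id,
                field="time_days",
            )

    def grades(self) -> tuple[int, int, int, int]:
        return tuple(self.stains[m].grade for m in allred.MARKER_ORDER)


@dataclass(frozen=True)
class Cohort:
    cases: tuple[CaseRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))
        seen: set[str] = set()
        for case in self.cases:
            if case.case_id in seen:
                raise DuplicateCaseIdError(f"duplicate case_id {case.case_id!r}")
            seen.add(case.case_id)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def pattern_counts(self) -> dict[Pattern, int]:
        counts = {p: 0 for p in Pattern}
        for case in self.cases:
            if case.latent_pattern is not None:
                counts[case.latent_pattern] += 1
        return counts


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_MARKER_COLS = [("ck56", Marker.CK56), ("p63", Marker.P63),
                ("gata6", Marker.GATA6), ("hnf4a", Marker.HNF4A)]

_SCORE_HEADER = ["case_id"]
for _prefix, _m in _MARKER_COLS:
    _SCORE_HEADER += [f"{_prefix}_intensity", f"{_prefix}_proportion"]
_SCORE_HEADER += ["histology", "stage", "sex", "age", "time_days", "event"]

_GRADE_COLS = [f"{p}_grade" for p, _ in _MARKER_COLS]


def _parse_enum(enum_cls, token: str, row_id: object, fieldname: str):
    try:
        return enum_cls(token.strip())
    except ValueError:
        raise UnknownTokenError(
            f"row {row_id}: unknown {fieldname} token {token!r}"
        ) from None


def _parse_int(token: str, row_id: object, fieldname: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FieldRangeError(
            f"row {row_id}: field {fieldname} is not an integer: {token!r}",
            row=row_id,
            field=fieldname,
        ) from None


def _case_from_row(row: Mapping[str, str], row_id: object, grade_mode: bool) -> CaseRecord:
    stains = {}
    for prefix, marker in _MARKER_COLS:
        if grade_mode:
            grade = allred.parse_grade_label(row[f"{prefix}_grade"])
            stains[marker.value] = MarkerStain.from_grade(marker, grade)
        else:
            intensity = _parse_int(row[f"{prefix}_intensity"], row_id, f"{prefix}_intensity")
            proportion = _parse_int(row[f"{prefix}_proportion"], row_id, f"{prefix}_proportion")
            try:
                stains[marker.value] = MarkerStain(marker, intensity, proportion)
            except FieldRangeError as exc:
                raise FieldRangeError(
                    f"row {row_id}: {prefix}: {exc}", row=row_id,
                    field=f"{prefix}_{exc.field}",
                ) from None
    latent = None
    token = (row.get("latent_pattern") or "").strip()
    if token:
        latent = _parse_enum(Pattern, token, row_id, "latent_pattern")
    try:
        event_int = _parse_int(row["event"], row_id, "event")
        if event_int not in (0, 1):
            raise FieldRangeError(
                f"row {row_id}: event must be 0 or 1", row=row_id, field="event"
            )
        return CaseRecord(
            case_id=row["case_id"].strip(),
            stains=stains,
            histology=_parse_enum(Histology, row["histology"], row_id, "histology"),
            stage=_parse_enum(Stage, row["stage"], row_id, "stage"),
            sex=_parse_enum(Sex, row["sex"], row_id, "sex"),
            age_years=_parse_int(row["age"], row_id, "age"),
            time_days=float(row["time_days"]),
            event=bool(event_int),
            latent_pattern=latent,
        )
    except ValueError:
        raise FieldRangeError(
            f"row {row_id}: time_days is not numeric: {row['time_days']!r}",
            row=row_id,
            field="time_days",
        ) from None


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV (score columns, or grade-only columns).

    Malformed mandatory fields raise a distinct named error carrying the
    row number; rows are never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"cohort file not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        score_mode = all(c in header for c in _SCORE_HEADER)
        grade_mode = (not score_mode) and all(
            c in header for c in ["case_id", *_GRADE_COLS, "histology", "stage",
                                  "sex", "age", "time_days", "event"]
        )
        if not (score_mode or grade_mode):
            raise SchemaError(
                f"{path}: header does not match the documented cohort schema "
                f"(got columns {header})"
            )
        cases = []
        for row_id, row in enumerate(reader, start=2):  # header is line 1
            cases.append(_case_from_row(row, row_id, grade_mode))
    return Cohort(cases=tuple(cases))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV that round-trips through :func:`read_cohort`.

    Score columns carry the raw intensity/proportion integers; derived
    grade columns are rendered with ``0/1+/2+/3+`` tokens for human
    readers (and for grade-only ingestion elsewhere).
    """
    path = Path(path)
    has_latent = any(c.latent_pattern is not None for c in cohort.cases)
    header = list(_SCORE_HEADER) + _GRADE_COLS + (["latent_pattern"] if has_latent else [])
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for case in cohort.cases:
            row: list[object] = [case.case_id]
            for _prefix, marker in _MARKER_COLS:
                stain = case.stains[marker.value]
                row += [stain.intensity, stain.proportion]
            row += [
                case.histology.value,
                case.stage.value,
                case.sex.value,
                case.age_years,
                repr(float(case.time_days)),
                int(case.event),
            ]
            row += [allred.grade_label(case.stains[m.value].grade)
                    for _p, m in _MARKER_COLS]
            if has_latent:
                row.append("" if case.latent_pattern is None else case.latent_pattern.value)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Cross-tabulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with labels."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise SchemaError("counts shape does not match labels")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise DegenerateTableError(
                f"table must be at least 2x2, got {counts.shape}"
            )
        if counts.min() < 0:
            raise FieldRangeError("negative cell count")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


_AGE_CUT = 70

#: Canonical level ordering per factor (clinical convention).
_FACTOR_LEVELS = {
    "histology": [h.value for h in Histology],
    "stage": [Stage.I.value, Stage.II.value, Stage.III.value, Stage.IV.value,
              Stage.UNKNOWN.value],
    "sex": [s.value for s in Sex],
    "age_group": ["<70", ">=70"],
    "pattern": [p.value for p in Pattern],
    "ck56_pos": ["negative", "positive"],
}


def _factor_value(case: CaseRecord, factor: str,
                  assignment: Mapping[str, Pattern] | None) -> str:
    if factor == "histology":
        return case.histology.value
    if factor == "stage":
        return case.stage.value
    if factor == "sex":
        return case.sex.value
    if factor == "age_group":
        return "<70" if case.age_years < _AGE_CUT else ">=70"
    if factor == "ck56_pos":
        return "positive" if case.stains[Marker.CK56.value].grade >= 1 else "negative"
    if factor == "pattern":
        if assignment is not None:
            pattern = assignment.get(case.case_id)
        else:
            pattern = case.latent_pattern
        if pattern is None:
            raise SchemaError(
                f"case {case.case_id}: no pattern available (provide an "
                "assignment or a latent_pattern column)"
            )
        return pattern.value
    raise UnknownTokenError(f"unknown factor {factor!r}")


def build_table(
    cohort: Cohort,
    row_factor: str,
    col_factor: str,
    *,
    drop_unknown: bool = False,
    assignment: Mapping[str, Pattern] | None = None,
) -> ContingencyTable:
    """Cross-tabulate two categorical factors of a cohort.

    With ``drop_unknown=True``, cases with ``stage == NA`` are excluded
    whenever one of the factors is ``stage`` (the printed reference
    stage table covers 182 of 190 cases for this reason).
    """
    cases = list(cohort.cases)
    if drop_unknown and "stage" in (row_factor, col_factor):
        cases = [c for c in cases if c.stage is not Stage.UNKNOWN]
    pairs = [(_factor_value(c, row_factor, assignment),
              _factor_value(c, col_factor, assignment)) for c in cases]
    row_levels = [lv for lv in _FACTOR_LEVELS[row_factor] if any(r == lv for r, _ in pairs)]
    col_levels = [lv for lv in _FACTOR_LEVELS[col_factor] if any(c == lv for _, c in pairs)]
    if len(row_levels) < 2 or len(col_levels) < 2:
        raise DegenerateTableError(
            f"factor with a single observed level: rows={row_levels}, "
            f"cols={col_levels}"
        )
    counts = np.zeros((len(row_levels), len(col_levels)), dtype=int)
    for r, c in pairs:
        counts[row_levels.index(r), col_levels.index(c)] += 1
    return ContingencyTable(tuple(row_levels), tuple(col_levels), counts)


# ---------------------------------------------------------------------------
# Packaged reference-table fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("ihcsub.fixtures").joinpath(name)


def load_table1_marginals() -> dict[str, tuple[int, int, int, int]]:
    """Printed marker grade distribution (marker -> counts per grade 0..3+)."""
    out: dict[str, tuple[int, int, int, int]] = {}
    with resources.as_file(_fixture_path("table1_marginals.csv")) as p:
        with open(p, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                out[row["marker"]] = tuple(
                    int(row[g]) for g in ("grade0", "grade1", "grade2", "grade3")
                )
    return out


def load_table2(which: str) -> ContingencyTable:
    """One of the printed cross-tabulations: 'stage', 'sex', 'age', 'histology'.

    Columns are the three IHC patterns in classical/transitional/basal
    order.  The stage table covers the 182 staged cases only.
    """
    if which not in ("stage", "sex", "age", "histology"):
        raise UnknownTokenError(f"no packaged table2 fixture {which!r}")
    rows = []
    labels = []
    with resources.as_file(_fixture_path(f"table2_{which}.csv")) as p:
        with open(p, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                labels.append(row["level"])
                rows.append([int(row[c]) for c in
                             ("classical", "transitional", "basal_like")])
    return ContingencyTable(
        tuple(labels),
        (Pattern.CLASSICAL.value, Pattern.TRANSITIONAL.value, Pattern.BASAL_LIKE.value),
        np.array(rows, dtype=int),
    )


def load_fixture_cohort() -> Cohort:
    """The packaged deterministic 190-case cohort.

    Its pattern sizes (85/85/20), pattern-wise histology/stage/sex/age
    cross-tabulations, and all four marker grade marginals reproduce the
    printed Tables 1 and 2 exactly.  Joint structure beyond those
    margins (and the survival columns) is arbitrary but deterministic.
    """
    with resources.as_file(_fixture_path("cohort_fixture_190.csv")) as p:
        return read_cohort(p)


def _expand(blocks: Sequence[tuple[object, int]]) -> list:
    out: list = []
    for value, count in blocks:
        out.extend([value] * count)
    return out


def build_fixture_cohort() -> Cohort:
    """Construct the deterministic reference fixture cohort in memory.

    Within each pattern, marker grades and clinical attributes are laid
    out in fixed blocks matching the printed pattern-wise counts; the
    attributes are mutually independent within pattern, which the
    printed tables do not constrain.
    """
    P = Pattern
    H = Histology
    S = Stage
    # per-pattern block specs: grades per marker, histology, stage (incl. the
    # 8 stage-unknown cases as 5 classical + 3 transitional), sex, age group
    blocks = {
        P.CLASSICAL: dict(
            n=85,
            ck56=[(0, 85)],
            p63=[(0, 85)],
            gata6=[(3, 85)],
            hnf4a=[(3, 66), (2, 19)],
            histology=[(H.GLANDULAR, 61), (H.POR_COMP, 24)],
            stage=[(S.I, 8), (S.II, 13), (S.III, 17), (S.IV, 42), (S.UNKNOWN, 5)],
            male=44,
            young=38,
        ),
        P.TRANSITIONAL: dict(
            n=85,
            ck56=[(2, 3), (1, 21), (0, 61)],
            p63=[(2, 2), (1, 43), (0, 40)],
            gata6=[(3, 30), (2, 55)],
            hnf4a=[(2, 46), (1, 31), (0, 8)],
            histology=[(H.GLANDULAR, 73), (H.POR_COMP, 12)],
            stage=[(S.I, 7), (S.II, 8), (S.III, 14), (S.IV, 53), (S.UNKNOWN, 3)],
            male=45,
            young=42,
        ),
        P.BASAL_LIKE: dict(
            n=20,
            ck56=[(3, 14), (2, 6)],
            p63=[(3, 8), (2, 12)],
            gata6=[(2, 5), (1, 13), (0, 2)],
            hnf4a=[(0, 20)],
            histology=[(H.SQ_DIFF, 16), (H.POR_COMP, 4)],
            stage=[(S.II, 2), (S.III, 6), (S.IV, 12)],
            male=7,
            young=6,
        ),
    }
    cases = []
    idx = 0
    for pattern, cfg in blocks.items():
        n = cfg["n"]
        grades = {m: _expand(cfg[k]) for m, k in
                  [("CK56", "ck56"), ("P63", "p63"),
                   ("GATA6", "gata6"), ("HNF4A", "hnf4a")]}
        histology = _expand(cfg["histology"])
        stage = _expand(cfg["stage"])
        for i in range(n):
            idx += 1
            stains = {
                m: MarkerStain.from_grade(Marker(m), grades[m][i])
                for m in allred.MARKER_ORDER
            }
            cases.append(CaseRecord(
                case_id=f"FX{idx:03d}",
                stains=stains,
                histology=histology[i],
                stage=stage[i],
                sex=Sex.M if i < cfg["male"] else Sex.F,
                age_years=40 + (i % 30) if i < cfg["young"] else 70 + (i % 18),
                time_days=float(30 + 17 * i),
                event=(i % 3 != 0),
                latent_pattern=pattern,
            ))
    return Cohort(cases=tuple(cases))
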