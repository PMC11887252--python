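"""Automated improvement/worsening rubric (-2 ... +2) for paired tests.

Each protocol view is graded by comparing Test 2 against Test 1 on three
axes: the time needed to obtain the view, the final precision, and the RAR
motion index (summed over the analyzed mechanical coordinates).  The five
clauses below formalize the rubric; RAR comparisons are ratios to the
Test 1 value of the same view, and the clauses are evaluated in the fixed
precedence +2, -2, +1, -1, else 0, so the extreme grades win where the
prose clauses overlap:

    +2  t2 <= t1/2           and p2 >= 0.80 and r2 <= r1
    -2  t2 >  2*t1           and (p2 < 0.80 or r2 > 1.3*r1)
    +1  t2 <= 0.95*t1        and p2 >= 0.80 and r2 <= 1.3*r1
    -1  t2 >  1.05*t1        or  p2 < 0.80  or  r2 >= 2*r1
     0  otherwise

When the Test 1 RAR is zero the ratio is undefined; maintenance conditions
are then read as satisfied only when the Test 2 RAR is also zero, and
deterioration conditions as fired whenever it is positive.

A student's aggregate score is the arithmetic mean over graded views;
students are classified improved (mean > 0), neutral (mean = 0) or
worsened (mean < 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .kinematics import AnatomyModel
from .precision_metric import (HOLD_SECONDS, PASS_THRESHOLD, attempt_passed,
                               final_precision, precision_series,
                               _targets_by_id)
from .rar_index import attempt_rar_total
from .session_log import SessionLog, ViewAttempt

logger = logging.getLogger(__name__)

GRADE_VALUES = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class GradeInputs:
    """Paired per-view metrics feeding the rubric.

    ``t``: attempt durations (s); ``p``: final precisions (fraction);
    ``r``: RAR totals over the analyzed coordinates; ``passed``: the
    pass/fail outcome of each attempt (carried for reporting; the rubric
    itself uses times, precisions and RAR).
    """

    t1: float
    t2: float
    p1: float
    p2: float
    r1: float
    r2: float
    passed1: bool = True
    passed2: bool = True

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValidationError("attempt durations must be positive")
        if not (0 <= self.p1 <= 1 and 0 <= self.p2 <= 1):
            raise ValidationError("precisions must lie in [0, 1]")
        if self.r1 < 0 or self.r2 < 0:
            raise ValidationError("RAR values must be non-negative")


@dataclass(frozen=True)
class ViewGrade:
    """A rubric grade and the clause that produced it."""

    value: int
    rationale: str

    def __post_init__(self) -> None:
        if self.value not in GRADE_VALUES:
            raise ValidationError(f"grade {self.value} outside rubric range")


def _rar_maintained(r2: float, r1: float, factor: float) -> bool:
    """r2 <= factor * r1, with the zero-baseline convention."""
    if r1 == 0:
        return r2 == 0
    return r2 <= factor * r1


def _rar_worse(r2: float, r1: float, factor: float, strict: bool) -> bool:
    """r2 > factor*r1 (strict) or r2 >= factor*r1, zero-baseline aware."""
    if r1 == 0:
        return r2 > 0
    return r2 > factor * r1 if strict else r2 >= factor * r1


def grade_view(g: GradeInputs) -> ViewGrade:
    """Grade one view's Test 1 -> Test 2 change on the -2..+2 rubric."""
    if g.t2 <= 0.5 * g.t1 and g.p2 >= PASS_THRESHOLD and \
            _rar_maintained(g.r2, g.r1, 1.0):
        return ViewGrade(2, "significant improvement: time at least halved, "
                            "precision above cutoff, RAR not worse")
    if g.t2 > 2.0 * g.t1 and (g.p2 < PASS_THRESHOLD or
                              _rar_worse(g.r2, g.r1, 1.3, strict=True)):
        return ViewGrade(-2, "significant deterioration: time more than "
                             "doubled with precision or RAR deterioration")
    if g.t2 <= 0.95 * g.t1 and g.p2 >= PASS_THRESHOLD and \
            _rar_maintained(g.r2, g.r1, 1.3):
        return ViewGrade(1, "improvement: time shorter by 5-99% with "
                            "precision and RAR maintained")
    if g.t2 > 1.05 * g.t1 or g.p2 < PASS_THRESHOLD or \
            _rar_worse(g.r2, g.r1, 2.0, strict=False):
        return ViewGrade(-1, "deterioration: time longer by >5%, or "
                             "precision below cutoff, or RAR doubled")
    return ViewGrade(0, "no significant change")


# ---------------------------------------------------------------------------
# from raw sessions
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class StudentGradeReport:
    """Per-view grades and the aggregate score for one student."""

    student_id: str
    per_view: dict[int, ViewGrade]
    inputs: dict[int, GradeInputs]
    mean_score: float
    classification: str     # improved | neutral | worsened
    skipped_views: list[int] = field(default_factory=list)


def view_metrics(attempt: ViewAttempt, target, anatomy: AnatomyModel,
                 threshold: float = PASS_THRESHOLD,
                 hold: float = HOLD_SECONDS,
                 use_logged: bool = False) -> tuple[float, float, float, bool]:
    """(duration, final precision, RAR total, passed) of one attempt."""
    series = precision_series(attempt, target, anatomy, use_logged)
    passed = attempt_passed(series, attempt, threshold, hold)
    p = final_precision(series, attempt, threshold, hold)
    return attempt.duration, p, attempt_rar_total(attempt), passed


def grade_student(session1: SessionLog, session2: SessionLog, targets,
                  anatomy: AnatomyModel,
                  threshold: float = PASS_THRESHOLD,
                  hold: float = HOLD_SECONDS,
                  use_logged: bool = False) -> StudentGradeReport:
    """Grade all matched views of one student's Test 1 / Test 2 pair.

    Views present in only one test are excluded from grading (logged).
    """
    if session1.student_id != session2.student_id:
        raise ValidationError("sessions belong to different students")
    if not (session1.test_id == 1 and session2.test_id == 2):
        raise ValidationError("expected a (test 1, test 2) session pair")
    by_id = _targets_by_id(targets)

    per_view: dict[int, ViewGrade] = {}
    inputs: dict[int, GradeInputs] = {}
    skipped: list[int] = []
    ids = sorted({a.view_id for a in session1.attempts}
                 | {a.view_id for a in session2.attempts})
    for vid in ids:
        a1 = session1.attempt_for(vid)
        a2 = session2.attempt_for(vid)
        if a1 is None or a2 is None:
            skipped.append(vid)
            logger.warning("student %s: view %d present in one test only; "
                           "excluded from grading", session1.student_id, vid)
            continue
        t1, p1, r1, ok1 = view_metrics(a1, by_id[vid], anatomy, threshold,
                                       hold, use_logged)
        t2, p2, r2, ok2 = view_metrics(a2, by_id[vid], anatomy, threshold,
                                       hold, use_logged)
        g = GradeInputs(t1=t1, t2=t2, p1=p1, p2=p2, r1=r1, r2=r2,
                        passed1=ok1, passed2=ok2)
        inputs[vid] = g
        per_view[vid] = grade_view(g)

    if not per_view:
        raise ValidationError(
            f"student {session1.student_id}: no matched views to grade")
    mean = float(np.mean([g.value for g in per_view.values()]))
    cls = "improved" if mean > 0 else ("worsened" if mean < 0 else "neutral")
    return StudentGradeReport(student_id=session1.student_id,
                              per_view=per_view, inputs=inputs,
                              mean_score=mean, classification=cls,
                              skipped_views=skipped)


@dataclass(eq=False)
class CohortGradeSummary:
    """Cohort-level counts and moments of the per-student mean scores."""

    n: int
    improved: int
    neutral: int
    worsened: int
    mean: float
    sd: float
    student_means: dict[str, float]


def cohort_grade_summary(pairs, targets, anatomy: AnatomyModel,
                         threshold: float = PASS_THRESHOLD,
                         hold: float = HOLD_SECONDS,
                         use_logged: bool = False) -> CohortGradeSummary:
    """Summarize per-student rubric outcomes over a cohort of session pairs.

    ``pairs`` is a sequence of (test 1, test 2) :class:`SessionLog` pairs.
    The SD is the sample standard deviation of the per-student means.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("empty cohort")
    reports = [grade_student(s1, s2, targets, anatomy, threshold, hold,
                             use_logged) for s1, s2 in pairs]
    means = np.array([r.mean_score for r in reports])
    counts = {"improved": 0, "neutral": 0, "worsened": 0}
    for r in reports:
        counts[r.classification] += 1
    sd = float(np.std(means, ddof=1)) if means.size > 1 else 0.0
    return CohortGradeSummary(
        n=len(reports), improved=counts["improved"],
        neutral=counts["neutral"], worsened=counts["worsened"],
        mean=float(np.mean(means)), sd=sd,
        student_means={r.student_id: r.mean_score for r in reports})
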