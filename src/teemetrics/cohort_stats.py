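"""Descriptive and comparative statistics for paired Test 1 / Test 2 metrics.

Conventions
-----------
* Normality is assessed with the Shapiro-Wilk test at alpha = 0.05;
  ``normal`` is None for degenerate inputs (n < 3 or constant vectors),
  in which case median/IQR is the preferred summary.
* Quartiles use linear interpolation (the type-7 convention).
* The study design is intrinsically paired, so the default comparison is a
  paired t-test when the differences look normal and the Wilcoxon
  signed-rank test otherwise.  The unpaired two-sample procedures
  (Student's t / Mann-Whitney U) remain available via ``paired=False`` for
  fidelity with reports that used them.
* Paired pass/fail outcomes are compared with the exact McNemar test
  (binomial on the discordant pairs).
* p-values are two-sided and reported raw, without multiple-testing
  correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .kinematics import AnatomyModel
from .precision_metric import (HOLD_SECONDS, PASS_THRESHOLD, _targets_by_id,
                               precision_series, view_mean_precision)
from .rar_index import rar

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: view_ids of the four representative views singled out for subanalysis:
#: ME Mitral Commissural, ME Bicaval, ME Asc Ao SAX, TG Basal SAX
FOUR_VIEW_IDS = (3, 11, 8, 12)


def _shapiro_normal(values: np.ndarray) -> bool | None:
    if values.size < 3 or np.ptp(values) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(stats.shapiro(values).pvalue > ALPHA)


def describe(values) -> dict:
    """Summary statistics: mean, sd, median, q1, q3, n, normality flag."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot describe an empty vector")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # type-7 interpolation
    return {"mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "n": int(values.size),
            "normal": _shapiro_normal(values)}


def signed_rank_test(test1, test2) -> dict:
    """Two-sided Wilcoxon signed-rank test of paired values.

    Uses the exact null distribution whenever scipy supports it (no ties
    or zero differences), so small-sample p-values agree with a full
    sign-flip enumeration.
    """
    res = stats.wilcoxon(np.asarray(test2, dtype=float),
                         np.asarray(test1, dtype=float),
                         alternative="two-sided", method="auto")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "method": "wilcoxon signed-rank"}


def compare_paired(test1, test2, paired: bool = True) -> dict:
    """Two-sided comparison of Test 1 vs Test 2 values.

    Paired mode (default): paired t-test when the paired differences pass
    Shapiro-Wilk, otherwise the Wilcoxon signed-rank test (exact null
    distribution where scipy supports it).  Unpaired mode applies the
    two-sample Student's t or Mann-Whitney U test by the same normality
    routing.  Identical vectors short-circuit to p = 1.
    """
    x1 = np.asarray(test1, dtype=float)
    x2 = np.asarray(test2, dtype=float)
    if paired and x1.shape != x2.shape:
        raise ValidationError("paired vectors must have equal length")
    if min(x1.size, x2.size) < 3:
        return {"statistic": float("nan"), "p_value": float("nan"),
                "method": "insufficient n"}
    if paired:
        d = x2 - x1
        if np.all(d == 0):
            return {"statistic": 0.0, "p_value": 1.0, "method": "degenerate"}
        if _shapiro_normal(d):
            res = stats.ttest_rel(x2, x1)
            method = "paired t-test"
        else:
            return signed_rank_test(x1, x2)
    else:
        if _shapiro_normal(x1) and _shapiro_normal(x2):
            res = stats.ttest_ind(x2, x1)
            method = "student t-test"
        else:
            res = stats.mannwhitneyu(x2, x1, alternative="two-sided")
            method = "mann-whitney u"
    return {"statistic": float(res.statistic),
            "p_value": float(res.pvalue), "method": method}


def compare_pass_counts(passed1, passed2) -> dict:
    """Exact McNemar comparison of paired pass/fail outcomes.

    Builds the paired 2x2 table and applies the exact binomial test to the
    discordant counts (b: passed test 1 only, c: passed test 2 only).
    """
    p1 = np.asarray(passed1, dtype=bool)
    p2 = np.asarray(passed2, dtype=bool)
    if p1.shape != p2.shape:
        raise ValidationError("paired outcome vectors must align")
    table = {"both_passed": int(np.sum(p1 & p2)),
             "test1_only": int(np.sum(p1 & ~p2)),
             "test2_only": int(np.sum(~p1 & p2)),
             "both_failed": int(np.sum(~p1 & ~p2))}
    b, c = table["test1_only"], table["test2_only"]
    if b + c == 0:
        p_value = 1.0
    else:
        p_value = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
    return {"p_value": p_value, "table": table, "method": "exact mcnemar"}


# ---------------------------------------------------------------------------
# metric tables
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class MetricTable:
    """One metric's paired per-student values, aligned by student order."""

    name: str
    test1: np.ndarray
    test2: np.ndarray
    expert: float | None = None

    def __post_init__(self) -> None:
        self.test1 = np.asarray(self.test1, dtype=float)
        self.test2 = np.asarray(self.test2, dtype=float)
        if self.test1.shape != self.test2.shape:
            raise ValidationError(f"{self.name}: paired vectors must align")

    def summary(self, paired: bool = True) -> dict:
        out = {"metric": self.name,
               "test1": describe(self.test1),
               "test2": describe(self.test2),
               "comparison": compare_paired(self.test1, self.test2,
                                            paired=paired)}
        if self.expert is not None:
            out["expert"] = float(self.expert)
        return out


def four_view_subanalysis(pairs, targets, anatomy: AnatomyModel,
                          view_ids=FOUR_VIEW_IDS,
                          threshold: float = PASS_THRESHOLD,
                          hold: float = HOLD_SECONDS,
                          use_logged: bool = False,
                          paired: bool = True) -> dict[int, dict]:
    """Per-view metric tables restricted to the four representative views.

    For each selected view, builds paired tables of attempt time, mean
    precision, rotation RAR and ante/retroflexion RAR across students, each
    with descriptive summaries and a paired comparison.  Students missing
    the view in either test are excluded from that view's table (logged);
    single-student tables skip the comparison.
    """
    by_id = _targets_by_id(targets)
    pairs = list(pairs)
    out: dict[int, dict] = {}
    for vid in view_ids:
        if vid not in by_id:
            logger.warning("view %d not in protocol; excluded from "
                           "subanalysis", vid)
            continue
        rows = {"time": ([], []), "precision": ([], []),
                "rar_rotation": ([], []), "rar_ante_retro": ([], [])}
        for s1, s2 in pairs:
            a1, a2 = s1.attempt_for(vid), s2.attempt_for(vid)
            if a1 is None or a2 is None:
                logger.warning("student %s: view %d missing in one test; "
                               "excluded from subanalysis",
                               s1.student_id, vid)
                continue
            for k, a in ((0, a1), (1, a2)):
                series = precision_series(a, by_id[vid], anatomy, use_logged)
                rows["time"][k].append(a.duration)
                rows["precision"][k].append(view_mean_precision(series))
                rows["rar_rotation"][k].append(rar(a.rotation, a.t))
                rows["rar_ante_retro"][k].append(rar(a.ante_retro, a.t))
        if not rows["time"][0]:
            logger.warning("view %d: no complete pairs; excluded", vid)
            continue
        out[vid] = {"view_name": by_id[vid].view_name}
        for name, (v1, v2) in rows.items():
            out[vid][name] = MetricTable(name, v1, v2).summary(paired=paired)
    return out
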