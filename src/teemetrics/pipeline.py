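"""End-to-end orchestration: ingest or simulate -> metrics -> grades -> stats.

``run`` drives a complete analysis from a :class:`RunConfig`: it resolves
the anatomy and protocol, obtains a cohort of paired sessions (either by
reading a logs directory or by simulating one), computes per-view metrics,
rubric grades and cohort statistics, and writes a deterministic report
bundle:

* ``views.csv``    -- one row per student/test/view with duration, mean and
  final precision, pass flag and per-coordinate RAR;
* ``grades.csv``   -- rubric inputs and grade per student/view;
* ``report.json``  -- machine-readable mirror of every table;
* ``manifest.json``-- version, config hash, seed and input checksums.

Two runs with the same seed and config produce byte-identical JSON.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .cohort_stats import (FOUR_VIEW_IDS, MetricTable, compare_pass_counts,
                           four_view_subanalysis)
from .errors import SessionFormatError, ValidationError
from .grading import GradeInputs, grade_view, view_metrics
from .kinematics import AnatomyModel, load_anatomy
from .precision_metric import (HOLD_SECONDS, PASS_THRESHOLD, PROTOCOL_SIZE,
                               _targets_by_id, load_protocol,
                               precision_series, view_mean_precision)
from .rar_index import ANALYZED_COORDS, FIGURE_COORDS, rar_per_coordinate
from .session_log import SessionLog, read_session, write_session
from .synthetic_data import CohortSpec, expert_reference, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode must be set: ``logs_dir`` (ingest existing
    session files) or ``simulate`` (cohort simulation parameters:
    ``n_students``, ``improvement_fraction``; the run seed applies).
    """

    out_dir: str = "teemetrics_out"
    logs_dir: str | None = None
    simulate: dict | None = None
    anatomy_path: str | None = None
    protocol_path: str | None = None
    threshold: float = PASS_THRESHOLD
    hold: float = HOLD_SECONDS
    paired_stats: bool = True
    use_logged_precision: bool = False
    include_expert: bool = True
    figures: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.logs_dir is None) == (self.simulate is None):
            raise ValidationError(
                "exactly one input mode required: logs_dir or simulate")
        if not 0 < self.threshold <= 1:
            raise ValidationError("threshold must lie in (0, 1]")
        if self.hold <= 0:
            raise ValidationError("hold must be positive")


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: RunConfig) -> str:
    doc = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


def version_and_provenance(config: RunConfig,
                           input_files: list[Path]) -> dict:
    """Manifest: tool version, config hash, seed and input checksums."""
    return {"tool": "teemetrics",
            "version": __version__,
            "config": asdict(config),
            "config_hash": config_hash(config),
            "seed": config.seed,
            "inputs": {str(p): _sha256_file(Path(p))
                       for p in sorted(map(str, input_files))}}


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------

def load_cohort(logs_dir: str | Path
                ) -> tuple[list[tuple[SessionLog, SessionLog]], list[Path],
                           list[str]]:
    """Read all session files in a directory and pair them by student.

    Returns (pairs, files_read, errors); invalid sessions are reported and
    skipped so the run continues for the valid remainder.
    """
    logs_dir = Path(logs_dir)
    files = sorted(list(logs_dir.glob("*.csv")) + list(logs_dir.glob("*.json")))
    by_student: dict[str, dict[int, SessionLog]] = {}
    errors: list[str] = []
    read_ok: list[Path] = []
    for path in files:
        if path.name == "manifest.json":
            continue
        try:
            s = read_session(path)
        except (SessionFormatError, ValidationError) as exc:
            errors.append(f"{path.name}: {exc}")
            logger.error("skipping %s: %s", path.name, exc)
            continue
        read_ok.append(path)
        by_student.setdefault(s.student_id, {})[s.test_id] = s
    pairs = []
    for sid in sorted(by_student):
        tests = by_student[sid]
        if 1 in tests and 2 in tests:
            pairs.append((tests[1], tests[2]))
        else:
            errors.append(f"student {sid}: missing test "
                          f"{1 if 1 not in tests else 2}")
            logger.warning("student %s lacks a complete test pair", sid)
    return pairs, read_ok, errors


# ---------------------------------------------------------------------------
# analysis core
# ---------------------------------------------------------------------------

def _attempt_record(student_id: str, test_id: int, attempt, target, anatomy,
                    threshold, hold, use_logged) -> dict:
    series = precision_series(attempt, target, anatomy, use_logged)
    duration, final_p, rar_total, passed = view_metrics(
        attempt, target, anatomy, threshold, hold, use_logged)
    rec = {"student_id": student_id, "test_id": test_id,
           "view_id": attempt.view_id, "view_name": attempt.view_name,
           "duration_s": duration,
           "mean_precision": view_mean_precision(series),
           "final_precision": final_p,
           "passed": passed,
           "perforated": attempt.perforated,
           "rar_total": rar_total}
    for c, v in rar_per_coordinate(attempt).items():
        rec[f"rar_{c}"] = v
    return rec


def analyze_cohort(pairs, targets, anatomy: AnatomyModel,
                   threshold: float = PASS_THRESHOLD,
                   hold: float = HOLD_SECONDS,
                   paired: bool = True,
                   use_logged: bool = False,
                   expert: SessionLog | None = None,
                   protocol_size: int = PROTOCOL_SIZE) -> dict:
    """Compute every table of the report from a cohort of session pairs."""
    by_id = _targets_by_id(targets)
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("empty cohort")

    view_rows: list[dict] = []
    per_student: dict[str, dict[int, dict[int, dict]]] = {}
    for s1, s2 in pairs:
        sid = s1.student_id
        per_student[sid] = {1: {}, 2: {}}
        for s in (s1, s2):
            for a in s.attempts:
                rec = _attempt_record(sid, s.test_id, a, by_id[a.view_id],
                                      anatomy, threshold, hold, use_logged)
                view_rows.append(rec)
                per_student[sid][s.test_id][a.view_id] = rec

    students = sorted(per_student)

    # rubric grades from the per-attempt metrics
    grade_rows: list[dict] = []
    student_means: dict[str, float] = {}
    for sid in students:
        t1v, t2v = per_student[sid][1], per_student[sid][2]
        values = []
        for vid in sorted(set(t1v) & set(t2v)):
            r1, r2 = t1v[vid], t2v[vid]
            g = GradeInputs(t1=r1["duration_s"], t2=r2["duration_s"],
                            p1=r1["final_precision"], p2=r2["final_precision"],
                            r1=r1["rar_total"], r2=r2["rar_total"],
                            passed1=r1["passed"], passed2=r2["passed"])
            grade = grade_view(g)
            values.append(grade.value)
            grade_rows.append({"student_id": sid, "view_id": vid,
                               "t1": g.t1, "t2": g.t2, "p1": g.p1,
                               "p2": g.p2, "r1": g.r1, "r2": g.r2,
                               "grade": grade.value,
                               "clause": grade.rationale})
        student_means[sid] = float(np.mean(values))

    means = np.array([student_means[s] for s in students])
    grades_block = {
        "per_student_mean": student_means,
        "improved": int(np.sum(means > 0)),
        "neutral": int(np.sum(means == 0)),
        "worsened": int(np.sum(means < 0)),
        "mean": float(np.mean(means)),
        "sd": float(np.std(means, ddof=1)) if means.size > 1 else 0.0}

    # session-level metric tables
    def session_values(test_id: int, fn) -> list[float]:
        return [fn(per_student[s][test_id]) for s in students]

    def total_time(view_map) -> float:
        return float(sum(r["duration_s"] for r in view_map.values()))

    def mean_prec(view_map) -> float:
        return float(np.mean([r["mean_precision"] for r in view_map.values()]))

    def n_passed(view_map) -> int:
        return int(sum(r["passed"] for r in view_map.values()))

    def success_pct(view_map) -> float:
        return 100.0 * n_passed(view_map) / protocol_size

    def all_passed(view_map) -> bool:
        return (len(view_map) >= protocol_size
                and n_passed(view_map) == len(view_map))

    passed1 = [all_passed(per_student[s][1]) for s in students]
    passed2 = [all_passed(per_student[s][2]) for s in students]

    expert_block = None
    if expert is not None:
        e_rows = [_attempt_record(expert.student_id, expert.test_id, a,
                                  by_id[a.view_id], anatomy, threshold, hold,
                                  use_logged)
                  for a in expert.attempts]
        expert_block = {
            "total_time_s": float(sum(r["duration_s"] for r in e_rows)),
            "mean_precision": float(np.mean([r["mean_precision"]
                                             for r in e_rows])),
            "n_passed": int(sum(r["passed"] for r in e_rows)),
            "rar": {c: float(sum(r[f"rar_{c}"] for r in e_rows))
                    for c in ANALYZED_COORDS}}

    def table(name, fn, expert_value=None) -> dict:
        return MetricTable(name, session_values(1, fn),
                           session_values(2, fn),
                           expert=expert_value).summary(paired=paired)

    e = expert_block or {}
    rar_tables = {}
    for c in ANALYZED_COORDS:
        def rar_sum(view_map, c=c):
            return float(sum(r[f"rar_{c}"] for r in view_map.values()))
        rar_tables[c] = table(f"rar_{c}", rar_sum,
                              e.get("rar", {}).get(c))
        rar_tables[c]["in_figures"] = c in FIGURE_COORDS

    report = {
        "n_students": len(students),
        "students": students,
        "pass_counts": {
            "test1_passed": int(np.sum(passed1)),
            "test2_passed": int(np.sum(passed2)),
            "per_student": {s: [bool(passed1[i]), bool(passed2[i])]
                            for i, s in enumerate(students)},
            "mcnemar": compare_pass_counts(passed1, passed2)},
        "success_percentage": table("success_percentage", success_pct),
        "mean_precision": table("mean_precision", mean_prec,
                                e.get("mean_precision")),
        "total_time_s": table("total_time_s", total_time,
                              e.get("total_time_s")),
        "rar": rar_tables,
        "four_views": four_view_subanalysis(
            pairs, targets, anatomy, FOUR_VIEW_IDS, threshold, hold,
            use_logged, paired),
        "grades": grades_block,
        "expert": expert_block,
        "views": view_rows,
        "grade_rows": grade_rows,
    }
    return report


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

_VIEW_CSV_COLS = ("student_id", "test_id", "view_id", "view_name",
                  "duration_s", "mean_precision", "final_precision",
                  "passed", "perforated", "rar_total",
                  *(f"rar_{c}" for c in ANALYZED_COORDS))

_GRADE_CSV_COLS = ("student_id", "view_id", "t1", "t2", "p1", "p2",
                   "r1", "r2", "grade", "clause")


def _write_table_csv(rows: list[dict], cols, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(cols), extrasaction="ignore")
        w.writeheader()
        w.writerows(rows)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(doc: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the report dict; raises :class:`TeemetricsError` subclasses on
    unusable configuration or inputs.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    anatomy = load_anatomy(config.anatomy_path)
    targets = load_protocol(config.protocol_path, anatomy=anatomy)

    input_files: list[Path] = []
    for p in (config.anatomy_path, config.protocol_path):
        if p is not None:
            input_files.append(Path(p))

    ingest_errors: list[str] = []
    if config.logs_dir is not None:
        pairs, files, ingest_errors = load_cohort(config.logs_dir)
        input_files.extend(files)
        if not pairs:
            raise SessionFormatError(
                f"no complete session pairs found in {config.logs_dir}")
    else:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        spec = CohortSpec(**sim)
        pairs = simulate_cohort(spec, anatomy)

    expert = None
    if config.include_expert:
        expert = expert_reference(targets, anatomy, seed=config.seed)

    report = analyze_cohort(pairs, targets, anatomy,
                            threshold=config.threshold, hold=config.hold,
                            paired=config.paired_stats,
                            use_logged=config.use_logged_precision,
                            expert=expert)
    # echo only the fields that influence the numbers, so identical
    # analyses written to different places stay byte-identical
    cfg_echo = asdict(config)
    for key in ("out_dir", "log_level", "figures"):
        cfg_echo.pop(key, None)
    report["config"] = cfg_echo
    if ingest_errors:
        report["ingest_errors"] = ingest_errors

    _write_table_csv(report["views"], _VIEW_CSV_COLS, out_dir / "views.csv")
    _write_table_csv(report["grade_rows"], _GRADE_CSV_COLS,
                     out_dir / "grades.csv")
    _dump_json(report, out_dir / "report.json")
    manifest = version_and_provenance(config, input_files)
    manifest["outputs"] = ["views.csv", "grades.csv", "report.json"]
    if config.figures:
        from .plots import cohort_figures
        manifest["outputs"] += cohort_figures(report, out_dir)
    _dump_json(manifest, out_dir / "manifest.json")
    return report


def write_simulated_logs(spec: CohortSpec, out_dir: str | Path,
                         anatomy: AnatomyModel | None = None) -> list[Path]:
    """Simulate a cohort and write one CSV per session plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = simulate_cohort(spec, anatomy)
    written: list[Path] = []
    for s1, s2 in pairs:
        for s in (s1, s2):
            path = out_dir / f"{s.student_id}_test{s.test_id}.csv"
            write_session(s, path)
            written.append(path)
    manifest = {"tool": "teemetrics", "version": __version__,
                "spec": {"n_students": spec.n_students,
                         "improvement_fraction": spec.improvement_fraction,
                         "seed": spec.seed},
                "files": [p.name for p in written]}
    _dump_json(manifest, out_dir / "manifest.json")
    return written
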