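"""Data model and file I/O for simulator probe-motion logs.

A session is one student's complete proficiency test on the TEE simulator:
an ordered sequence of view attempts, each a multi-coordinate time series of
the probe control state sampled nominally every 100 ms.  The five logged
control coordinates are insertion depth (cm), probe rotation (deg),
ante/retroflexion (deg, anteflexion positive), left/right flexion (deg,
leftward positive) and the electronic omniplane angle (deg, 0-180).  An
optional per-sample precision fraction and a perforation event flag complete
the record.

Two on-disk dialects are supported, selected by file extension:

* ``.csv`` -- long format, one row per sample, columns
  ``student_id, test_id, view_id, view_name, t, depth, rotation, ante_retro,
  left_right, omniplane, precision, event``.  Lines starting with ``#`` are
  comments; ``#meta key=<json>`` lines carry session metadata.
* ``.json`` -- one object per session mirroring the same content.

Floats are written in shortest round-trip representation so that
``read_session(write_session(s)) == s`` holds exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import SessionFormatError, ValidationError

#: the five probe control coordinates, in canonical column order
CONTROL_COORDS = ("depth", "rotation", "ante_retro", "left_right", "omniplane")

CSV_COLUMNS = ("student_id", "test_id", "view_id", "view_name", "t",
               *CONTROL_COORDS, "precision", "event")

PERFORATION_EVENT = "perforation"

_OMNIPLANE_RANGE = (0.0, 180.0)
_EPS = 1e-9


class Sample(NamedTuple):
    """One timestamped probe control state."""

    t: float
    depth: float
    rotation: float
    ante_retro: float
    left_right: float
    omniplane: float
    precision: float | None = None


class GapReport(NamedTuple):
    """An inter-sample interval deviating from the nominal sampling period."""

    index: int      #: index of the interval (between samples index and index+1)
    dt: float       #: observed interval, seconds


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(eq=False)
class ViewAttempt:
    """The contiguous trajectory segment recorded for one protocol view.

    Coordinate channels are stored as equal-length float arrays; ``precision``
    is either ``None`` (not logged) or an array of fractions in [0, 1].
    """

    view_id: int
    view_name: str
    t: np.ndarray
    depth: np.ndarray
    rotation: np.ndarray
    ante_retro: np.ndarray
    left_right: np.ndarray
    omniplane: np.ndarray
    precision: np.ndarray | None = None
    perforated: bool = False

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t)
        for name in CONTROL_COORDS:
            setattr(self, name, _as_float_array(getattr(self, name)))
        if self.precision is not None:
            self.precision = _as_float_array(self.precision)
        self.view_id = int(self.view_id)
        self.perforated = bool(self.perforated)

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Attempt duration in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])

    def coord(self, name: str) -> np.ndarray:
        if name not in CONTROL_COORDS:
            raise KeyError(f"unknown coordinate {name!r}")
        return getattr(self, name)

    def control_array(self) -> np.ndarray:
        """(n_samples, 5) array of control coordinates in canonical order."""
        return np.column_stack([getattr(self, c) for c in CONTROL_COORDS])

    @property
    def samples(self) -> list[Sample]:
        prec: list[float | None]
        if self.precision is None:
            prec = [None] * self.n_samples
        else:
            prec = [float(p) for p in self.precision]
        return [Sample(float(self.t[i]), float(self.depth[i]),
                       float(self.rotation[i]), float(self.ante_retro[i]),
                       float(self.left_right[i]), float(self.omniplane[i]),
                       prec[i])
                for i in range(self.n_samples)]

    @classmethod
    def from_samples(cls, view_id: int, view_name: str,
                     samples: list[Sample], perforated: bool = False
                     ) -> "ViewAttempt":
        if not samples:
            raise ValidationError(f"view {view_id}: attempt has no samples")
        precs = [s.precision for s in samples]
        has_prec = any(p is not None for p in precs)
        if has_prec and any(p is None for p in precs):
            raise ValidationError(
                f"view {view_id}: precision present on some samples only")
        return cls(
            view_id=view_id, view_name=view_name,
            t=[s.t for s in samples],
            depth=[s.depth for s in samples],
            rotation=[s.rotation for s in samples],
            ante_retro=[s.ante_retro for s in samples],
            left_right=[s.left_right for s in samples],
            omniplane=[s.omniplane for s in samples],
            precision=[s.precision for s in samples] if has_prec else None,
            perforated=perforated)

    # -- validation & equality --------------------------------------------

    def validate(self) -> None:
        label = f"view {self.view_id} ({self.view_name})"
        if self.n_samples < 2:
            raise ValidationError(f"{label}: fewer than 2 samples")
        arrays = [self.t] + [self.coord(c) for c in CONTROL_COORDS]
        for arr in arrays:
            if arr.shape != self.t.shape:
                raise ValidationError(f"{label}: channel length mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{label}: non-finite value")
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValidationError(
                f"{label}: non-monotone time at row {int(bad[0]) + 1}")
        lo, hi = _OMNIPLANE_RANGE
        if np.any(self.omniplane < lo - _EPS) or np.any(self.omniplane > hi + _EPS):
            raise ValidationError(f"{label}: omniplane outside [0, 180]")
        if self.precision is not None:
            if self.precision.shape != self.t.shape:
                raise ValidationError(f"{label}: precision length mismatch")
            if not np.all(np.isfinite(self.precision)):
                raise ValidationError(f"{label}: non-finite precision")
            if np.any(self.precision < -_EPS) or np.any(self.precision > 1 + _EPS):
                raise ValidationError(f"{label}: precision outside [0, 1]")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ViewAttempt):
            return NotImplemented
        if (self.view_id, self.view_name, self.perforated) != \
           (other.view_id, other.view_name, other.perforated):
            return False
        for name in ("t", *CONTROL_COORDS):
            if not np.array_equal(getattr(self, name), getattr(other, name)):
                return False
        if (self.precision is None) != (other.precision is None):
            return False
        if self.precision is not None and \
           not np.array_equal(self.precision, other.precision):
            return False
        return True


@dataclass(eq=False)
class SessionLog:
    """One student's full proficiency test (ordered view attempts)."""

    student_id: str
    test_id: int
    attempts: list[ViewAttempt]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.test_id = int(self.test_id)

    def attempt_for(self, view_id: int) -> ViewAttempt | None:
        for a in self.attempts:
            if a.view_id == view_id:
                return a
        return None

    @property
    def total_time(self) -> float:
        """Sum of attempt durations, seconds."""
        return float(sum(a.duration for a in self.attempts))

    def validate(self) -> None:
        if self.test_id not in (1, 2):
            raise ValidationError(
                f"session {self.student_id}: test_id must be 1 or 2")
        seen: set[int] = set()
        prev = None
        for a in self.attempts:
            if a.view_id in seen:
                raise ValidationError(
                    f"session {self.student_id}: duplicate view_id {a.view_id}")
            seen.add(a.view_id)
            if prev is not None and a.view_id < prev:
                raise ValidationError(
                    f"session {self.student_id}: attempts out of protocol "
                    f"order at view_id {a.view_id}")
            prev = a.view_id
            a.validate()

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionLog):
            return NotImplemented
        return (self.student_id == other.student_id
                and self.test_id == other.test_id
                and self.metadata == other.metadata
                and self.attempts == other.attempts)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips the float exactly."""
    return repr(float(x))


def read_session(path: str | Path) -> SessionLog:
    """Read and validate one session file (CSV or JSON by extension)."""
    path = Path(path)
    if not path.exists():
        raise SessionFormatError(f"no such file: {path}")
    if path.suffix.lower() == ".json":
        session = _read_json(path)
    else:
        session = _read_csv(path)
    session.validate()
    return session


def write_session(session: SessionLog, path: str | Path) -> Path:
    """Write a validated session to CSV or JSON (by extension)."""
    session.validate()
    path = Path(path)
    if path.suffix.lower() == ".json":
        _write_json(session, path)
    else:
        _write_csv(session, path)
    return path


def _read_metadata_lines(path: Path) -> dict:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("#meta "):
                body = line[len("#meta "):].strip()
                key, _, value = body.partition("=")
                try:
                    meta[key] = json.loads(value)
                except json.JSONDecodeError:
                    meta[key] = value
    return meta


def _read_csv(path: Path) -> SessionLog:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip",
                         dtype={"student_id": str, "view_name": str,
                                "event": str})
    except pd.errors.EmptyDataError:
        raise SessionFormatError(f"{path}: empty file") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(
            f"{path}: missing required column '{missing[0]}'")

    meta = _read_metadata_lines(path)
    if df.empty:
        sid = meta.pop("student_id", "unknown")
        tid = meta.pop("test_id", 1)
        return SessionLog(str(sid), int(tid), [], metadata=meta)

    sids = df["student_id"].unique()
    tids = df["test_id"].unique()
    if len(sids) != 1 or len(tids) != 1:
        raise SessionFormatError(
            f"{path}: a session file must contain one student_id/test_id pair")
    meta.pop("student_id", None)
    meta.pop("test_id", None)

    attempts: list[ViewAttempt] = []
    # contiguous blocks of view_id delimit attempts; a strict time reset
    # (t restarting from attempt start) opens a new block too, so a
    # re-visited view surfaces as a duplicate during validation instead of
    # being merged silently
    vid = df["view_id"].to_numpy()
    tcol = df["t"].to_numpy(dtype=float)
    boundary = (vid[1:] != vid[:-1]) | (tcol[1:] < tcol[:-1])
    blocks = np.concatenate([[0], np.cumsum(boundary)])
    for _, grp in df.groupby(blocks, sort=False):
        view_id = grp["view_id"].iloc[0]
        prec = grp["precision"].to_numpy(dtype=float)
        if np.all(np.isnan(prec)):
            prec_arr = None
        elif np.any(np.isnan(prec)):
            raise SessionFormatError(
                f"{path}: view {view_id} has precision on some rows only")
        else:
            prec_arr = prec
        events = grp["event"].fillna("")
        perforated = (events == PERFORATION_EVENT).any()
        attempts.append(ViewAttempt(
            view_id=int(view_id),
            view_name=str(grp["view_name"].iloc[0]),
            t=grp["t"].to_numpy(dtype=float),
            depth=grp["depth"].to_numpy(dtype=float),
            rotation=grp["rotation"].to_numpy(dtype=float),
            ante_retro=grp["ante_retro"].to_numpy(dtype=float),
            left_right=grp["left_right"].to_numpy(dtype=float),
            omniplane=grp["omniplane"].to_numpy(dtype=float),
            precision=prec_arr,
            perforated=bool(perforated)))

    return SessionLog(str(sids[0]), int(tids[0]), attempts, metadata=meta)


def _write_csv(session: SessionLog, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# teemetrics session log: depth in cm, angles in deg "
                 "(anteflex/leftward positive), t in s from attempt start\n")
        if not session.attempts:
            fh.write(f"#meta student_id={json.dumps(session.student_id)}\n")
            fh.write(f"#meta test_id={json.dumps(session.test_id)}\n")
        for key, value in session.metadata.items():
            fh.write(f"#meta {key}={json.dumps(value)}\n")
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for a in session.attempts:
            event = PERFORATION_EVENT if a.perforated else ""
            for i in range(a.n_samples):
                prec = "" if a.precision is None else _fmt(a.precision[i])
                writer.writerow([
                    session.student_id, session.test_id, a.view_id,
                    a.view_name, _fmt(a.t[i]), _fmt(a.depth[i]),
                    _fmt(a.rotation[i]), _fmt(a.ante_retro[i]),
                    _fmt(a.left_right[i]), _fmt(a.omniplane[i]),
                    prec, event])


def _attempt_to_dict(a: ViewAttempt) -> dict:
    d = {"view_id": a.view_id, "view_name": a.view_name,
         "perforated": a.perforated,
         "t": a.t.tolist()}
    for c in CONTROL_COORDS:
        d[c] = a.coord(c).tolist()
    d["precision"] = None if a.precision is None else a.precision.tolist()
    return d


def _write_json(session: SessionLog, path: Path) -> None:
    doc = {"student_id": session.student_id,
           "test_id": session.test_id,
           "metadata": session.metadata,
           "attempts": [_attempt_to_dict(a) for a in session.attempts]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _read_json(path: Path) -> SessionLog:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("student_id", "test_id", "attempts"):
        if key not in doc:
            raise SessionFormatError(f"{path}: missing required column '{key}'")
    attempts = []
    for ad in doc["attempts"]:
        missing = [k for k in ("view_id", "view_name", "t", *CONTROL_COORDS)
                   if k not in ad]
        if missing:
            raise SessionFormatError(
                f"{path}: missing required column '{missing[0]}'")
        attempts.append(ViewAttempt(
            view_id=ad["view_id"], view_name=ad["view_name"],
            t=ad["t"],
            **{c: ad[c] for c in CONTROL_COORDS},
            precision=ad.get("precision"),
            perforated=bool(ad.get("perforated", False))))
    return SessionLog(str(doc["student_id"]), int(doc["test_id"]),
                      attempts, metadata=doc.get("metadata", {}))


# ---------------------------------------------------------------------------
# sampling diagnostics
# ---------------------------------------------------------------------------

def resample_check(attempt: ViewAttempt, nominal_dt: float = 0.1,
                   tol: float = 0.5) -> list[GapReport]:
    """Report inter-sample intervals deviating from the nominal 100 ms clock.

    An interval ``dt`` is flagged when ``|dt - nominal_dt| > tol * nominal_dt``.
    An empty list means clean sampling.  No interpolation is performed; RAR
    and precision averaging use the actual timestamps.
    """
    dts = np.diff(attempt.t)
    bad = np.flatnonzero(np.abs(dts - nominal_dt) > tol * nominal_dt)
    return [GapReport(int(i), float(dts[i])) for i in bad]
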