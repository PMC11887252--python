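"""Plane-precision scoring and pass/fail decisions.

Each protocol view is defined by three expert landmark points P1..P3 and
per-point tolerance limits L1..L3: the ideal imaging plane contains all
three points, and a plane is still acceptable while each point lies within
its tolerance distance of the plane.  Precision maps the three
perpendicular point-to-plane distances d_i onto a fraction:

    precision = clamp(1 - 0.2 * mean_i(d_i / L_i), 0, 1)

so a plane through all three points scores 1.0 and a plane exactly at the
tolerance limits scores 0.80 -- the published pass cutoff.  A view is
passed when the attempt ends in a held state: every sample in the trailing
window of at least ``hold`` seconds (default 3 s) is at or above the
threshold (default 0.80), and no perforation occurred.  A session is passed
when all 16 protocol views are passed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .kinematics import (AnatomyModel, ControlState, Plane, load_anatomy,
                         probe_plane, probe_planes)
from .session_log import SessionLog, ViewAttempt

PASS_THRESHOLD = 0.80
HOLD_SECONDS = 3.0
PROTOCOL_SIZE = 16

_EPS = 1e-9


@dataclass(eq=False)
class TargetView:
    """A view's expert-defined ideal plane and acceptance limits."""

    view_id: int
    view_name: str
    ref_points: np.ndarray      # (3, 3), cm
    tolerances: np.ndarray      # (3,), cm, positive
    target_state: ControlState

    def __post_init__(self) -> None:
        self.ref_points = np.asarray(self.ref_points, dtype=float)
        self.tolerances = np.asarray(self.tolerances, dtype=float)
        if self.ref_points.shape != (3, 3):
            raise ValidationError("ref_points must be (3, 3)")
        if self.tolerances.shape != (3,) or np.any(self.tolerances <= 0):
            raise ValidationError("tolerances must be 3 positive distances")
        v1 = self.ref_points[1] - self.ref_points[0]
        v2 = self.ref_points[2] - self.ref_points[0]
        if np.linalg.norm(np.cross(v1, v2)) < 1e-9:
            raise ValidationError(
                f"view {self.view_id}: reference points are collinear")


@dataclass(eq=False)
class PrecisionSeries:
    """Per-sample precision fractions aligned with an attempt's timestamps."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must align")


# ---------------------------------------------------------------------------
# core scoring
# ---------------------------------------------------------------------------

def point_plane_distance(p: np.ndarray, plane: Plane) -> float:
    """Perpendicular distance from a point to a plane, cm."""
    return float(abs(np.dot(np.asarray(p, dtype=float) - plane.origin,
                            plane.normal)))


def precision(plane: Plane, target: TargetView) -> float:
    """Precision fraction of one plane against a view's landmarks."""
    d = np.abs((target.ref_points - plane.origin) @ plane.normal)
    return float(np.clip(1.0 - 0.2 * np.mean(d / target.tolerances), 0.0, 1.0))


def _precision_values(origins: np.ndarray, normals: np.ndarray,
                      in_range: np.ndarray, target: TargetView) -> np.ndarray:
    # distances of the 3 landmarks to every plane, vectorized
    diff = target.ref_points[None, :, :] - origins[:, None, :]   # (n, 3, 3)
    d = np.abs(np.einsum("nij,nj->ni", diff, normals))
    vals = np.clip(1.0 - 0.2 * np.mean(d / target.tolerances, axis=1),
                   0.0, 1.0)
    vals[~in_range] = 0.0
    return vals


def precision_series(attempt: ViewAttempt, target: TargetView,
                     anatomy: AnatomyModel,
                     use_logged: bool = False) -> PrecisionSeries:
    """Per-sample precision for an attempt.

    By default precision is recomputed from geometry through the forward
    kinematic model; samples whose depth leaves the navigable range score 0.
    With ``use_logged=True`` the precision channel recorded in the log is
    returned instead (an error if the log carries none).
    """
    if use_logged:
        if attempt.precision is None:
            raise ValidationError(
                f"view {attempt.view_id}: no logged precision channel")
        return PrecisionSeries(attempt.t.copy(), attempt.precision.copy())
    origins, normals, _, in_range = probe_planes(anatomy,
                                                 attempt.control_array())
    return PrecisionSeries(attempt.t.copy(),
                           _precision_values(origins, normals, in_range,
                                             target))


def detect_perforation(attempt: ViewAttempt, anatomy: AnatomyModel) -> bool:
    """True when any sample's depth exceeds the perforation limit."""
    return bool(np.any(attempt.depth > anatomy.max_depth_perforation))


# ---------------------------------------------------------------------------
# pass rule
# ---------------------------------------------------------------------------

def _hold_start_index(times: np.ndarray, values: np.ndarray,
                      threshold: float, hold: float) -> int | None:
    """Start index of the terminal held window, or None if not held.

    The window runs from the first sample after the last sub-threshold one
    to the end of the attempt and must span at least ``hold`` seconds.
    """
    below = np.flatnonzero(values < threshold)
    j = 0 if below.size == 0 else int(below[-1]) + 1
    if j >= times.size:
        return None
    if times[-1] - times[j] >= hold - _EPS:
        return j
    return None


def attempt_passed(series: PrecisionSeries, attempt: ViewAttempt,
                   threshold: float = PASS_THRESHOLD,
                   hold: float = HOLD_SECONDS) -> bool:
    """Pass rule: not perforated, and final precision held above threshold.

    "Final" is read strictly: the attempt must end inside the held window.
    Attempts shorter than ``hold`` cannot pass.
    """
    if attempt.perforated:
        return False
    return _hold_start_index(series.times, series.values,
                             threshold, hold) is not None


def final_precision(series: PrecisionSeries, attempt: ViewAttempt,
                    threshold: float = PASS_THRESHOLD,
                    hold: float = HOLD_SECONDS) -> float:
    """Final precision of an attempt.

    Mean precision over the terminal held window when the attempt ends
    held; otherwise the last sample's precision.
    """
    j = _hold_start_index(series.times, series.values, threshold, hold)
    if j is None or attempt.perforated:
        return float(series.values[-1])
    return float(np.mean(series.values[j:]))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def view_mean_precision(series: PrecisionSeries) -> float:
    """Arithmetic mean of all precision samples of one view."""
    if series.values.size == 0:
        raise ValidationError("empty precision series")
    return float(np.mean(series.values))


def _targets_by_id(targets) -> dict[int, TargetView]:
    if isinstance(targets, dict):
        return targets
    return {tv.view_id: tv for tv in targets}


def test_mean_precision(session: SessionLog, targets, anatomy: AnatomyModel,
                        use_logged: bool = False) -> float:
    """Mean over the session's views of the per-view mean precision.

    Per-view means are computed first, then averaged unweighted, so views
    do not contribute in proportion to their duration.
    """
    by_id = _targets_by_id(targets)
    if not session.attempts:
        raise ValidationError(f"session {session.student_id}: no attempts")
    means = [view_mean_precision(
        precision_series(a, by_id[a.view_id], anatomy, use_logged))
        for a in session.attempts]
    return float(np.mean(means))


def success_percentage(session: SessionLog, targets, anatomy: AnatomyModel,
                       protocol_size: int = PROTOCOL_SIZE,
                       threshold: float = PASS_THRESHOLD,
                       hold: float = HOLD_SECONDS,
                       use_logged: bool = False) -> float:
    """Passed views divided by the protocol size, as a percentage."""
    by_id = _targets_by_id(targets)
    n_passed = 0
    for a in session.attempts:
        series = precision_series(a, by_id[a.view_id], anatomy, use_logged)
        if attempt_passed(series, a, threshold, hold):
            n_passed += 1
    return 100.0 * n_passed / protocol_size


def session_passed(session: SessionLog, targets, anatomy: AnatomyModel,
                   protocol_size: int = PROTOCOL_SIZE,
                   threshold: float = PASS_THRESHOLD,
                   hold: float = HOLD_SECONDS,
                   use_logged: bool = False) -> bool:
    """True when every one of the protocol's views is passed."""
    if len(session.attempts) < protocol_size:
        return False
    by_id = _targets_by_id(targets)
    for a in session.attempts:
        series = precision_series(a, by_id[a.view_id], anatomy, use_logged)
        if not attempt_passed(series, a, threshold, hold):
            return False
    return True


# ---------------------------------------------------------------------------
# protocol file
# ---------------------------------------------------------------------------

def _target_from_doc(doc: dict, anatomy: AnatomyModel) -> TargetView:
    state = ControlState(**{k: float(v)
                            for k, v in doc["target_state"].items()})
    if "ref_points" in doc:
        ref_points = np.asarray(doc["ref_points"], dtype=float)
    else:
        # synthesize landmarks in the ideal plane via the forward model
        plane = probe_plane(anatomy, state)
        offsets = np.asarray(doc["ref_offsets"], dtype=float)
        ref_points = (plane.origin[None, :]
                      + offsets[:, 0:1] * plane.in_plane_axes[0]
                      + offsets[:, 1:2] * plane.in_plane_axes[1])
    return TargetView(view_id=int(doc["view_id"]),
                      view_name=str(doc["view_name"]),
                      ref_points=ref_points,
                      tolerances=np.asarray(doc["tolerances"], dtype=float),
                      target_state=state)


def load_protocol(path: str | Path | None = None,
                  anatomy: AnatomyModel | None = None) -> list[TargetView]:
    """Load the examination protocol (default: the bundled 16-view file).

    Landmark points may be given explicitly (``ref_points``) or as in-plane
    offsets (``ref_offsets``) that are placed through the forward model at
    the view's target state, guaranteeing consistency with the kinematics.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "protocol.yaml"
    if anatomy is None:
        anatomy = load_anatomy()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return [_target_from_doc(v, anatomy) for v in doc["views"]]
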