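"""Rapidity-and-randomity (RAR) index of probe motion.

The RAR index of one coordinate signal over one view attempt is the
cumulative absolute rate of change,

    RAR = sum_n | ds_n / dt |,

with the derivative estimated by the central difference on actual
timestamps,

    ds/dt = (s_{n+1} - s_{n-1}) / (t_{n+1} - t_{n-1}).

The sum runs over the interior sample indices where the central difference
is defined; no one-sided endpoint differences are added (their contribution
is negligible at 10 Hz sampling).  The index is a surrogate for potentially
injurious probe motion, so it is computed for the four mechanical
coordinates only -- depth, rotation and both flexions; the omniplane angle
is electronic and excluded.  Angle signals are treated as unwrapped
continuous quantities: the log writer must not wrap rotation at +/-180 deg,
which would create spurious spikes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .session_log import SessionLog, ViewAttempt

logger = logging.getLogger(__name__)

#: coordinates entering the motion analysis (omniplane deliberately absent)
ANALYZED_COORDS = ("depth", "rotation", "ante_retro", "left_right")

#: coordinates shown in the study's figures (both bends are nevertheless
#: computed and reported)
FIGURE_COORDS = ("rotation", "ante_retro")


@dataclass(eq=False)
class RARResult:
    """Per-view RAR values of one coordinate and their session total."""

    coordinate: str
    per_view: dict[int, float]
    session_total: float


def central_difference(s, t) -> np.ndarray:
    """Central-difference derivative estimates at interior indices.

    Uses actual timestamps, so non-uniform sampling is handled without
    interpolation.  Returns an empty array for signals shorter than 3.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if s.shape != t.shape:
        raise ValidationError("signal and time arrays must align")
    if s.size < 3:
        return np.empty(0)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("timestamps must be strictly increasing")
    return (s[2:] - s[:-2]) / (t[2:] - t[:-2])


def rar(s, t) -> float:
    """RAR value of one signal: sum of absolute central differences.

    Non-negative; zero for constant signals.  Degenerate signals (< 3
    samples) yield 0 with a logged warning.
    """
    s = np.asarray(s, dtype=float)
    if s.size < 3:
        logger.warning("RAR of a %d-sample signal is degenerate; returning 0",
                       s.size)
        return 0.0
    return float(np.sum(np.abs(central_difference(s, t))))


def rar_per_coordinate(attempt: ViewAttempt) -> dict[str, float]:
    """RAR computed independently for each analyzed coordinate."""
    return {c: rar(attempt.coord(c), attempt.t) for c in ANALYZED_COORDS}


def attempt_rar_total(attempt: ViewAttempt) -> float:
    """Sum of RAR over the analyzed coordinates (rubric input)."""
    return float(sum(rar_per_coordinate(attempt).values()))


def session_rar(session: SessionLog, coordinate: str) -> RARResult:
    """Per-view RAR values of one coordinate and their cumulative sum.

    Views are never concatenated: each attempt's derivative estimates stay
    inside the attempt, so no spurious inter-view motion is counted.
    """
    if coordinate not in ANALYZED_COORDS:
        raise ValidationError(
            f"coordinate {coordinate!r} is not part of the RAR analysis")
    per_view = {a.view_id: rar(a.coord(coordinate), a.t)
                for a in session.attempts}
    return RARResult(coordinate=coordinate, per_view=per_view,
                     session_total=float(sum(per_view.values())))
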