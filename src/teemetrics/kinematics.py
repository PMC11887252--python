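"""Forward kinematics: probe control state -> imaging-plane pose.

The probe tip travels along a curved esophagus centerline; its five control
coordinates (depth, handle rotation, ante/retroflexion, left/right flexion,
omniplane angle) together determine the position and orientation of the
imaging plane in Cartesian space.  This module realizes that mapping with a
deliberately simple geometric model:

* the esophagus is a cubic spline through a few 3-D control points,
  re-parameterized by arc length, so that insertion depth equals arc length
  travelled along the curve;
* a reference frame (tangent, normal, binormal) is parallel-transported
  along the curve to avoid spurious frame flips;
* handle rotation spins the frame about the tangent; the two flexions tilt
  the tip axis (pure re-orientation, no translation); the omniplane angle
  finally spins the imaging plane about the transducer axis, leaving the
  tip position fixed.

The same forward model is used both to score students' planes against
expert targets and to construct those targets in the first place, so the
absolute fidelity of the mapping is less important than its smoothness and
internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .errors import DepthOutOfRangeError, ValidationError

_EPS = 1e-9


@dataclass(frozen=True)
class ControlState:
    """One probe control configuration (depth cm, angles deg)."""

    depth: float
    rotation: float
    ante_retro: float
    left_right: float
    omniplane: float

    def __post_init__(self) -> None:
        vals = (self.depth, self.rotation, self.ante_retro,
                self.left_right, self.omniplane)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("control state has non-finite coordinate")
        if not (-_EPS <= self.omniplane <= 180 + _EPS):
            raise ValidationError(
                f"omniplane {self.omniplane} outside [0, 180]")

    def as_array(self) -> np.ndarray:
        return np.array([self.depth, self.rotation, self.ante_retro,
                         self.left_right, self.omniplane], dtype=float)

    @classmethod
    def from_array(cls, a) -> "ControlState":
        a = np.asarray(a, dtype=float)
        return cls(*(float(x) for x in a))


@dataclass(eq=False)
class Plane:
    """Imaging plane: transducer-tip origin, unit normal, two in-plane axes.

    ``(in_plane_axes[0], in_plane_axes[1], normal)`` form a right-handed
    orthonormal triple.
    """

    origin: np.ndarray
    normal: np.ndarray
    in_plane_axes: np.ndarray  # shape (2, 3)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.in_plane_axes = np.asarray(self.in_plane_axes, dtype=float)

    def validate(self, tol: float = 1e-8) -> None:
        a1, a2 = self.in_plane_axes
        for v in (self.normal, a1, a2):
            if abs(np.linalg.norm(v) - 1) > tol:
                raise ValidationError("plane axis not unit length")
        if abs(np.dot(self.normal, a1)) > tol or \
           abs(np.dot(self.normal, a2)) > tol or abs(np.dot(a1, a2)) > tol:
            raise ValidationError("plane axes not orthogonal")
        if np.linalg.norm(np.cross(a1, a2) - self.normal) > 10 * tol:
            raise ValidationError("plane triple not right-handed")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass(eq=False)
class AnatomyModel:
    """Esophagus centerline plus depth limits.

    ``control_points`` (>= 4, cm) define a cubic-spline curve; insertion
    depth is measured as arc length from the first control point (the mouth
    end).  ``depth_range`` bounds navigable depths; pushing beyond
    ``max_depth_perforation`` models an esophageal perforation.
    """

    control_points: np.ndarray
    depth_range: tuple[float, float]
    max_depth_perforation: float

    _GRID = 4096  # dense arc-length grid resolution

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValidationError("control_points must be (n, 3)")
        if self.control_points.shape[0] < 4:
            raise ValidationError("anatomy needs at least 4 control points")
        self.depth_range = (float(self.depth_range[0]),
                            float(self.depth_range[1]))
        self.max_depth_perforation = float(self.max_depth_perforation)
        self._table = None
        lo, hi = self.depth_range
        if not lo < hi:
            raise ValidationError("depth_range must be increasing")
        if self.max_depth_perforation < hi:
            raise ValidationError(
                "max_depth_perforation must be >= depth_range max")
        total = self.arc_length_total
        if lo < -_EPS or hi > total + _EPS:
            raise ValidationError(
                f"depth_range {self.depth_range} outside curve span "
                f"[0, {total:.2f}]")

    # -- dense arc-length table -------------------------------------------

    def _build_table(self) -> dict:
        pts = self.control_points
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        spline = CubicSpline(chord, pts, axis=0)
        # integrate arc length on a fine grid, then re-parameterize
        uu = np.linspace(0.0, chord[-1], 8 * self._GRID)
        fine = spline(uu)
        seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
        s_fine = np.concatenate([[0.0], np.cumsum(seg)])
        total = float(s_fine[-1])
        s_grid = np.linspace(0.0, total, self._GRID)
        u_grid = np.interp(s_grid, s_fine, uu)
        pos = CubicSpline(s_grid, spline(u_grid), axis=0)
        tan = pos.derivative()(s_grid)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        normals = self._parallel_transport(tan)
        return {"total": total, "s_grid": s_grid, "pos": pos,
                "tangents": tan, "normals": normals}

    @staticmethod
    def _parallel_transport(tangents: np.ndarray) -> np.ndarray:
        t0 = tangents[0]
        seed = np.eye(3)[int(np.argmin(np.abs(t0)))]
        n = _unit(seed - np.dot(seed, t0) * t0)
        normals = np.empty_like(tangents)
        normals[0] = n
        for i in range(1, len(tangents)):
            ta, tb = tangents[i - 1], tangents[i]
            v = np.cross(ta, tb)
            s = np.linalg.norm(v)
            if s > 1e-14:
                axis = v / s
                ang = np.arctan2(s, np.dot(ta, tb))
                n = Rotation.from_rotvec(axis * ang).apply(n)
            n = _unit(n - np.dot(n, tb) * tb)
            normals[i] = n
        return normals

    @property
    def table(self) -> dict:
        if self._table is None:
            self._table = self._build_table()
        return self._table

    @property
    def arc_length_total(self) -> float:
        return self.table["total"]

    # -- frame queries -----------------------------------------------------

    def frames_at(self, depths: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray]:
        """Vectorized (point, tangent, normal) at given depths.

        Depths are clamped to the curve span for geometric evaluation;
        range policy is the caller's concern.
        """
        tab = self.table
        d = np.clip(np.asarray(depths, dtype=float), 0.0, tab["total"])
        p = tab["pos"](d)
        tan = tab["pos"].derivative()(d)
        tan /= np.linalg.norm(tan, axis=-1, keepdims=True)
        s_grid = tab["s_grid"]
        nrm = np.empty_like(tan)
        for k in range(3):
            nrm[..., k] = np.interp(d, s_grid, tab["normals"][:, k])
        nrm -= np.sum(nrm * tan, axis=-1, keepdims=True) * tan
        nrm /= np.linalg.norm(nrm, axis=-1, keepdims=True)
        return p, tan, nrm


def centerline_frame(anatomy: AnatomyModel, depth: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame of the esophagus centerline at an insertion depth.

    Returns ``(point, tangent, reference_normal)``; the reference normal is
    parallel-transported along the curve so it varies continuously with
    depth.  Raises :class:`DepthOutOfRangeError` outside ``depth_range``.
    """
    lo, hi = anatomy.depth_range
    if not (lo - _EPS <= depth <= hi + _EPS):
        raise DepthOutOfRangeError(
            f"depth {depth} cm outside navigable range [{lo}, {hi}]")
    p, tan, nrm = anatomy.frames_at(np.array([depth]))
    return p[0], tan[0], nrm[0]


def _apply_rot(axes_angles_deg: np.ndarray, axis: np.ndarray,
               *vecs: np.ndarray) -> tuple[np.ndarray, ...]:
    rot = Rotation.from_rotvec(np.deg2rad(axes_angles_deg)[:, None] * axis)
    return tuple(rot.apply(v) for v in vecs)


def probe_planes(anatomy: AnatomyModel, states: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized forward model for an (n, 5) array of control states.

    Columns follow the canonical coordinate order (depth, rotation,
    ante_retro, left_right, omniplane).  Returns ``(origins, normals,
    axes, in_range)`` where ``axes`` has shape (n, 2, 3) and ``in_range``
    flags depths inside ``depth_range`` (out-of-range states are evaluated
    with clamped geometry; the caller decides how to score them).
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    depth, rotation, ante_retro, left_right, omniplane = states.T
    lo, hi = anatomy.depth_range
    in_range = (depth >= lo - _EPS) & (depth <= hi + _EPS)
    origin, e3, e1 = anatomy.frames_at(depth)   # tangent e3, ref normal e1
    e2 = np.cross(e3, e1)                       # binormal
    # handle rotation about the esophageal tangent
    e1, e2 = _apply_rot(rotation, e3, e1, e2)
    # ante/retroflexion: tip tilt about the lateral axis
    e1, e3 = _apply_rot(ante_retro, e2, e1, e3)
    # left/right flexion: tip tilt about the antero-posterior axis
    e2, e3 = _apply_rot(left_right, e1, e2, e3)
    # omniplane: electronic spin of the imaging plane about the transducer
    # axis -- origin stays fixed
    e1, e2 = _apply_rot(omniplane, e3, e1, e2)
    axes = np.stack([e2, e3], axis=1)           # plane spanned by (e2, e3)
    return origin, e1, axes, in_range


def probe_plane(anatomy: AnatomyModel, state: ControlState) -> Plane:
    """Imaging plane reached by one control state.

    Composition order: centerline frame at depth -> handle rotation about
    the tangent -> ante/retro tilt -> left/right tilt -> omniplane spin.
    With an all-zero state the plane normal equals the centerline reference
    normal.  Raises :class:`DepthOutOfRangeError` when depth is outside the
    navigable range.
    """
    lo, hi = anatomy.depth_range
    if not (lo - _EPS <= state.depth <= hi + _EPS):
        raise DepthOutOfRangeError(
            f"depth {state.depth} cm outside navigable range [{lo}, {hi}]")
    origins, normals, axes, _ = probe_planes(anatomy,
                                             state.as_array()[None, :])
    return Plane(origin=origins[0], normal=normals[0], in_plane_axes=axes[0])


# ---------------------------------------------------------------------------
# default anatomy
# ---------------------------------------------------------------------------

def anatomy_from_dict(doc: dict) -> AnatomyModel:
    return AnatomyModel(control_points=np.asarray(doc["control_points"],
                                                  dtype=float),
                        depth_range=tuple(doc["depth_range"]),
                        max_depth_perforation=doc["max_depth_perforation"])


def load_anatomy(path: str | Path | None = None) -> AnatomyModel:
    """Load an anatomy model from YAML (default: the bundled gentle curve)."""
    if path is None:
        path = Path(__file__).parent / "data" / "anatomy.yaml"
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return anatomy_from_dict(doc)
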