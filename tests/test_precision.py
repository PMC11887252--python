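"""Plane-precision scoring, the 80% cutoff anchor and the pass rule."""

import numpy as np
import pytest

from teemetrics import (ControlState, TargetView, attempt_passed,
                        final_precision, point_plane_distance, precision,
                        precision_series, probe_plane, session_passed,
                        success_percentage, view_mean_precision)
from teemetrics import test_mean_precision as per_test_mean_precision
from teemetrics.errors import ValidationError

from teemetrics.precision_metric import PrecisionSeries

from conftest import make_attempt, make_session


def offset_target(plane, distances, tolerances, view_id=1):
    """TargetView whose landmarks sit at given perpendicular distances."""
    u = [(4.0, 1.0), (-3.0, 2.5), (2.0, -3.0)]
    pts = [plane.origin + a * plane.in_plane_axes[0]
           + b * plane.in_plane_axes[1] + d * plane.normal
           for (a, b), d in zip(u, distances)]
    return TargetView(view_id=view_id, view_name="synthetic", ref_points=pts,
                      tolerances=tolerances,
                      target_state=ControlState(30, 0, 0, 0, 0))


@pytest.fixture(scope="module")
def plane(anatomy):
    return probe_plane(anatomy, ControlState(30.0, 20.0, 5.0, 0.0, 45.0))


def test_point_plane_distance_basics(plane):
    assert point_plane_distance(plane.origin, plane) == 0.0
    assert point_plane_distance(plane.origin + plane.normal, plane) == \
        pytest.approx(1.0, abs=1e-12)


def test_point_plane_distance_matches_implicit_equation(plane):
    rng = np.random.default_rng(3)
    n = plane.normal
    d0 = -np.dot(n, plane.origin)
    for _ in range(100):
        p = plane.origin + rng.normal(scale=5.0, size=3)
        expected = abs(np.dot(n, p) + d0)   # |ax + by + cz + d| with unit n
        assert point_plane_distance(p, plane) == pytest.approx(expected,
                                                               abs=1e-12)


def test_precision_anchors(plane):
    """1.0 through all landmarks; exactly 0.8 at the tolerance limits."""
    L = [0.8, 0.5, 1.2]
    assert precision(plane, offset_target(plane, [0, 0, 0], L)) == \
        pytest.approx(1.0, abs=1e-12)
    assert precision(plane, offset_target(plane, L, L)) == \
        pytest.approx(0.8, abs=1e-12)
    assert precision(plane, offset_target(plane, [10 * l for l in L], L)) == 0.0


def test_precision_monotone_and_relabel_invariant(plane):
    L = [0.8, 0.8, 0.8]
    prev = 1.1
    for d in np.linspace(0, 3, 13):
        val = precision(plane, offset_target(plane, [d, 0.2, 0.4], L))
        assert val <= prev + 1e-12
        prev = val
    perm = [2, 0, 1]
    t1 = offset_target(plane, [0.1, 0.7, 1.3], [0.5, 0.8, 1.1])
    t2 = TargetView(view_id=1, view_name="perm",
                    ref_points=t1.ref_points[perm],
                    tolerances=t1.tolerances[perm],
                    target_state=t1.target_state)
    assert precision(plane, t1) == pytest.approx(precision(plane, t2),
                                                 abs=1e-12)


def test_series_at_target_state_is_one(anatomy, protocol):
    tv = protocol[10]
    s = tv.target_state
    attempt = make_attempt(view_id=tv.view_id, n=40, depth=s.depth,
                           rotation=s.rotation, ante_retro=s.ante_retro,
                           left_right=s.left_right, omniplane=s.omniplane)
    series = precision_series(attempt, tv, anatomy)
    assert series.values.shape == attempt.t.shape
    assert np.all(series.values > 1 - 1e-9)


def test_series_at_tolerance_offset_state_is_point_eight(anatomy, plane):
    target = offset_target(plane, [0.8, 0.8, 0.8], [0.8, 0.8, 0.8])
    attempt = make_attempt(view_id=1, n=10, depth=30.0, rotation=20.0,
                           ante_retro=5.0, left_right=0.0, omniplane=45.0)
    series = precision_series(attempt, target, anatomy)
    assert series.values == pytest.approx(np.full(10, 0.8), abs=1e-9)


def test_series_out_of_range_depth_scores_zero(anatomy, protocol):
    tv = protocol[0]
    depth = np.full(10, tv.target_state.depth)
    depth[3] = anatomy.depth_range[1] + 2.0
    attempt = make_attempt(view_id=tv.view_id, n=10, depth=depth,
                           ante_retro=tv.target_state.ante_retro,
                           omniplane=tv.target_state.omniplane)
    series = precision_series(attempt, tv, anatomy)
    assert series.values[3] == 0.0


def test_logged_channel_selected_by_flag(anatomy, protocol):
    tv = protocol[0]
    attempt = make_attempt(view_id=tv.view_id, n=5, precision=0.42)
    series = precision_series(attempt, tv, anatomy, use_logged=True)
    assert np.all(series.values == 0.42)
    with pytest.raises(ValidationError):
        precision_series(make_attempt(view_id=tv.view_id, n=5), tv, anatomy,
                         use_logged=True)


# -- pass rule ---------------------------------------------------------------

def series_of(values, dt=0.1):
    values = np.asarray(values, dtype=float)
    return PrecisionSeries(np.arange(len(values)) * dt, values)


def test_pass_requires_terminal_hold():
    a = make_attempt(view_id=1, n=51)
    assert attempt_passed(series_of(np.full(51, 0.85)), a)
    # high for 10 s, but the final 0.5 s dips below: "final precision" fails
    vals = np.concatenate([np.full(101, 0.85), np.full(5, 0.7)])
    assert not attempt_passed(series_of(vals), make_attempt(view_id=1, n=106))
    # a dip earlier than the final 3 s does not matter
    vals = np.concatenate([np.full(50, 0.5), np.full(40, 0.9)])
    assert attempt_passed(series_of(vals), make_attempt(view_id=1, n=90))


def test_perforation_always_fails():
    a = make_attempt(view_id=1, n=60, perforated=True)
    assert not attempt_passed(series_of(np.full(60, 0.95)), a)


def test_short_attempt_cannot_pass():
    a = make_attempt(view_id=1, n=20)
    assert not attempt_passed(series_of(np.full(20, 0.99)), a)


def test_zero_threshold_passes_any_long_attempt():
    a = make_attempt(view_id=1, n=40)
    assert attempt_passed(series_of(np.zeros(40)), a, threshold=0.0)


def test_final_precision_definitions():
    a = make_attempt(view_id=1, n=60)
    vals = np.concatenate([np.full(20, 0.3), np.full(40, 0.9)])
    assert final_precision(series_of(vals), a) == pytest.approx(0.9)
    vals = np.concatenate([np.full(59, 0.9), [0.4]])
    assert final_precision(series_of(vals), a) == pytest.approx(0.4)


# -- aggregation -------------------------------------------------------------

def test_view_mean_precision_examples():
    assert view_mean_precision(series_of([0.2, 0.4, 0.9])) == pytest.approx(0.5)
    assert view_mean_precision(series_of([1.0])) == 1.0
    with pytest.raises(ValidationError):
        view_mean_precision(series_of([]))


def test_test_mean_weights_views_equally(anatomy, targets_by_id):
    # short view at 0.4, long view at 0.6: per-view means first
    a1 = make_attempt(view_id=1, n=10, precision=0.4)
    a2 = make_attempt(view_id=2, n=1000, precision=0.6)
    session = make_session([a1, a2])
    got = per_test_mean_precision(session, targets_by_id, anatomy,
                              use_logged=True)
    assert got == pytest.approx(0.5)
    pooled = np.mean(np.concatenate([a1.precision, a2.precision]))
    assert abs(pooled - got) > 0.05


def test_success_percentage_and_session_pass(anatomy, targets_by_id):
    passing = [make_attempt(view_id=v, n=40, precision=0.9)
               for v in range(1, 16)]
    failing = [make_attempt(view_id=16, n=40, precision=0.5)]
    session = make_session(passing + failing)
    pct = success_percentage(session, targets_by_id, anatomy,
                             use_logged=True)
    assert pct == pytest.approx(93.75)
    assert not session_passed(session, targets_by_id, anatomy,
                              use_logged=True)
    all_pass = make_session([make_attempt(view_id=v, n=40, precision=0.9)
                             for v in range(1, 17)])
    assert success_percentage(all_pass, targets_by_id, anatomy,
                              use_logged=True) == 100.0
    assert session_passed(all_pass, targets_by_id, anatomy, use_logged=True)
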