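"""Session log I/O: round trips, dialect validation, sampling checks."""

import textwrap

import numpy as np
import pytest
from hypothesis import given, strategies as st

from teemetrics import read_session, resample_check, write_session
from teemetrics.errors import SessionFormatError, ValidationError
from teemetrics.session_log import Sample, SessionLog, ViewAttempt
from teemetrics.synthetic_data import expert_reference

from conftest import make_attempt, make_session


@pytest.mark.parametrize("suffix", [".csv", ".json"])
def test_round_trip_16_view_session(tmp_path, anatomy, protocol, suffix):
    """A full 16-view synthetic session survives write/read unchanged."""
    session = expert_reference(protocol, anatomy, seed=5)
    session.metadata["note"] = "reference run"
    path = write_session(session, tmp_path / f"expert{suffix}")
    assert read_session(path) == session


def test_hand_written_fixture_parses(tmp_path):
    """A 3-row file yields one attempt of 3 samples spanning 0.2 s."""
    text = textwrap.dedent("""\
        # comment line
        student_id,test_id,view_id,view_name,t,depth,rotation,ante_retro,left_right,omniplane,precision,event
        s01,1,1,ME 5-chamber,0.0,30.0,0.0,0.0,0.0,0.0,,
        s01,1,1,ME 5-chamber,0.1,30.1,1.0,0.0,0.0,0.0,,
        s01,1,1,ME 5-chamber,0.2,30.2,2.0,0.0,0.0,0.0,,
        """)
    path = tmp_path / "s.csv"
    path.write_text(text)
    session = read_session(path)
    assert len(session.attempts) == 1
    a = session.attempts[0]
    assert a.n_samples == 3
    assert a.duration == pytest.approx(0.2)
    assert a.precision is None and not a.perforated


def test_perforation_event_round_trip(tmp_path):
    s = make_session([make_attempt(view_id=1),
                      make_attempt(view_id=2, perforated=True)])
    path = write_session(s, tmp_path / "s.csv")
    text = path.read_text()
    assert "perforation" in text
    back = read_session(path)
    assert [a.perforated for a in back.attempts] == [False, True]


def test_empty_session_writes_header_only(tmp_path):
    s = SessionLog("s01", 1, [])
    path = write_session(s, tmp_path / "empty.csv")
    lines = [l for l in path.read_text().splitlines()
             if not l.startswith("#")]
    assert len(lines) == 1 and lines[0].startswith("student_id,")
    assert read_session(path) == s


def test_duplicate_view_id_rejected(tmp_path):
    s = make_session([make_attempt(view_id=4), make_attempt(view_id=4)])
    with pytest.raises(ValidationError, match="duplicate view_id"):
        s.validate()
    # the same duplication written as two CSV blocks is caught on read
    good = make_session([make_attempt(view_id=4)])
    path = write_session(good, tmp_path / "dup.csv")
    rows = path.read_text().splitlines()
    path.write_text("\n".join(rows + rows[2:]) + "\n")
    with pytest.raises(ValidationError, match="duplicate view_id"):
        read_session(path)


def test_missing_column_named(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("student_id,test_id,view_id,view_name,t\n")
    with pytest.raises(SessionFormatError, match="depth"):
        read_session(path)


def test_non_monotone_time_rejected():
    a = make_attempt(view_id=1)
    a.t = a.t.copy()
    a.t[10] = a.t[9]
    with pytest.raises(ValidationError, match="non-monotone time"):
        a.validate()


def test_omniplane_range_enforced():
    a = make_attempt(view_id=1, omniplane=200.0)
    with pytest.raises(ValidationError, match="omniplane"):
        a.validate()


def test_resample_check_uniform_and_gap():
    a = make_attempt(view_id=1, n=40)
    assert resample_check(a) == []
    t = a.t.copy()
    t[20:] += 0.3            # one 0.4 s gap at interval index 19
    a.t = t
    reports = resample_check(a)
    assert len(reports) == 1
    assert reports[0].index == 19
    assert reports[0].dt == pytest.approx(0.4)


def test_resample_check_two_sample_attempt():
    a = make_attempt(view_id=1, n=2)
    assert len(resample_check(a)) <= 1


# -- property: read(write(x)) == x ------------------------------------------

finite = st.floats(min_value=-500, max_value=500, allow_nan=False,
                   width=64)


@st.composite
def attempt_strategy(draw, view_id):
    n = draw(st.integers(min_value=2, max_value=6))
    cols = {c: draw(st.lists(finite, min_size=n, max_size=n))
            for c in ("depth", "rotation", "ante_retro", "left_right")}
    cols["omniplane"] = draw(st.lists(
        st.floats(min_value=0, max_value=180, allow_nan=False),
        min_size=n, max_size=n))
    dts = draw(st.lists(st.floats(min_value=0.05, max_value=0.5,
                                  allow_nan=False), min_size=n, max_size=n))
    t = np.cumsum(dts)
    prec = None
    if draw(st.booleans()):
        prec = draw(st.lists(st.floats(min_value=0, max_value=1,
                                       allow_nan=False),
                             min_size=n, max_size=n))
    return ViewAttempt(view_id=view_id, view_name=f"view {view_id}", t=t,
                       precision=prec, perforated=draw(st.booleans()),
                       **cols)


@st.composite
def session_strategy(draw):
    vids = draw(st.lists(st.integers(min_value=1, max_value=16),
                         unique=True, min_size=1, max_size=3))
    attempts = [draw(attempt_strategy(v)) for v in sorted(vids)]
    return SessionLog(draw(st.sampled_from(["s01", "alpha", "x y"])),
                      draw(st.sampled_from([1, 2])), attempts,
                      metadata=draw(st.dictionaries(
                          st.sampled_from(["date", "sim"]),
                          st.text(max_size=8), max_size=2)))


@given(session=session_strategy(), suffix=st.sampled_from([".csv", ".json"]))
def test_round_trip_random_sessions(session, suffix, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("rt")
    path = write_session(session, tmp / f"s{suffix}")
    assert read_session(path) == session


def test_samples_view_and_from_samples_round_trip():
    a = make_attempt(view_id=2, n=4, precision=0.5)
    rebuilt = ViewAttempt.from_samples(2, a.view_name, a.samples)
    assert rebuilt == a
    assert isinstance(a.samples[0], Sample)
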