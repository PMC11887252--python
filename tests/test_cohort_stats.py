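"""Descriptive statistics, paired comparisons and their exact oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from teemetrics import (compare_paired, compare_pass_counts, describe,
                        four_view_subanalysis)
from teemetrics.cohort_stats import FOUR_VIEW_IDS, MetricTable, signed_rank_test
from teemetrics.errors import ValidationError

from conftest import make_attempt, make_session


def test_describe_basics():
    d = describe([1, 2, 3])
    assert d["mean"] == 2 and d["median"] == 2 and d["n"] == 3
    assert d["sd"] == pytest.approx(1.0)


def test_describe_type7_quartiles():
    d = describe([1, 2, 3, 4])
    assert d["median"] == pytest.approx(2.5)
    assert d["q1"] == pytest.approx(1.75)    # linear-interpolation rule
    assert d["q3"] == pytest.approx(3.25)


def test_describe_degenerate():
    d = describe([5.0] * 10)
    assert d["sd"] == 0.0 and d["normal"] is None
    assert describe([1.0, 2.0])["normal"] is None
    with pytest.raises(ValidationError):
        describe([])


def test_compare_identical_is_degenerate():
    x = [1.0, 2.0, 3.0, 4.0]
    res = compare_paired(x, x)
    assert res["p_value"] == 1.0 and res["method"] == "degenerate"


def test_compare_detects_large_shift():
    rng = np.random.default_rng(0)
    x1 = rng.normal(size=12)
    x2 = x1 + 50 + rng.normal(scale=0.1, size=12)
    res = compare_paired(x1, x2)
    assert res["p_value"] < 1e-3
    # invariant to a common shift of both vectors
    res2 = compare_paired(x1 + 7, x2 + 7)
    assert res2["method"] == res["method"]
    assert res2["p_value"] == pytest.approx(res["p_value"], rel=1e-9)


def test_unpaired_methods_available():
    rng = np.random.default_rng(1)
    x1 = rng.normal(size=15)
    res = compare_paired(x1, x1 + 1.0, paired=False)
    assert res["method"] in ("student t-test", "mann-whitney u")


def exact_signed_rank_p(diffs):
    """Full 2^n sign-flip enumeration of the signed-rank null."""
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    ranks = rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    ws = [float(np.sum(ranks[np.array(signs, dtype=bool)]))
          for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.array(ws)
    cdf = np.mean(ws <= w_obs)
    sf = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(cdf, sf))


@pytest.mark.parametrize("diffs", [
    [1.5, -0.7, 2.2, 0.9, -1.1, 3.0],
    [0.3, 0.8, 1.9, 2.5, -0.1, 0.6, 1.2],
    [-2.0, -1.5, -0.9, 0.4, 1.1, 2.8, 3.5, 0.2],
    [0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
])
def test_signed_rank_matches_exact_enumeration(diffs):
    x1 = np.zeros(len(diffs))
    res = signed_rank_test(x1, np.array(diffs))
    assert res["p_value"] == pytest.approx(exact_signed_rank_p(diffs),
                                           abs=1e-12)


def test_mcnemar_exact_binomial():
    # 5 discordant pairs all one way: p = 2 * (1/2)^5 = 0.0625
    p1 = [True] * 5 + [True] * 3 + [False] * 2
    p2 = [False] * 5 + [True] * 3 + [False] * 2
    res = compare_pass_counts(p1, p2)
    assert res["p_value"] == pytest.approx(0.0625, abs=1e-12)
    assert res["table"]["test1_only"] == 5
    assert res["table"]["test2_only"] == 0
    assert sum(res["table"].values()) == 10
    # no discordant pairs -> p = 1
    res = compare_pass_counts([True, False], [True, False])
    assert res["p_value"] == 1.0


def test_metric_table_summary_shape():
    t = MetricTable("time", [10, 12, 14, 16], [8, 9, 10, 11], expert=5.0)
    s = t.summary()
    assert set(s) == {"metric", "test1", "test2", "comparison", "expert"}
    with pytest.raises(ValidationError):
        MetricTable("bad", [1, 2], [1, 2, 3])


# -- four-view subanalysis ---------------------------------------------------

def cohort_with_improvement(n_students, improved_views, t1=100.0, t2=40.0):
    pairs = []
    for i in range(n_students):
        def attempts(test):
            out = []
            for v in range(1, 17):
                sec = t2 if (test == 2 and v in improved_views) else t1
                n = int(round(sec / 0.1)) + 1
                out.append(make_attempt(view_id=v, n=n, precision=0.9))
            return out
        pairs.append((make_session(attempts(1), f"s{i}", 1),
                      make_session(attempts(2), f"s{i}", 2)))
    return pairs


def test_four_view_blocks_and_focused_improvement(anatomy, targets_by_id):
    pairs = cohort_with_improvement(4, set(FOUR_VIEW_IDS))
    out = four_view_subanalysis(pairs, targets_by_id, anatomy,
                                use_logged=True)
    assert sorted(out) == sorted(FOUR_VIEW_IDS)
    for vid in FOUR_VIEW_IDS:
        block = out[vid]
        assert block["time"]["test1"]["median"] == pytest.approx(100.0)
        assert block["time"]["test2"]["median"] == pytest.approx(40.0)
    # the full-protocol total dilutes the same change by the 12 flat views
    sub_ratio = out[FOUR_VIEW_IDS[0]]["time"]["test2"]["mean"] / 100.0
    totals1 = [sum(a.duration for a in s1.attempts) for s1, _ in pairs]
    totals2 = [sum(a.duration for a in s2.attempts) for _, s2 in pairs]
    full_ratio = np.mean(totals2) / np.mean(totals1)
    assert sub_ratio < 0.5 < full_ratio


def test_four_view_single_student_skips_comparison(anatomy, targets_by_id):
    pairs = cohort_with_improvement(1, set(FOUR_VIEW_IDS))
    out = four_view_subanalysis(pairs, targets_by_id, anatomy,
                                use_logged=True)
    assert out[3]["time"]["comparison"]["method"] == "insufficient n"


def test_four_view_missing_view_excluded(anatomy, targets_by_id):
    pairs = cohort_with_improvement(2, set(FOUR_VIEW_IDS))
    # student 0 never attempted view 3 in test 2
    pairs[0][1].attempts = [a for a in pairs[0][1].attempts
                            if a.view_id != 3]
    out = four_view_subanalysis(pairs, targets_by_id, anatomy,
                                use_logged=True)
    assert out[3]["time"]["test1"]["n"] == 1
    assert out[11]["time"]["test1"]["n"] == 2
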