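"""Greedy allometric matching, percentile filtering, and tree-list completion."""

import numpy as np
import pytest

from forestinv.allometry import PowerModel, predict_dbh
from forestinv.matching import (
    complete_tree_list,
    filter_matches,
    match_dbh_to_heights,
    pairs_to_frame,
)
from forestinv.stems import StemRecord
from forestinv.treetops import TreeTop

from _oracles import sequential_greedy_match

REGIONAL = PowerModel(2.5, 0.9, residual_lo=-4.0, residual_hi=4.0)


def _stem(sid, x, y, dbh):
    return StemRecord(sid, x, y, dbh, n_inliers=20, rmse=0.5)


def _height_for_dbh(dbh):
    return (dbh / REGIONAL.a) ** (1.0 / REGIONAL.b)


def test_smallest_difference_wins_over_distance():
    """The pair with the smallest DBH difference matches, not the nearest."""
    h24 = _height_for_dbh(24.0)
    h30 = _height_for_dbh(30.0)
    tops = [TreeTop(1, 3.0, 0.0, h24), TreeTop(2, 2.0, 0.0, h30)]
    stems = [_stem(1, 0.0, 0.0, 25.0)]
    pairs = match_dbh_to_heights(tops, stems, REGIONAL)
    assert len(pairs) == 1
    assert pairs[0].tree_id == 1  # cost 1 beats cost 5 despite larger distance
    assert pairs[0].cost == pytest.approx(1.0, abs=1e-9)


def test_radius_cut():
    tops = [TreeTop(1, 4.5, 0.0, 10.0)]
    stems = [_stem(1, 0.0, 0.0, 20.0)]
    assert match_dbh_to_heights(tops, stems, REGIONAL) == []


def test_one_to_one_and_completeness(rng):
    tops = [TreeTop(i + 1, rng.uniform(0, 20), rng.uniform(0, 20), rng.uniform(5, 20))
            for i in range(12)]
    stems = [_stem(i + 1, rng.uniform(0, 20), rng.uniform(0, 20), rng.uniform(8, 40))
             for i in range(9)]
    pairs = match_dbh_to_heights(tops, stems, REGIONAL)
    assert len({p.tree_id for p in pairs}) == len(pairs)
    assert len({p.stem_id for p in pairs}) == len(pairs)
    assert all(p.distance <= 4.0 and p.cost >= 0 for p in pairs)


def test_matches_equal_brute_force_oracle(rng):
    for _ in range(25):
        n_s = rng.integers(1, 9)
        n_t = rng.integers(1, 9)
        tops = [TreeTop(i + 1, rng.uniform(0, 10), rng.uniform(0, 10),
                        rng.uniform(3, 20)) for i in range(n_t)]
        stems = [_stem(i + 1, rng.uniform(0, 10), rng.uniform(0, 10),
                       rng.uniform(5, 45)) for i in range(n_s)]
        got = {(p.stem_id, p.tree_id)
               for p in match_dbh_to_heights(tops, stems, REGIONAL)}
        want = sequential_greedy_match(tops, stems, REGIONAL)
        assert got == want


def test_matching_order_invariance(rng):
    tops = [TreeTop(i + 1, rng.uniform(0, 15), rng.uniform(0, 15), rng.uniform(4, 18))
            for i in range(10)]
    stems = [_stem(i + 1, rng.uniform(0, 15), rng.uniform(0, 15), rng.uniform(6, 40))
             for i in range(8)]
    a = {(p.stem_id, p.tree_id) for p in match_dbh_to_heights(tops, stems, REGIONAL)}
    perm_t = [tops[i] for i in rng.permutation(len(tops))]
    perm_s = [stems[i] for i in rng.permutation(len(stems))]
    b = {(p.stem_id, p.tree_id) for p in match_dbh_to_heights(perm_t, perm_s, REGIONAL)}
    assert a == b


def test_filter_matches_examples():
    h = 10.0
    on_curve = predict_dbh(REGIONAL, h)
    tops = [TreeTop(1, 0.0, 0.0, h), TreeTop(2, 10.0, 0.0, h)]
    stems = [_stem(1, 0.1, 0.0, on_curve), _stem(2, 10.1, 0.0, on_curve + 8.0)]
    pairs = match_dbh_to_heights(tops, stems, REGIONAL)
    passed = filter_matches(pairs, REGIONAL)
    assert [p.stem_id for p in passed] == [1]
    assert pairs[0].passed_filter != pairs[1].passed_filter


def test_gross_errors_removed(rng):
    """+/-20 cm corruptions on 10% of stems are nearly all filtered out."""
    n = 200
    h = rng.uniform(5, 20, n)
    dbh = predict_dbh(REGIONAL, h) + rng.uniform(-3.0, 3.0, n)
    gross = rng.choice(n, n // 10, replace=False)
    dbh[gross] += rng.choice([-20.0, 20.0], size=len(gross))
    xs = np.arange(n) * 10.0
    tops = [TreeTop(i + 1, xs[i], 0.0, h[i]) for i in range(n)]
    stems = [_stem(i + 1, xs[i] + 0.2, 0.0, dbh[i]) for i in range(n)]
    pairs = match_dbh_to_heights(tops, stems, REGIONAL)
    passed_ids = {p.stem_id for p in filter_matches(pairs, REGIONAL)}
    removed = sum(1 for g in gross if (g + 1) not in passed_ids)
    assert removed / len(gross) >= 0.90


def test_complete_all_matched():
    h = [8.0, 12.0, 16.0, 20.0]
    tops = [TreeTop(i + 1, i * 10.0, 0.0, h[i]) for i in range(4)]
    stems = [_stem(i + 1, i * 10.0 + 0.1, 0.0, predict_dbh(REGIONAL, h[i]))
             for i in range(4)]
    pairs = filter_matches(match_dbh_to_heights(tops, stems, REGIONAL), REGIONAL)
    tl, model = complete_tree_list(tops, pairs)
    assert len(tl) == 4
    assert (tl.frame["dbh_source"] == "extracted").all()
    np.testing.assert_allclose(tl.frame["dbh_cm"], predict_dbh(REGIONAL, np.array(h)))


def test_complete_zero_stems_regional_fallback():
    tops = [TreeTop(1, 0.0, 0.0, 10.0), TreeTop(2, 5.0, 0.0, 15.0)]
    tl, model = complete_tree_list(tops, [], regional=REGIONAL)
    assert model is REGIONAL
    assert (tl.frame["dbh_source"] == "modeled").all()
    assert tl.frame["dbh_cm"].iloc[0] == pytest.approx(predict_dbh(REGIONAL, 10.0))


def test_complete_requires_fallback_when_sparse():
    tops = [TreeTop(1, 0.0, 0.0, 10.0)]
    with pytest.raises(ValueError):
        complete_tree_list(tops, [], regional=None)


def test_pairs_frame_columns():
    tops = [TreeTop(1, 0.0, 0.0, 10.0)]
    stems = [_stem(1, 0.1, 0.0, 20.0)]
    pairs = match_dbh_to_heights(tops, stems, REGIONAL)
    df = pairs_to_frame(pairs)
    assert list(df.columns) == ["tree_id", "stem_id", "height_m", "dbh_extracted_cm",
                                "dbh_regional_cm", "distance_m", "cost_cm", "passed_filter"]
    assert len(df) == 1
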