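"""Stem mapping, stem-point classification, and RANSAC DBH fitting."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from forestinv.errors import ParameterError
from forestinv.io_formats import PointClass, PointCloud
from forestinv.stems import (
    StemParams,
    assign_tree_points,
    classify_stem_points,
    fit_dbh,
    hough_circles,
    map_stems_hough,
    slice_cloud,
)


def _norm(x, y, z, tree_id=None):
    c = PointCloud(np.asarray(x, float), np.asarray(y, float), np.asarray(z, float),
                   tree_id=tree_id)
    c.normalized = True
    return c


def _circle_points(rng, n, cx, cy, r, z=1.37, arc=(0.0, 2 * np.pi)):
    ang = rng.uniform(arc[0], arc[1], n)
    return cx + r * np.cos(ang), cy + r * np.sin(ang), np.full(n, z)


# --------------------------------------------------------------- slice_cloud


def test_slice_basic():
    c = _norm([0, 0, 0], [0, 0, 0], [0.05, 1.37, 5.0])
    out = slice_cloud(c, 0.1, 4.0)
    assert len(out) == 1 and out.z[0] == 1.37


def test_slice_empty_ok():
    out = slice_cloud(_norm([0], [0], [9.0]), 0.1, 4.0)
    assert len(out) == 0


def test_slice_uniform_fraction(rng):
    n = 10000
    c = _norm(rng.uniform(0, 5, n), rng.uniform(0, 5, n), rng.uniform(0, 10, n))
    frac = len(slice_cloud(c, 0.1, 4.0)) / n
    expected = (4.0 - 0.1) / 10.0
    assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / n)


def test_slice_param_error():
    with pytest.raises(ParameterError):
        slice_cloud(_norm([0], [0], [1.0]), 4.0, 0.1)


# ---------------------------------------------------------- Hough stem mapping


def test_hough_single_circle(rng):
    x, y, z = _circle_points(rng, 200, 5.0, 5.0, 0.15)
    cands = map_stems_hough(_norm(x, y, z))
    assert len(cands) == 1
    cx, cy, r = cands[0]
    assert abs(cx - 5.0) <= 0.025 and abs(cy - 5.0) <= 0.025
    assert abs(r - 0.15) <= 0.025


def test_hough_two_circles(rng):
    x1, y1, z1 = _circle_points(rng, 200, 5.0, 5.0, 0.15)
    x2, y2, z2 = _circle_points(rng, 200, 8.0, 5.0, 0.12)
    cands = map_stems_hough(
        _norm(np.concatenate([x1, x2]), np.concatenate([y1, y2]), np.concatenate([z1, z2]))
    )
    assert len(cands) == 2
    xs = sorted(c[0] for c in cands)
    assert abs(xs[0] - 5.0) <= 0.05 and abs(xs[1] - 8.0) <= 0.05


def test_hough_sparse_noise_below_threshold(rng):
    x = rng.uniform(0, 5, 60)
    y = rng.uniform(0, 5, 60)
    peaks = hough_circles(x, y, max_diameter=1.0, min_density=0.5, merge_distance=1.0)
    assert peaks == []


def test_hough_candidates_monotone_in_density(rng):
    counts = []
    for n in (400, 60, 12):
        x, y, z = _circle_points(rng, n, 5.0, 5.0, 0.15)
        peaks = hough_circles(x, y, max_diameter=1.0, min_density=0.5, merge_distance=1.0)
        counts.append(len(peaks))
    assert counts[0] >= counts[1] >= counts[2]


def test_hough_empty_slice():
    assert map_stems_hough(_norm([], [], [])) == []


# ---------------------------------------------------------- tree-ID attribution


def test_assign_tree_points_rules():
    centers = [(0.0, 0.0), (3.0, 0.0)]
    #           0.3 m from A      0.6 m from both    0.4 from A/0.45 from B-ish
    slab = _norm([0.3, 1.5, 0.4], [0.0, 2.0, 0.0], [1.0, 1.0, 1.0])
    out = assign_tree_points(slab, centers)
    assert out.tree_id[0] == 1
    assert out.tree_id[1] == 0  # outside 0.5 m of every center
    assert out.tree_id[2] == 1  # nearest-center rule


def test_assign_nearest_on_overlap():
    centers = [(0.0, 0.0), (0.85, 0.0)]
    slab = _norm([0.4], [0.0], [1.0])  # 0.4 from A, 0.45 from B
    out = assign_tree_points(slab, centers)
    assert out.tree_id[0] == 1


def test_assign_no_centers_unchanged():
    slab = _norm([0.1], [0.1], [1.0])
    out = assign_tree_points(slab, [])
    assert out.tree_id[0] == 0


# ------------------------------------------------------ stem-point classification


def _cylinder_cloud(rng, n, cx=5.0, cy=5.0, r=0.08, zlo=0.1, zhi=4.0, tree_id=1):
    ang = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(zlo, zhi, n)
    return (cx + r * np.cos(ang), cy + r * np.sin(ang), z,
            np.full(n, tree_id, np.int32))


def test_noiseless_cylinder_mostly_stem(rng):
    x, y, z, tid = _cylinder_cloud(rng, 3000)
    out = classify_stem_points(_norm(x, y, z, tid))
    assert (out.point_class == PointClass.STEM).mean() >= 0.99


def test_crown_noise_removed(rng):
    x, y, z, tid = _cylinder_cloud(rng, 2400)
    n_noise = 600  # 20% of the labeled points
    na = rng.uniform(0, 2 * np.pi, n_noise)
    nr = 0.5 * np.sqrt(rng.uniform(size=n_noise))
    nx = 5.0 + nr * np.cos(na)
    ny = 5.0 + nr * np.sin(na)
    nz = rng.uniform(0.1, 4.0, n_noise)
    cloud = _norm(np.concatenate([x, nx]), np.concatenate([y, ny]),
                  np.concatenate([z, nz]),
                  np.concatenate([tid, np.ones(n_noise, np.int32)]))
    out = classify_stem_points(cloud)
    noise_kept = (out.point_class[2400:] == PointClass.STEM).mean()
    assert noise_kept <= 0.05  # >= 95% of injected noise removed
    assert (out.point_class[:2400] == PointClass.STEM).mean() >= 0.95


def test_two_point_tree_dropped():
    cloud = _norm([5.0, 5.1], [5.0, 5.0], [1.37, 1.40], np.array([1, 1], np.int32))
    out = classify_stem_points(cloud)
    assert (out.point_class != PointClass.STEM).all()
    assert fit_dbh(out) == []


# ----------------------------------------------------------------- DBH fitting


def _stem_band(rng, n=300, cx=5.0, cy=5.0, r=0.15, arc=(0.0, 2 * np.pi)):
    x, y, z = _circle_points(rng, n, cx, cy, r, arc=arc)
    z = rng.uniform(1.32, 1.42, n)
    cloud = _norm(x, y, z, np.ones(n, np.int32))
    cloud.point_class[:] = int(PointClass.STEM)
    return cloud


def test_exact_circle_dbh(rng):
    recs = fit_dbh(_stem_band(rng), seed=0)
    assert len(recs) == 1
    assert recs[0].dbh == pytest.approx(30.0, abs=1.0)  # rasterization bound
    assert abs(recs[0].x - 5.0) <= 0.01 and abs(recs[0].y - 5.0) <= 0.01
    assert recs[0].n_inliers >= 3


def test_arc_120_degrees(rng):
    recs = fit_dbh(_stem_band(rng, arc=(0.0, 2 * np.pi / 3)), seed=0)
    assert len(recs) == 1
    assert recs[0].dbh == pytest.approx(30.0, abs=2.0)


def test_ransac_with_outliers(rng):
    cloud = _stem_band(rng, n=280)
    n_out = 120  # ~30% of occupied cells end up as outliers
    ox = rng.uniform(4.5, 5.5, n_out)
    oy = rng.uniform(4.5, 5.5, n_out)
    oz = rng.uniform(1.32, 1.42, n_out)
    noisy = _norm(np.concatenate([cloud.x, ox]), np.concatenate([cloud.y, oy]),
                  np.concatenate([cloud.z, oz]),
                  np.concatenate([cloud.tree_id, np.ones(n_out, np.int32)]))
    noisy.point_class[:] = int(PointClass.STEM)
    recs = fit_dbh(noisy, seed=0)
    assert len(recs) == 1
    assert recs[0].dbh == pytest.approx(30.0, abs=1.0)


def test_fit_dbh_translation_invariance(rng):
    cloud = _stem_band(rng)
    moved = cloud.copy()
    moved.x = cloud.x + 123.375
    moved.y = cloud.y - 45.113
    a = fit_dbh(cloud, seed=5)[0]
    b = fit_dbh(moved, seed=5)[0]
    # identical occupied-cell sets; only least-squares round-off differs
    assert b.dbh == pytest.approx(a.dbh, abs=1e-5)
    assert b.x - a.x == pytest.approx(123.375, abs=1e-5)
    assert b.rmse == pytest.approx(a.rmse, abs=1e-5)


def test_too_few_cells_omitted(rng):
    cloud = _norm([5.0, 5.003], [5.0, 5.0], [1.37, 1.37], np.array([1, 1], np.int32))
    cloud.point_class[:] = int(PointClass.STEM)
    assert fit_dbh(cloud) == []  # both points share one or two 1 cm cells


def test_stand_stem_recovery(small_stand, small_normalized):
    """End-to-end stem extraction on the labeled stand: >= 80% of stems
    recovered within 2 cm, no stems reported away from true trees."""
    truth, _ = small_stand
    params = StemParams()
    slab = slice_cloud(small_normalized, params.slice_zmin, params.slice_zmax)
    centers = map_stems_hough(slab, params)
    labeled = assign_tree_points(slab, centers)
    recs = fit_dbh(classify_stem_points(labeled, params), params, seed=3)
    tt = truth.trees
    tree = cKDTree(tt[["x", "y"]].to_numpy())
    d, i = tree.query(np.array([[r.x, r.y] for r in recs]))
    assert (d >= 0.5).mean() <= 0.05  # false positives
    good = 0
    for rec, dd, ii in zip(recs, d, i):
        if dd < 0.5 and abs(rec.dbh - tt["dbh_cm"].iloc[ii]) <= 2.0:
            good += 1
    assert good / len(tt) >= 0.8


def test_param_invariants():
    with pytest.raises(ParameterError):
        StemParams(map_zlo=0.05)  # violates slice_zmin < map_zlo
    with pytest.raises(ParameterError):
        StemParams(dbh_thickness=0.0)
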