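"""Isocontour detection, features, pairing, saliency labeling and classification."""

import numpy as np
import pytest

from mitoseg import generate_toy_polygons
from mitoseg.contours import (
    Contour,
    balance_training_pairs,
    classify_salient,
    contour_features,
    cross_validated_scores,
    detect_isocontours,
    enumerate_pairs,
    filter_by_perimeter,
    label_salient_ground_truth,
    rasterize_interior,
    train_contour_model,
)

SP = (10.0, 10.0)  # (y, x) nm


def _disc_slice(radius_px: float, shape=(100, 100), center=None, value=1.0):
    """Disc with a 1 px linear ramp at the rim (the 50% level is the circle)."""
    cy, cx = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    r = np.hypot(yy - cy, xx - cx)
    return value * np.clip(radius_px - r + 0.5, 0.0, 1.0)


def test_empty_slice_has_no_contours():
    assert detect_isocontours(np.zeros((50, 50)), [0.5], SP) == []


def test_disc_contour_perimeter_matches_circle():
    img = _disc_slice(25.0)  # radius 0.25 um at 10 nm pixels
    cs = detect_isocontours(img, [0.5], SP)
    assert len(cs) == 1
    assert cs[0].perimeter_um == pytest.approx(2 * np.pi * 0.25, rel=0.02)


def test_levels_reference_value_scales_thresholds():
    img = _disc_slice(20.0, value=0.4)
    # with ref 1.0 a 0.5 level exceeds the slice max -> nothing
    assert detect_isocontours(img, [0.5], SP, ref_value=1.0) == []
    # referencing the slice max finds the disc boundary
    assert len(detect_isocontours(img, [0.5], SP)) == 1


def test_border_touching_contour_closed_along_border():
    img = np.zeros((60, 60))
    img[:30, :] = 1.0  # half-plane: level curve would run off both sides
    cs = detect_isocontours(img, [0.5], SP)
    assert len(cs) == 1
    v = cs[0].vertices_um
    np.testing.assert_allclose(v[0], v[-1])
    # interior area ~ half the slice
    mask = rasterize_interior(cs[0], img.shape, SP)
    assert mask.sum() == pytest.approx(30 * 60, rel=0.05)


def test_invalid_levels_rejected():
    with pytest.raises(ValueError):
        detect_isocontours(np.ones((10, 10)), [0.5, 0.3], SP)


def test_perimeter_filter_boundary_inclusive():
    cs = [generate_toy_polygons("circle", p / (2 * np.pi)) for p in (0.3, 0.7, 5.0, 7.0)]
    kept = filter_by_perimeter(cs, 0.6, 6.0)
    assert len(kept) == 2
    assert filter_by_perimeter([], 0.6, 6.0) == []
    assert filter_by_perimeter(kept, 0.6, 6.0) == kept
    # gates are inclusive: a contour sitting exactly on the bound survives
    exact = generate_toy_polygons("square", 0.25)
    p = exact.perimeter_um
    assert filter_by_perimeter([exact], p, 6.0) == [exact]
    assert filter_by_perimeter([exact], 0.6, p) == [exact]
    with pytest.raises(ValueError):
        filter_by_perimeter(cs, 6.0, 0.6)


def test_square_features_closed_form():
    sq = generate_toy_polygons("square", 1.0)
    raw = np.full((220, 220), 37.0)
    prob = np.full((220, 220), 0.25)
    f = contour_features(sq, raw, prob, SP)
    assert f.perimeter_um == pytest.approx(4.0, rel=1e-6)
    assert f.area_um2 == pytest.approx(1.0, rel=1e-6)
    assert f.mean_gray_on_contour == pytest.approx(37.0)
    assert f.mean_prob_inside == pytest.approx(0.25)


def test_exact_ellipse_self_fit_overlap():
    e = generate_toy_polygons("ellipse", 0.4)
    raw = np.zeros((220, 220))
    f = contour_features(e, raw, raw, SP)
    assert f.ellipse_overlap > 0.98
    assert f.ellipse_width_um == pytest.approx(0.8, rel=0.05)
    assert f.ellipse_height_um == pytest.approx(0.4, rel=0.05)


def test_star_less_elliptical_than_square():
    star = generate_toy_polygons("irregular", 0.5)
    sq = generate_toy_polygons("square", 0.5)
    raw = np.zeros((220, 220))
    f_star = contour_features(star, raw, raw, SP)
    f_sq = contour_features(sq, raw, raw, SP)
    assert f_star.ellipse_overlap < f_sq.ellipse_overlap


def test_degenerate_polygon_rejected():
    c = Contour(0, 0, np.array([[0.1, 0.1], [0.1, 0.1], [0.1, 0.1], [0.1, 0.1]]), 0.5)
    with pytest.raises(ValueError, match="degenerate"):
        contour_features(c, np.zeros((10, 10)), np.zeros((10, 10)), SP)


def _featured(kind, size, plane, center):
    c = generate_toy_polygons(kind, size, plane=plane, center_um=center)
    raw = np.zeros((400, 400))
    c.features = contour_features(c, raw, raw, SP)
    return c


def test_concentric_pair_and_gate():
    a = _featured("circle", 0.2, 0, (1.0, 1.0))
    b = _featured("circle", 0.3, 1, (1.0, 1.0))
    pairs = enumerate_pairs({0: [a], 1: [b]}, D_um=0.4)
    assert len(pairs) == 1
    assert pairs[0].center_distance_um == pytest.approx(0.0, abs=1e-9)
    assert pairs[0].feature_vector.shape == (22,)
    # far centers: strict gate removes the pair
    far = _featured("circle", 0.3, 1, (1.0, 1.5))
    assert enumerate_pairs({0: [a], 1: [far]}, D_um=0.4) == []


def test_pair_vector_layout():
    a = _featured("circle", 0.2, 3, (1.0, 1.0))
    b = _featured("ellipse", 0.3, 4, (1.1, 1.2))
    (p,) = enumerate_pairs({3: [a], 4: [b]}, D_um=1.0)
    fa, fb = a.features.as_array(), b.features.as_array()
    np.testing.assert_allclose(p.feature_vector[:7], fa)
    np.testing.assert_allclose(p.feature_vector[7:14], fb)
    assert p.feature_vector[14] == pytest.approx(np.hypot(0.1, 0.2), rel=1e-6)
    np.testing.assert_allclose(p.feature_vector[15:], fa - fb)


def test_pair_enumeration_matches_brute_force(rng):
    """The gated pair set must equal exhaustive O(n^2) enumeration."""
    by_plane = {}
    for plane in range(4):
        cs = []
        for _ in range(rng.integers(2, 6)):
            center = tuple(rng.uniform(0.5, 3.0, size=2))
            cs.append(_featured("circle", float(rng.uniform(0.1, 0.3)), plane, center))
        by_plane[plane] = cs
    D = 0.7
    got = {
        (p.a.plane_i, id(p.a), id(p.b)) for p in enumerate_pairs(by_plane, D)
    }
    expected = set()
    for i in range(3):
        for a in by_plane[i]:
            for b in by_plane[i + 1]:
                if np.linalg.norm(a.center_um - b.center_um) < D:
                    expected.add((i, id(a), id(b)))
    assert got == expected


def test_saliency_ground_truth_rule():
    c = generate_toy_polygons("circle", 0.2, center_um=(1.0, 1.0))
    full = np.ones((200, 200), dtype=np.uint8)
    empty = np.zeros((200, 200), dtype=np.uint8)
    assert label_salient_ground_truth(c, full, 0.9, SP) == 1
    assert label_salient_ground_truth(c, empty, 0.9, SP) == 0
    half = np.zeros((200, 200), dtype=np.uint8)
    half[:, :100] = 1  # covers ~half the disc centered at x=100
    assert label_salient_ground_truth(c, half, 0.9, SP) == 0
    assert label_salient_ground_truth(c, half, 0.4, SP) == 1


def test_saliency_empty_interior_rejected():
    tiny = Contour(0, 0, np.array([[0.001, 0.001], [0.001, 0.002], [0.002, 0.0015]]), 0.5)
    with pytest.raises(ValueError, match="empty"):
        label_salient_ground_truth(tiny, np.ones((50, 50), dtype=np.uint8), 0.9, SP)


def test_balance_duplication():
    X = np.arange(10, dtype=float).reshape(5, 2)
    y = np.array([1, 0, 1, 0, 0])
    X0, y0 = balance_training_pairs(X, y, 0)
    np.testing.assert_array_equal(X0, X)
    X6, y6 = balance_training_pairs(X, y, 6)
    assert (y6 == 1).sum() == 2 * 7
    assert (y6 == 0).sum() == 3
    # duplicates sit right after their original: deterministic order
    np.testing.assert_array_equal(X6[:7], np.tile(X[0], (7, 1)))
    Xn, yn = balance_training_pairs(X, np.zeros(5, int), 6)
    np.testing.assert_array_equal(Xn, X)


def test_balance_hundred_positives_n6():
    X = np.zeros((1100, 22))
    y = np.concatenate([np.ones(100, int), np.zeros(1000, int)])
    _, y2 = balance_training_pairs(X, y, 6)
    assert (y2 == 1).sum() == 700


def _separable_pairs(n=120, d=22, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (rng.random(n) < 0.4).astype(int)
    X[y == 1, 0] += 6.0
    return X, y


def test_contour_model_separable_cv_auc():
    from sklearn.metrics import roc_auc_score

    X, y = _separable_pairs()
    yt, s = cross_validated_scores(X, y, M=2, rf_trees=50, seed=0)
    assert roc_auc_score(yt, s) > 0.95


def test_contour_model_permuted_labels_chance_level():
    from sklearn.metrics import roc_auc_score

    X, y = _separable_pairs(n=300)
    rng = np.random.default_rng(5)
    yp = rng.permutation(y)
    yt, s = cross_validated_scores(X, yp, M=2, rf_trees=50, seed=0)
    assert 0.4 <= roc_auc_score(yt, s) <= 0.6


def test_contour_model_validation():
    X, y = _separable_pairs()
    with pytest.raises(ValueError, match="feature"):
        train_contour_model(X[:, :7], y, M=2, rf_trees=10, seed=0)
    with pytest.raises(ValueError):
        train_contour_model(X, np.ones_like(y), M=2, rf_trees=10, seed=0)
    m1 = train_contour_model(X[:, :7], y, M=1, rf_trees=10, seed=0)
    assert m1.n_features == 7


def test_saliency_monotone_in_threshold():
    """Lowering T can only grow the salient set; T>1 empties it."""
    rng = np.random.default_rng(2)
    pairs = []
    for k in range(15):
        a = _featured("circle", 0.15 + 0.01 * k, 0, (1.0 + 0.05 * k, 1.0))
        b = _featured("circle", 0.15 + 0.01 * k, 1, (1.0 + 0.05 * k, 1.0))
        pairs.extend(enumerate_pairs({0: [a], 1: [b]}, D_um=0.4))
    X, y = _separable_pairs(n=60)
    model = train_contour_model(X, y, M=2, rf_trees=30, seed=0)
    prev: set[int] = set()
    for T in [1.01, 0.8, 0.5, 0.25, 0.0]:
        salient = {id(c) for c in classify_salient(model, pairs, T)}
        assert prev <= salient
        prev = salient
    assert classify_salient(model, pairs, 1.01) == []
    # T=0 keeps every gated contour
    assert len(classify_salient(model, pairs, 0.0)) == 2 * 15
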