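"""Patch extraction, training-set sampling, and the texture classifier."""

import numpy as np
import pytest

from mitoseg import (
    IntensityVolume,
    LabelVolume,
    PatchTrainingSet,
    extract_patch,
    predict_probability_map,
    sample_training_patches,
    train_patch_model,
)
from mitoseg.metrics import roc_auc

SPACING = (50.0, 10.0, 10.0)


def _mirror_index(i: int, n: int) -> int:
    """Independent reflect-padding oracle (no edge repeat), any offset."""
    period = 2 * (n - 1)
    i = abs(i) % period
    return period - i if i >= n else i


def test_constant_volume_patch_is_constant():
    vol = IntensityVolume(np.full((3, 30, 30), 100, dtype=np.uint8), SPACING)
    patch = extract_patch(vol, 1, 15, 15, 11)
    assert patch.shape == (121,)
    assert (patch == 100).all()


def test_single_pixel_patch():
    data = np.arange(2 * 5 * 5, dtype=np.uint8).reshape(2, 5, 5)
    vol = IntensityVolume(data, SPACING)
    assert extract_patch(vol, 1, 2, 3, 1)[0] == data[1, 2, 3]


def test_corner_patch_matches_mirror_oracle():
    data = (np.arange(20)[None, :, None] * np.arange(20)[None, None, :]).astype(float)
    vol = IntensityVolume(data, SPACING)
    N = 7
    got = extract_patch(vol, 0, 0, 0, N).reshape(N, N)
    half = N // 2
    expected = np.empty((N, N))
    for dy in range(N):
        for dx in range(N):
            expected[dy, dx] = data[
                0, _mirror_index(dy - half, 20), _mirror_index(dx - half, 20)
            ]
    np.testing.assert_allclose(got, expected)


def test_even_or_oversized_patch_rejected():
    vol = IntensityVolume(np.zeros((1, 10, 10), dtype=np.uint8), SPACING)
    with pytest.raises(ValueError):
        extract_patch(vol, 0, 5, 5, 4)
    with pytest.raises(ValueError):
        extract_patch(vol, 0, 5, 5, 21)


def test_sampling_counts_and_determinism(small_phantom):
    volume, labels = small_phantom
    ts1 = sample_training_patches(volume, labels, 689, 902, 11, seed=5)
    ts2 = sample_training_patches(volume, labels, 689, 902, 11, seed=5)
    assert len(ts1.vectors) == 1591
    assert ts1.counts == (689, 902)
    np.testing.assert_array_equal(ts1.indices, ts2.indices)
    ts3 = sample_training_patches(volume, labels, 689, 902, 11, seed=6)
    assert (ts1.indices != ts3.indices).any()


def test_sampling_insufficient_class_rejected():
    vol = IntensityVolume(np.zeros((2, 20, 20), dtype=np.uint8), SPACING)
    lab = LabelVolume(np.zeros((2, 20, 20), dtype=np.uint8), SPACING)
    with pytest.raises(ValueError, match="positive"):
        sample_training_patches(vol, lab, 10, 10, 5, seed=0)


def _separable_training_set(n=60, N=5):
    rng = np.random.default_rng(1)
    pos = np.full((n, N * N), 255.0) - rng.uniform(0, 5, (n, N * N))
    neg = np.zeros((n, N * N)) + rng.uniform(0, 5, (n, N * N))
    X = np.vstack([pos, neg]).astype(np.float32)
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    return PatchTrainingSet(vectors=X, labels=y, patch_size=N)


def test_separable_grays_reach_perfect_training_accuracy():
    ts = _separable_training_set()
    model = train_patch_model(ts, rf_trees=25, seed=0)
    assert (model.classifier.predict(ts.vectors) == ts.labels).all()


def test_single_class_training_rejected():
    ts = _separable_training_set()
    ts.labels[:] = 1
    with pytest.raises(ValueError):
        train_patch_model(ts, rf_trees=10, seed=0)


def test_permuted_labels_give_chance_level_auc(small_phantom):
    """Shuffling labels destroys the texture signal: out-of-bag AUC ~ 0.5."""
    volume, labels = small_phantom
    ts = sample_training_patches(volume, labels, 250, 250, 11, seed=2)
    rng = np.random.default_rng(3)
    ts_perm = PatchTrainingSet(
        vectors=ts.vectors, labels=rng.permutation(ts.labels), patch_size=11
    )
    model = train_patch_model(ts_perm, rf_trees=100, seed=2)
    from sklearn.metrics import roc_auc_score

    oob = model.classifier.oob_decision_function_[:, 1]
    auc = roc_auc_score(ts_perm.labels, oob)
    assert 0.4 <= auc <= 0.6


def test_phantom_training_oob_auc_high(small_patch_model):
    from sklearn.metrics import roc_auc_score

    clf = small_patch_model.classifier
    y = clf.oob_decision_function_[:, 1]
    # oob_score_ is accuracy; recompute AUC from the oob votes
    labels = np.concatenate([np.ones(300, int), np.zeros(400, int)])
    assert roc_auc_score(labels, y) > 0.8


def test_probability_map_shape_range_and_determinism(small_phantom, small_patch_model):
    volume, _ = small_phantom
    sub = IntensityVolume(volume.data[:2], volume.spacing)
    m1 = predict_probability_map(small_patch_model, sub)
    m2 = predict_probability_map(small_patch_model, sub)
    assert m1.shape == sub.shape
    assert 0.0 <= m1.data.min() and m1.data.max() <= 1.0
    np.testing.assert_array_equal(m1.data, m2.data)


def test_separable_model_scores_dark_slice_low():
    ts = _separable_training_set()
    model = train_patch_model(ts, rf_trees=25, seed=0)
    dark = IntensityVolume(np.zeros((1, 12, 12), dtype=np.uint8), SPACING)
    prob = predict_probability_map(model, dark)
    assert (prob.data < 0.5).all()


def test_map_roc_dominates_intensity_threshold(small_phantom, small_probability_map):
    """The learned texture map must beat naive dark-thresholding pixelwise."""
    volume, labels = small_phantom
    auc_map = roc_auc(small_probability_map.data, labels)
    auc_int = roc_auc(255.0 - volume.data, labels)
    assert auc_map > auc_int
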