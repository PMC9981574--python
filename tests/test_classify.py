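"""Patch pipeline and classifier contracts."""

import numpy as np
import pytest

from daphtrack import (
    CandidateObject,
    SceneParams,
    classify_objects,
    confusion_metrics,
    extract_patch,
    generate_patch_db,
    sobel_features,
    train_classifier,
)
from daphtrack.classify import area_average_resize, f1_score, features_from_patches, load_model, save_model

from .oracles import manual_sobel


# ---------------------------------------------------------------------------
# extract_patch


def test_constant_crop_gives_constant_patch():
    frame = np.full((30, 30), 120.0)
    patch = extract_patch(frame, (5, 5, 12, 9))
    assert patch.shape == (8, 8)
    np.testing.assert_allclose(patch, 120.0 / 255.0)


def test_eight_by_eight_crop_is_identity(rng):
    frame = rng.uniform(0, 255, (20, 20))
    patch = extract_patch(frame, (3, 4, 8, 8))
    np.testing.assert_allclose(patch, frame[4:12, 3:11] / 255.0)


def test_checkerboard_area_averaging():
    # 16x16 checkerboard of 2x2 tiles: each 8x8 output pixel is the mean of
    # its 2x2 source block, i.e. the tile value itself
    tiles = np.indices((8, 8)).sum(axis=0) % 2
    board = np.kron(tiles, np.ones((2, 2))) * 255.0
    frame = np.zeros((20, 20))
    frame[2:18, 2:18] = board
    patch = extract_patch(frame, (2, 2, 16, 16))
    np.testing.assert_allclose(patch, tiles.astype(float))


def test_degenerate_bbox_rejected():
    with pytest.raises(ValueError):
        extract_patch(np.zeros((10, 10)), (2, 2, 0, 5))


def test_area_average_resize_preserves_mean(rng):
    img = rng.uniform(0, 1, (13, 17))
    out = area_average_resize(img, (8, 8))
    # area averaging with equal-length intervals preserves the global mean
    assert abs(out.mean() - img.mean()) < 0.02


# ---------------------------------------------------------------------------
# sobel features


def test_constant_patch_has_zero_features():
    feats = sobel_features(np.full((8, 8), 0.6))
    assert feats.shape == (64,)
    np.testing.assert_allclose(feats, 0.0, atol=1e-12)


def test_vertical_step_matches_manual_convolution():
    patch = np.zeros((8, 8))
    patch[:, 4:] = 1.0
    feats = sobel_features(patch).reshape(8, 8)
    oracle = manual_sobel(patch)
    np.testing.assert_allclose(feats, oracle, atol=1e-12)
    # columns away from the step have zero response
    assert np.all(feats[:, :3] == 0.0) and np.all(feats[:, 6:] == 0.0)


def test_rotation_permutes_gradients_but_keeps_magnitudes(rng):
    patch = rng.uniform(0, 1, (8, 8))
    a = np.sort(sobel_features(patch))
    b = np.sort(sobel_features(np.rot90(patch)))
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_translation_with_bbox_leaves_features_unchanged(rng):
    # shifting the bbox together with the blob content is feature-invariant
    frame = np.full((40, 40), 200.0)
    blob = rng.uniform(0, 255, (10, 12))
    frame[5:15, 5:17] = blob
    f1 = sobel_features(extract_patch(frame, (5, 5, 12, 10)))
    frame2 = np.full((40, 40), 200.0)
    frame2[20:30, 13:25] = blob
    f2 = sobel_features(extract_patch(frame2, (13, 20, 12, 10)))
    np.testing.assert_allclose(f1, f2, atol=1e-12)


# ---------------------------------------------------------------------------
# training


def _separable_features(n=40):
    X = np.zeros((2 * n, 64))
    X[:n, 0] = 1.0
    X[n:, 0] = 10.0
    y = np.array(["daphnia"] * n + ["noise"] * n)
    return X, y


@pytest.mark.parametrize("method", ["rf", "svm"])
def test_perfectly_separable_training(method):
    X, y = _separable_features()
    model = train_classifier(X, y, method=method, seed=0)
    assert np.all(model.predict(X) == y)


def test_single_class_rejected():
    X = np.zeros((5, 64))
    with pytest.raises(ValueError):
        train_classifier(X, ["noise"] * 5, method="rf")


def test_same_seed_reproduces_predictions():
    p = SceneParams(seed=9)
    patches, labels = generate_patch_db(p, 50)
    X = features_from_patches(patches)
    probe = X[::3]
    m1 = train_classifier(X, labels, method="rf", seed=77)
    m2 = train_classifier(X, labels, method="rf", seed=77)
    np.testing.assert_array_equal(m1.score(probe), m2.score(probe))


def test_synthetic_db_holdout_accuracy_and_seed_stability():
    from sklearn.model_selection import train_test_split

    patches, labels = generate_patch_db(SceneParams(seed=13), 200)
    X = features_from_patches(patches)
    Xtr, Xte, ytr, yte = train_test_split(X, labels, test_size=0.25, random_state=0, stratify=labels)
    accs = []
    for seed in (0, 1):
        model = train_classifier(Xtr, ytr, method="rf", seed=seed)
        accs.append(float(np.mean(model.predict(Xte) == yte)))
    assert min(accs) >= 0.95
    assert abs(accs[0] - accs[1]) < 0.05


def test_model_round_trips_through_disk(tmp_path):
    X, y = _separable_features(10)
    model = train_classifier(X, y, method="rf", seed=1)
    save_model(model, tmp_path / "model.joblib")
    loaded = load_model(tmp_path / "model.joblib")
    np.testing.assert_array_equal(loaded.score(X), model.score(X))
    assert loaded.method == "rf"


# ---------------------------------------------------------------------------
# classify_objects


def test_classify_empty_object_list():
    X, y = _separable_features(10)
    model = train_classifier(X, y, method="rf", seed=0)
    assert classify_objects(model, np.zeros((10, 10)), []) == []


def test_training_exemplar_is_retained():
    p = SceneParams(seed=21)
    patches, labels = generate_patch_db(p, 100)
    X = features_from_patches(patches)
    model = train_classifier(X, labels, method="rf", seed=0)
    # paint a daphnia training patch into a frame and classify its bbox
    idx = int(np.nonzero(labels == "daphnia")[0][0])
    frame = np.full((30, 30), p.bg_level)
    frame[10:18, 10:18] = patches[idx] * 255.0
    obj = CandidateObject(0, (10, 10, 8, 8), (13.5, 13.5), 64)
    kept = classify_objects(model, frame, [obj])
    assert len(kept) == 1 and kept[0][0] is obj and kept[0][1] >= 0.5


# ---------------------------------------------------------------------------
# confusion metrics


def test_confusion_counts_and_derived_metrics():
    # TP=90, FP=10, FN=5, TN=20
    true = ["daphnia"] * 95 + ["noise"] * 30
    pred = ["daphnia"] * 90 + ["noise"] * 5 + ["daphnia"] * 10 + ["noise"] * 20
    c = confusion_metrics(pred, true)
    assert (c.tp, c.fp, c.fn, c.tn) == (90, 10, 5, 20)
    assert c.precision == pytest.approx(0.900, abs=5e-4)
    assert c.recall == pytest.approx(0.9474, abs=5e-5)
    assert c.f1 == pytest.approx(0.9231, abs=5e-5)
    assert c.accuracy == pytest.approx(0.880, abs=5e-4)


def test_zero_denominators_are_undefined_not_zero():
    c = confusion_metrics(["noise", "noise"], ["noise", "noise"])
    assert c.precision is None and c.recall is None and c.f1 is None
    assert c.accuracy == 1.0


def test_empty_labels_rejected():
    with pytest.raises(ValueError):
        confusion_metrics([], [])


def test_f1_is_harmonic_mean(rng):
    for _ in range(50):
        p, r = rng.uniform(0.05, 1.0, 2)
        f1 = f1_score(p, r)
        assert f1 == pytest.approx(2 / (1 / p + 1 / r))
        assert min(p, r) <= f1 <= max(p, r)
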