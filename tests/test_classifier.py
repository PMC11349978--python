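"""Tests for the dual CNN, GAO weight refinement and the OA grader."""

import numpy as np
import pytest

from gao_kneegrade.classifier import (
    DCNNSpec,
    DualCNNClassifier,
    NearestPatternGrader,
    TrainedMatrix,
    assign_grade,
    build_dcnn,
    fit_grades,
    gao_tune_fcnn,
    train_backbone,
)
from gao_kneegrade.optim import GAOConfig


def small_spec(**kw):
    defaults = dict(input_size=16, mfm_grid=(4, 4), width_multiplier=0.05)
    defaults.update(kw)
    return DCNNSpec(**defaults)


def toy_batch(rng, n=8, size=16):
    images = rng.random((n, size, size)) * 255
    mfms = rng.standard_normal((n, 4, 4, 6))
    labels = np.arange(n) % 2
    return images, mfms, labels


def test_branch_shapes_follow_pooling_arithmetic():
    model = build_dcnn(DCNNSpec(input_size=64, mfm_grid=(4, 4), width_multiplier=1.0), seed=0)
    x = np.zeros((1, 1, 64, 64), dtype=np.float32)
    for layer in model.branch1:
        x = layer.forward(x)
    assert x.shape == (1, 128, 16, 16)  # two 2x pools on a 64-pixel input
    m = np.zeros((1, 6, 4, 4), dtype=np.float32)
    for layer in model.branch2:
        m = layer.forward(m)
    assert m.shape == (1, 64, 1, 1)


@pytest.mark.parametrize("size", [32, 64, 128])
def test_shape_oracle_across_input_sizes(size):
    model = build_dcnn(DCNNSpec(input_size=size, mfm_grid=(4, 4), width_multiplier=0.05), seed=1)
    x = np.zeros((2, 1, size, size), dtype=np.float32)
    for layer in model.branch1:
        x = layer.forward(x)
    assert x.shape[2:] == (size // 4, size // 4)


def test_same_seed_gives_identical_initialisation():
    w1 = build_dcnn(small_spec(), seed=4).get_weights()
    w2 = build_dcnn(small_spec(), seed=4).get_weights()
    assert all((w1[k] == w2[k]).all() for k in w1)


def test_too_small_inputs_are_rejected():
    with pytest.raises(ValueError):
        DCNNSpec(input_size=2).validate()
    with pytest.raises(ValueError):
        DCNNSpec(mfm_grid=(2, 2)).validate()


def test_forward_outputs_live_on_the_probability_simplex(rng):
    model = build_dcnn(small_spec(), seed=0)
    images, mfms, _ = toy_batch(rng)
    probs = model.predict_proba(images, mfms)
    assert probs.shape == (8, 2)
    assert (probs >= 0).all()
    assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6


def test_zero_inputs_are_reproducible():
    model = build_dcnn(small_spec(), seed=2)
    z_img, z_mfm = np.zeros((1, 16, 16)), np.zeros((1, 4, 4, 6))
    p1 = model.predict_proba(z_img, z_mfm)
    p2 = model.predict_proba(z_img, z_mfm)
    assert (p1 == p2).all()


def test_softmax_sharpens_when_logit_gap_doubles():
    from gao_kneegrade.nn import softmax

    base = softmax(np.array([[1.0, 0.0]]))
    sharp = softmax(np.array([[2.0, 0.0]]))
    assert sharp[0, 0] > base[0, 0]


def test_zero_epochs_returns_initial_weights(rng):
    model = build_dcnn(small_spec(), seed=3)
    init = model.get_weights()
    images, mfms, labels = toy_batch(rng)
    tm = train_backbone(model, images, mfms, labels, epochs=0)
    assert all((tm.weights[k] == init[k]).all() for k in init)


def test_training_is_deterministic_for_a_seed(rng):
    images, mfms, labels = toy_batch(rng, n=12)
    tms = []
    for _ in range(2):
        model = build_dcnn(small_spec(), seed=5)
        tms.append(train_backbone(model, images, mfms, labels, epochs=2, seed=5))
    assert all((tms[0].weights[k] == tms[1].weights[k]).all() for k in tms[0].weights)


def test_single_class_training_is_rejected(rng):
    images, mfms, _ = toy_batch(rng)
    model = build_dcnn(small_spec(), seed=0)
    with pytest.raises(ValueError):
        train_backbone(model, images, mfms, np.zeros(8, dtype=int), epochs=1)


def test_trained_matrix_round_trips_bit_exactly(tmp_path, rng):
    images, mfms, labels = toy_batch(rng)
    model = build_dcnn(small_spec(), seed=6)
    tm = train_backbone(model, images, mfms, labels, epochs=1, seed=6)
    path = tmp_path / "tm.npz"
    tm.save(path)
    loaded = TrainedMatrix.load(path)
    assert all((loaded.weights[k] == tm.weights[k]).all() for k in tm.weights)
    m2 = loaded.build_model()
    assert (m2.predict_proba(images, mfms) == model.predict_proba(images, mfms)).all()


def test_gao_tuning_never_degrades_validation_fitness(rng):
    images, mfms, labels = toy_batch(rng, n=16)
    model = build_dcnn(small_spec(), seed=7)
    train_backbone(model, images, mfms, labels, epochs=2, seed=7)
    feats = model.penultimate(images[8:], mfms[8:])
    from gao_kneegrade.classifier import _val_fitness

    layer = model.final_dense
    incumbent = np.concatenate([layer.W.ravel(), layer.b])
    pre = _val_fitness(incumbent, feats, labels[8:], layer.W.shape)
    cfg = GAOConfig(max_iterations=10, convergence_window=10, population_size=10, seed=7)
    tm = gao_tune_fcnn(model, (images[:8], mfms[:8], labels[:8]), (images[8:], mfms[8:], labels[8:]), cfg)
    assert tm.metadata["val_fitness"] <= pre


def test_gao_tuning_is_deterministic(rng):
    images, mfms, labels = toy_batch(rng, n=16)
    results = []
    for _ in range(2):
        model = build_dcnn(small_spec(), seed=8)
        train_backbone(model, images, mfms, labels, epochs=1, seed=8)
        cfg = GAOConfig(max_iterations=5, convergence_window=5, population_size=8, seed=8)
        tm = gao_tune_fcnn(model, (images, mfms, labels), (images, mfms, labels), cfg)
        results.append(tm.weights)
    assert all((results[0][k] == results[1][k]).all() for k in results[0])


def test_gao_dimension_cap_is_enforced(rng):
    images, mfms, labels = toy_batch(rng)
    model = build_dcnn(small_spec(width_multiplier=0.25), seed=0)
    train_backbone(model, images, mfms, labels, epochs=0)
    with pytest.raises(ValueError, match="width"):
        gao_tune_fcnn(model, (images, mfms, labels), (images, mfms, labels), dim_cap=4)


def test_estimator_fits_and_predicts_separable_phantoms(small_phantom_set):
    d = small_phantom_set
    clf = DualCNNClassifier(
        input_size=64, mfm_grid=d["mfms"].shape[1:3], epochs=8,
        gao_iterations=5, seed=0,
    )
    clf.fit((d["images"], d["mfms"]), d["labels"])
    assert clf.val_fitness_ <= clf.pre_tuning_val_fitness_
    train_acc = (clf.predict((d["images"], d["mfms"])) == d["labels"]).mean()
    assert train_acc >= 0.8
    params = clf.get_params()
    assert params["epochs"] == 8  # sklearn param plumbing intact


# ---------------------------------------------------------------------------
# nearest-pattern grading


def test_single_sample_per_grade_centroids_equal_samples():
    F = np.arange(24, dtype=float).reshape(4, 6)
    grader = fit_grades(F, np.array([1, 2, 3, 4]))
    Z = (F - grader.mean_) / grader.std_
    assert np.allclose(grader.centroids_, Z)
    assert (assign_grade(F, grader) == [1, 2, 3, 4]).all()


def test_duplicated_samples_leave_centroids_unchanged():
    F = np.arange(24, dtype=float).reshape(4, 6)
    g1 = fit_grades(F, np.array([1, 2, 3, 4]))
    g2 = fit_grades(np.vstack([F, F]), np.array([1, 2, 3, 4, 1, 2, 3, 4]))
    assert np.allclose(g1.centroids_, g2.centroids_)


def test_equidistant_feature_takes_the_lower_grade(rng):
    F = np.vstack([rng.standard_normal((3, 6)) + mu for mu in (0.0, 4.0, 8.0, 12.0)])
    grades = np.repeat([1, 2, 3, 4], 3)
    grader = fit_grades(F, grades)
    mid = grader.mean_ + grader.std_ * (grader.centroids_[1] + grader.centroids_[2]) / 2.0
    # exact midpoint between grades 2 and 3 under equal dispersion
    grader.dispersion_ = np.ones_like(grader.dispersion_)
    assert assign_grade(mid, grader)[0] == 2


def test_missing_grade_is_reported():
    F = np.random.default_rng(0).random((6, 6))
    with pytest.raises(ValueError, match=r"\[3, 4\]"):
        fit_grades(F, np.array([1, 1, 2, 2, 1, 2]))


def test_well_separated_clusters_grade_accurately(rng):
    n = 400
    grades = rng.integers(1, 5, n)
    centers = {g: rng.normal(0, 5, 6) for g in (1, 2, 3, 4)}
    F = np.stack([centers[g] + rng.normal(0, 0.5, 6) for g in grades])
    half = n // 2
    grader = fit_grades(F[:half], grades[:half])
    acc = (assign_grade(F[half:], grader) == grades[half:]).mean()
    assert acc >= 0.95
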