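"""Attention-MIL forward algebra, stratified folds, training behaviour."""

import dataclasses

import numpy as np
import pytest

from ibdatlas.cohort import Bag
from ibdatlas.mil import (
    AttMILParams,
    _backward,
    attention_map,
    attmil_forward,
    cross_validate,
    ensemble_predict,
    init_weights,
    stratified_kfold,
    train_fold,
)


@pytest.fixture()
def params():
    return AttMILParams(feature_dim=7, embed_dim=5, attn_dim=3, seed=1)


@pytest.fixture()
def weights(params, rng):
    w = init_weights(params)
    for k in w:
        w[k] = rng.normal(0, 0.5, size=w[k].shape)
    return w


def test_single_tile_bag_attention_is_one(params, weights, rng):
    X = rng.normal(size=(1, 7))
    _, a, _ = attmil_forward(X, weights)
    np.testing.assert_allclose(a, [1.0])


def test_prediction_permutation_invariant(params, weights, rng):
    X = rng.normal(size=(9, 7))
    y1, a1, _ = attmil_forward(X, weights)
    perm = rng.permutation(9)
    y2, a2, _ = attmil_forward(X[perm], weights)
    assert y1 == pytest.approx(y2, abs=1e-12)
    np.testing.assert_allclose(a1[perm], a2, atol=1e-12)


def test_tile_duplication_keeps_prediction_halves_attention(params, weights, rng):
    X = rng.normal(size=(4, 7))
    y1, a1, _ = attmil_forward(X, weights)
    y2, a2, _ = attmil_forward(np.vstack([X, X]), weights)
    assert y2 == pytest.approx(y1, abs=1e-10)
    np.testing.assert_allclose(a2[:4], a1 / 2, atol=1e-12)
    assert a2.sum() == pytest.approx(1.0)


def test_attention_sums_to_one(params, weights, rng):
    for _ in range(5):
        _, a, _ = attmil_forward(rng.normal(size=(rng.integers(1, 30), 7)), weights)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)
        assert (a >= 0).all()


def test_dimension_mismatch_rejected(params, weights, rng):
    with pytest.raises(ValueError, match="dim"):
        attmil_forward(rng.normal(size=(3, 5)), weights)


@pytest.mark.parametrize("gated", [False, True])
def test_backward_matches_numerical_gradient(gated, rng):
    p = AttMILParams(feature_dim=6, embed_dim=4, attn_dim=3, gated=gated, seed=2)
    w = init_weights(p)
    for k in w:
        w[k] = rng.normal(0, 0.5, size=w[k].shape)
    X = rng.normal(size=(5, 6))
    t = 0.4
    yhat, _, cache = attmil_forward(X, w, gated)
    grads = _backward(2 * (yhat - t), w, cache, gated)
    eps = 1e-6
    for k in w:
        it = np.nditer(w[k], flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            w[k][i] += eps
            lp = (attmil_forward(X, w, gated)[0] - t) ** 2
            w[k][i] -= 2 * eps
            lm = (attmil_forward(X, w, gated)[0] - t) ** 2
            w[k][i] += eps
            assert grads[k][i] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


def test_stratified_kfold_sizes_and_balance(rng):
    targets = rng.random(100)
    plan = stratified_kfold(targets, k=5, seed=0)
    sizes = np.bincount(plan.assignment, minlength=5)
    assert sizes.tolist() == [20] * 5
    # per-fold target means stay close to the global mean
    for f in range(5):
        assert abs(targets[plan.assignment == f].mean() - targets.mean()) < 0.08
    # identical targets: single bin, still balanced
    plan2 = stratified_kfold(np.full(23, 0.5), k=5, seed=1)
    sizes2 = np.bincount(plan2.assignment, minlength=5)
    assert sizes2.max() - sizes2.min() <= 1
    with pytest.raises(ValueError):
        stratified_kfold([0.1, 0.2], k=5)


def _toy_bags(n, d, seed, signal=2.0, tiles=(10, 25)):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=d)
    u /= np.linalg.norm(u)
    bags = []
    for i in range(n):
        sev = rng.random()
        nt = int(rng.integers(*tiles))
        X = rng.normal(size=(nt, d))
        lesion = rng.random(nt) < sev
        X[lesion] += signal * u
        bags.append(Bag(f"B{i}", X, float(sev), lesion))
    return bags


def test_training_is_deterministic_and_loss_decreases():
    bags = _toy_bags(40, 8, seed=3)
    p = AttMILParams(feature_dim=8, embed_dim=8, attn_dim=4, epochs=5, seed=9)
    w1, log1 = train_fold(bags, p)
    w2, log2 = train_fold(bags, p)
    for k in w1:
        np.testing.assert_array_equal(w1[k], w2[k])
    assert log1 == log2
    assert log1[-1] < log1[0]


def test_cross_validate_partitions_bags():
    bags = _toy_bags(30, 6, seed=4)
    p = AttMILParams(feature_dim=6, embed_dim=6, attn_dim=3, epochs=2, seed=0)
    res = cross_validate(bags, p)
    assert np.isfinite(res["oof_predictions"]).all()  # every bag predicted once
    assert len(res["models"]) == 5
    counts = np.bincount(res["plan"].assignment, minlength=5)
    assert counts.sum() == 30 and counts.max() - counts.min() <= 1


def test_ensemble_is_arithmetic_mean(weights, rng):
    bags = [Bag("b", rng.normal(size=(5, 7)), 0.5)]
    single = ensemble_predict([weights], bags, clip=False)
    same = ensemble_predict([weights, weights], bags, clip=False)
    np.testing.assert_allclose(single, same)
    w2 = {k: v + 0.1 for k, v in weights.items()}
    p1 = attmil_forward(bags[0].features, weights)[0]
    p2 = attmil_forward(bags[0].features, w2)[0]
    both = ensemble_predict([weights, w2], bags, clip=False)
    assert both[0] == pytest.approx((p1 + p2) / 2)
    clipped = ensemble_predict([weights, w2], bags, clip=True)
    assert 0.0 <= clipped[0] <= 1.0


def test_attention_map_threshold_and_degenerate(weights, rng):
    bag = Bag("b", rng.normal(size=(12, 7)), 0.3)
    m = attention_map(weights, bag, threshold=0.0, top_k=5)
    assert m.flagged.all()  # threshold 0 flags every tile
    assert len(m.top_k) == 5
    assert m.rescaled.min() == 0.0 and m.rescaled.max() == 1.0
    # uniform-feature bag: identical tiles -> uniform attention -> degenerate
    uniform = Bag("u", np.tile(rng.normal(size=(1, 7)), (6, 1)), 0.3)
    mu = attention_map(weights, uniform)
    assert mu.degenerate
    assert not mu.flagged.any()


def test_heldout_correlation_increases_with_signal():
    rs = []
    for shift in (0.0, 1.0, 2.0):
        bags = _toy_bags(150, 16, seed=11, signal=shift, tiles=(30, 60))
        p = AttMILParams(feature_dim=16, embed_dim=32, attn_dim=16, epochs=15, seed=1)
        rs.append(cross_validate(bags, p)["pooled_r"])
    assert rs[0] < rs[1] < rs[2]  # held-out R increases with the planted signal
    assert abs(rs[0]) < 0.3 and rs[2] > 0.5
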