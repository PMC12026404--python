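"""Attention-based multiple-instance regression of histologic activity.

A whole-slide image enters as a bag of tile feature vectors (n_tiles x d)
with one normalized histopathology score as the bag label. The model
embeds each tile (linear + ReLU), pools the bag with learned softmax
attention — optionally gated:

    h_i = relu(W1 x_i + b1)
    u_i = w' tanh(V' h_i)            (gated: elementwise * sigmoid(U' h_i))
    a   = softmax(u),  z = sum_i a_i h_i,  prediction = wo' z + bo

— and regresses the pooled representation on the score with mean-squared
error, batch size 1, learning rate 1e-4 and decoupled weight decay 0.01
under an adaptive-moment (AdamW-style) optimizer. Training, 5-fold
score-stratified cross-validation, fold ensembling by arithmetic
averaging, and attention-map extraction are all plain NumPy with explicit
gradients, so the pipeline is deterministic given a seed and runs on one
CPU.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .cohort import Bag

__all__ = [
    "AttMILParams",
    "FoldPlan",
    "AttentionMap",
    "init_weights",
    "attmil_forward",
    "stratified_kfold",
    "train_fold",
    "cross_validate",
    "ensemble_predict",
    "attention_map",
]


@dataclasses.dataclass
class AttMILParams:
    """Hyperparameters; the stated pipeline defaults are lr 1e-4, weight
    decay 0.01, batch size 1."""

    feature_dim: int = 64
    embed_dim: int = 32
    attn_dim: int = 16
    gated: bool = False
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 1
    epochs: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def init_weights(params: AttMILParams) -> dict[str, np.ndarray]:
    """He-scaled Gaussian init, seeded; biases start at zero."""
    rng = np.random.default_rng(params.seed)
    d, e, a = params.feature_dim, params.embed_dim, params.attn_dim
    w = {
        "W1": rng.normal(0, np.sqrt(2.0 / d), size=(d, e)),
        "b1": np.zeros(e),
        "V": rng.normal(0, np.sqrt(1.0 / e), size=(e, a)),
        "w": rng.normal(0, np.sqrt(1.0 / a), size=a),
        "wo": rng.normal(0, np.sqrt(1.0 / e), size=e),
        "bo": np.zeros(1),
    }
    if params.gated:
        w["U"] = rng.normal(0, np.sqrt(1.0 / e), size=(e, a))
    return w


def attmil_forward(
    X: np.ndarray, weights: dict[str, np.ndarray], gated: bool = False
) -> tuple[float, np.ndarray, dict]:
    """Forward pass over one bag; returns (prediction, attention, cache).

    Attention weights are a softmax over tiles and sum to 1; the
    prediction is permutation-invariant in tile order because pooling is a
    weighted sum.
    """
    if X.ndim != 2 or X.shape[1] != weights["W1"].shape[0]:
        raise ValueError(
            f"bag feature dim {X.shape} does not match model dim {weights['W1'].shape[0]}"
        )
    pre1 = X @ weights["W1"] + weights["b1"]
    H = np.maximum(pre1, 0.0)
    T = np.tanh(H @ weights["V"])
    if gated:
        G = 1.0 / (1.0 + np.exp(-(H @ weights["U"])))
        M = T * G
    else:
        G = None
        M = T
    u = M @ weights["w"]
    u = u - u.max()  # stable softmax
    expu = np.exp(u)
    a = expu / expu.sum()
    z = a @ H
    yhat = float(z @ weights["wo"] + weights["bo"][0])
    cache = {"X": X, "pre1": pre1, "H": H, "T": T, "G": G, "a": a, "z": z}
    return yhat, a, cache


def _backward(
    dyhat: float, weights: dict[str, np.ndarray], cache: dict, gated: bool
) -> dict[str, np.ndarray]:
    X, H, T, G, a, z = (cache[k] for k in ("X", "H", "T", "G", "a", "z"))
    grads = {
        "wo": dyhat * z,
        "bo": np.array([dyhat]),
    }
    dz = dyhat * weights["wo"]
    da = dyhat * (H @ weights["wo"])
    dH = a[:, None] * dz[None, :]
    # softmax backward
    du = a * (da - float(a @ da))
    if gated:
        M = T * G
        dM = np.outer(du, weights["w"])
        dT = dM * G
        dG = dM * T
        dpreU = dG * G * (1.0 - G)
        grads["U"] = H.T @ dpreU
        dH += dpreU @ weights["U"].T
        grads["w"] = M.T @ du
    else:
        dT = np.outer(du, weights["w"])
        grads["w"] = T.T @ du
    dpreV = dT * (1.0 - T**2)
    grads["V"] = H.T @ dpreV
    dH += dpreV @ weights["V"].T
    dpre1 = dH * (cache["pre1"] > 0)
    grads["W1"] = X.T @ dpre1
    grads["b1"] = dpre1.sum(axis=0)
    return grads


class _AdamW:
    """Adaptive-moment optimizer with decoupled weight decay.

    Weight decay is applied to weight matrices/vectors, not biases."""

    def __init__(self, weights, lr, weight_decay, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = *betas, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}

    def step(self, weights, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if k not in ("b1", "bo"):
                upd = upd + self.wd * weights[k]
            weights[k] -= self.lr * upd


@dataclasses.dataclass
class FoldPlan:
    """Fold assignment per bag with the stratification bin edges used."""

    k: int
    assignment: np.ndarray  # fold index per bag
    bin_edges: np.ndarray

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def stratified_kfold(
    targets: Sequence[float], k: int = 5, n_bins: int = 4, seed: int = 0
) -> FoldPlan:
    """Score-stratified k-fold split.

    Targets are cut into quantile bins; within each bin the bags are
    shuffled (seeded) and dealt round-robin to folds with a carry-over
    counter, so per-bin fold counts differ by at most 1 and overall fold
    sizes differ by at most 1. Degenerate targets (all identical) fall in
    a single bin, giving a plain balanced shuffle split.
    """
    t = np.asarray(targets, float)
    if len(t) < k:
        raise ValueError(f"need at least k={k} bags, got {len(t)}")
    edges = np.unique(np.quantile(t, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.digitize(t, edges, right=True)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(t), dtype=int)
    counter = 0
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = counter % k
            counter += 1
    return FoldPlan(k=k, assignment=assignment, bin_edges=edges)


def train_fold(
    bags: Sequence[Bag], params: AttMILParams
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Train one attMIL model on the given bags; returns (weights, loss log).

    Deterministic given params.seed and the bag order: the same RNG drives
    both initialization and per-epoch shuffling.
    """
    rng = np.random.default_rng(params.seed)
    weights = init_weights(params)
    opt = _AdamW(weights, params.learning_rate, params.weight_decay)
    log = []
    n = len(bags)
    for _ in range(params.epochs):
        order = rng.permutation(n)
        total = 0.0
        for i in order:
            bag = bags[i]
            yhat, _, cache = attmil_forward(bag.features, weights, params.gated)
            err = yhat - bag.target
            loss = err * err
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss on bag {bag.slide_id}; "
                    f"prediction={yhat}, target={bag.target}"
                )
            grads = _backward(2.0 * err, weights, cache, params.gated)
            opt.step(weights, grads)
            total += loss
        log.append(total / n)
    return weights, log


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def cross_validate(
    bags: Sequence[Bag], params: AttMILParams, plan: FoldPlan | None = None
) -> dict:
    """k-fold cross-validation; every bag predicted once out-of-fold.

    Returns out-of-fold predictions (bag order), the trained fold models,
    per-fold Pearson R between true and predicted scores, and the pooled R.
    """
    if plan is None:
        plan = stratified_kfold([b.target for b in bags], seed=params.seed)
    oof = np.full(len(bags), np.nan)
    models, fold_r = [], []
    targets = np.array([b.target for b in bags])
    for fold in range(plan.k):
        train_idx, test_idx = plan.fold_indices(fold)
        fold_params = dataclasses.replace(params, seed=params.seed + fold)
        weights, _ = train_fold([bags[i] for i in train_idx], fold_params)
        preds = np.array(
            [attmil_forward(bags[i].features, weights, params.gated)[0] for i in test_idx]
        )
        oof[test_idx] = preds
        models.append(weights)
        fold_r.append(_pearson(targets[test_idx], preds))
    return {
        "oof_predictions": oof,
        "models": models,
        "fold_r": fold_r,
        "pooled_r": _pearson(targets, oof),
        "plan": plan,
    }


def ensemble_predict(
    models: Sequence[dict[str, np.ndarray]],
    bags: Sequence[Bag],
    gated: bool = False,
    clip: bool = True,
) -> np.ndarray:
    """Arithmetic mean of per-model slide predictions.

    Predictions are clipped to [0, 1] at reporting time (the targets are
    normalized scores); pass clip=False for the raw ensemble mean.
    """
    if not models:
        raise ValueError("need at least one model")
    preds = np.array(
        [[attmil_forward(b.features, m, gated)[0] for b in bags] for m in models]
    )
    out = preds.mean(axis=0)
    return np.clip(out, 0.0, 1.0) if clip else out


@dataclasses.dataclass
class AttentionMap:
    """Attention weights of one slide plus display-ready rescaling."""

    slide_id: str
    attention: np.ndarray  # softmax weights, sum to 1
    rescaled: np.ndarray  # min-max rescaled to [0, 1]
    flagged: np.ndarray  # rescaled >= threshold
    top_k: np.ndarray  # tile indices, highest attention first
    threshold: float
    degenerate: bool  # attention (near-)uniform; rescaling uninformative


def attention_map(
    weights: dict[str, np.ndarray],
    bag: Bag,
    threshold: float = 0.4,
    top_k: int = 10,
    gated: bool = False,
) -> AttentionMap:
    """Extract and rescale the attention over one bag's tiles.

    Raw softmax attention is min-max rescaled to [0, 1] for display; tiles
    at or above the threshold are flagged, and the top-k tile indices are
    reported for review. A bag with (numerically) uniform attention is
    flagged degenerate — its rescaling carries no information.
    """
    _, a, _ = attmil_forward(bag.features, weights, gated)
    span = a.max() - a.min()
    degenerate = span < 1e-12
    rescaled = np.zeros_like(a) if degenerate else (a - a.min()) / span
    order = np.argsort(-a, kind="stable")
    return AttentionMap(
        slide_id=bag.slide_id,
        attention=a,
        rescaled=rescaled,
        flagged=rescaled >= threshold if not degenerate else np.zeros_like(a, bool),
        top_k=order[: min(top_k, len(a))],
        threshold=threshold,
        degenerate=degenerate,
    )
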