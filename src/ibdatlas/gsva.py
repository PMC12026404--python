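"""Single-sample gene-set variation scoring (kernel-CDF rank random walk).

The procedure scores how coherently a feature set sits at the top (or
bottom) of a sample's expression profile, relative to the other samples:

1. *Kernel CDF transform.* Each feature i is rescaled across samples with a
   Gaussian kernel estimate of its cumulative distribution,
   ``z_ij = (1/n) sum_k Phi((x_ij - x_ik) / h_i)`` with bandwidth
   ``h_i = s_i / 4`` (s_i = sample standard deviation of feature i), or
   with the plain empirical CDF (``ecdf`` kernel), which makes the whole
   pipeline invariant to any strictly increasing per-feature transform.
2. *Symmetric rank statistic.* Within each sample, features are ordered by
   z descending; a feature at rank r (1-based) carries weight
   ``|p/2 - r|`` so extremes at either end count most.
3. *Weighted random walk.* Walking down the ranked list, set members step
   up by their normalized weight ``|r|^tau / sum_set |r|^tau`` and
   non-members step down by ``1/(p - |set|)``. The enrichment score is
   either (max positive excursion) + (min negative excursion)
   ("difference" mode, the default) or the single largest-magnitude
   excursion ("max_deviation" mode). With tau = 1 the score lies in
   [-1, 1].

Used for the biopsy molecular inflammation score (bMIS) on log2(TPM+1)
expression and for scoring serum-protein severity signatures (IPSS) on NPX
matrices.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .proteomics import SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentParams",
    "kcdf_transform",
    "enrichment_score",
    "score_sets",
    "bmis",
    "ipss_score",
]


@dataclasses.dataclass
class EnrichmentParams:
    """Parameters of the kernel transform and the rank walk.

    kernel: 'gaussian_kcdf' (bandwidth s_i/4 per feature) or 'ecdf'.
    tau: weight exponent on the symmetric rank statistic (>= 0).
    es_mode: 'difference' or 'max_deviation'.
    min_set_size: sets with fewer surviving features are skipped.
    """

    kernel: str = "gaussian_kcdf"
    tau: float = 1.0
    es_mode: str = "difference"
    min_set_size: int = 2

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian_kcdf", "ecdf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.es_mode not in ("difference", "max_deviation"):
            raise ValueError(f"unknown es_mode {self.es_mode!r}")


def kcdf_transform(X: pd.DataFrame, params: EnrichmentParams | None = None) -> pd.DataFrame:
    """Cross-sample kernel CDF transform, one feature (row) at a time.

    Gaussian kernel: z_ij = (1/n) sum_k Phi((x_ij - x_ik)/h_i), h_i = s_i/4.
    A zero-variance feature has no bandwidth; it is an error (named in the
    message) rather than silently perturbed. The ecdf kernel returns
    rank/n with midranks for ties.
    """
    params = params or EnrichmentParams()
    if X.shape[1] < 3:
        raise ValueError("kernel CDF needs at least 3 samples for cross-sample spread")
    vals = X.to_numpy(float)
    if params.kernel == "ecdf":
        Z = np.apply_along_axis(lambda r: rankdata(r) / len(r), 1, vals)
    else:
        s = vals.std(axis=1, ddof=1)
        bad = np.flatnonzero(s <= 0)
        if bad.size:
            names = list(X.index[bad[:5]])
            raise ValueError(
                f"zero-variance feature(s) under gaussian kernel: {names}"
                + (" ..." if bad.size > 5 else "")
            )
        h = s / 4.0
        Z = np.empty_like(vals)
        block = max(1, int(2e6 // (vals.shape[1] ** 2)))  # bound peak memory
        for start in range(0, vals.shape[0], block):
            sl = slice(start, start + block)
            diffs = (vals[sl, :, None] - vals[sl, None, :]) / h[sl, None, None]
            Z[sl] = norm.cdf(diffs).mean(axis=2)
    return pd.DataFrame(Z, index=X.index, columns=X.columns)


def _walk_scores(
    order: np.ndarray, weights: np.ndarray, in_set: np.ndarray, es_mode: str
) -> float:
    """Run the rank walk over one ordered profile and return the ES."""
    p = len(order)
    members = in_set[order]
    w = weights[order]
    wset = np.abs(w) * members
    denom = wset.sum()
    if denom == 0:
        # all member weights zero (can only happen at even p with tau>0
        # and members exactly at p/2): walk up uniformly instead
        wset = members.astype(float)
        denom = wset.sum()
    steps = np.where(members, wset / denom, -1.0 / (p - members.sum()))
    walk = np.cumsum(steps)
    if es_mode == "difference":
        return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))
    peak = walk[np.argmax(np.abs(walk))]
    return float(peak)


def enrichment_score(
    z_column: pd.Series | np.ndarray,
    feature_set: Iterable[str] | np.ndarray,
    params: EnrichmentParams | None = None,
    feature_names: Sequence[str] | None = None,
) -> float:
    """Enrichment score of one feature set in one sample's z profile.

    Features are ordered by z descending, ties broken by stable feature
    order; the symmetric rank statistic |p/2 - rank|^tau weights the up
    steps of the walk. Requires 1 <= |set| < p (strict: the complement
    must be nonempty).
    """
    params = params or EnrichmentParams()
    if isinstance(z_column, pd.Series):
        feature_names = list(z_column.index)
        z = z_column.to_numpy(float)
    else:
        z = np.asarray(z_column, float)
        if feature_names is None:
            raise ValueError("feature_names required with a bare array")
    names = np.asarray(feature_names)
    in_set = np.isin(names, list(feature_set))
    k = int(in_set.sum())
    p = len(z)
    if k == 0:
        raise ValueError("feature set shares no features with the profile")
    if k == p:
        raise ValueError("feature set equals the whole profile; complement is empty")
    # stable sort on -z keeps original feature order among ties
    order = np.argsort(-z, kind="stable")
    ranks = np.empty(p)
    ranks[order] = np.arange(1, p + 1)
    weights = np.abs(p / 2.0 - ranks) ** params.tau
    return _walk_scores(order, weights, in_set, params.es_mode)


def score_sets(
    X: pd.DataFrame,
    sets: Sequence[SignatureSet],
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Score every set in every sample; returns samples x sets DataFrame.

    Features absent from X are dropped from each set with a logged count;
    sets left with fewer than ``params.min_set_size`` features are skipped
    with a warning. Deterministic: no randomness anywhere in the pipeline.
    """
    params = params or EnrichmentParams()
    Z = kcdf_transform(X, params)
    zvals = Z.to_numpy(float)
    names = np.asarray(Z.index)
    p = len(names)
    results: dict[str, np.ndarray] = {}
    for s in sets:
        members = [m for m in s.members if m in set(names)]
        dropped = len(s.members) - len(members)
        if dropped:
            logger.info("set %s: dropped %d feature(s) absent from the matrix", s.name, dropped)
        if len(members) < params.min_set_size or len(members) >= p:
            warnings.warn(
                f"set {s.name}: {len(members)} usable features; skipped", stacklevel=2
            )
            continue
        in_set = np.isin(names, members)
        col = np.empty(Z.shape[1])
        for j in range(Z.shape[1]):
            z = zvals[:, j]
            order = np.argsort(-z, kind="stable")
            ranks = np.empty(p)
            ranks[order] = np.arange(1, p + 1)
            weights = np.abs(p / 2.0 - ranks) ** params.tau
            col[j] = _walk_scores(order, weights, in_set, params.es_mode)
        results[s.name] = col
    return pd.DataFrame(results, index=Z.columns)


def bmis(
    X_expr: pd.DataFrame,
    up_set: SignatureSet,
    down_set: SignatureSet | None = None,
    params: EnrichmentParams | None = None,
) -> pd.Series:
    """Biopsy molecular inflammation score per sample.

    Single-sample enrichment of the inflammation up-signature on
    log2(TPM+1) expression, minus the down-signature score when one is
    supplied. The signature gene lists are external inputs.
    """
    sets = [up_set] + ([down_set] if down_set is not None else [])
    scores = score_sets(X_expr, sets, params)
    out = scores[up_set.name].copy()
    if down_set is not None:
        out = out - scores[down_set.name]
    out.name = "bMIS"
    return out


def ipss_score(
    npx_wide: pd.DataFrame,
    signature: SignatureSet,
    params: EnrichmentParams | None = None,
    method: str = "gsva",
) -> pd.Series:
    """Per-sample severity score of a serum protein signature.

    Default: the same single-sample enrichment machinery applied to the
    (detection-filtered) NPX matrix with the signature as the set. A
    simpler ``method='mean_z'`` alternative averages per-protein z-scores
    (NPX standardized across samples) over the signature.

    Missing NPX values are below-LOD censored measurements; for the
    rank-based score they are placed at the bottom of the protein's
    ranking by filling with the protein's observed minimum. Proteins with
    no observed value at all are dropped.
    """
    if method == "mean_z":
        vals = npx_wide.to_numpy(float)
        mu = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
        z = (vals - mu) / sd
        mask = npx_wide.index.isin(signature.members)
        out = pd.Series(np.nanmean(z[mask], axis=0), index=npx_wide.columns)
    elif method == "gsva":
        filled = npx_wide.dropna(axis=0, how="all")
        filled = filled.apply(lambda row: row.fillna(row.min()), axis=1)
        scores = score_sets(filled, [signature], params)
        out = scores[signature.name]
    else:
        raise ValueError(f"unknown method {method!r}")
    out.name = signature.name
    return out
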