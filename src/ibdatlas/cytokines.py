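"""Cytokine signaling activity inference from expression profiles.

Bulk route: a differential expression profile y (log2(TPM+1) of a case
group minus a reference group, mean-centered) is regressed on a gene x
cytokine response-signature matrix S by ridge regression,
``beta = (S'S + alpha I)^-1 S' y``. Each cytokine's z-score is its
coefficient divided by a standard error estimated from the spread of
coefficients under random permutations of the gene labels of y; two-sided
permutation p-values use the add-one correction. With zero permutations
the classical linear-model t formulation supplies SE and p instead.

Single-cell route: per-cell weighted-mean activity over a (cytokine, gene,
weight) network, normalized against a gene-label permutation null.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteomics import bh_adjust

__all__ = [
    "prepare_profile",
    "ridge_fit",
    "permutation_z",
    "group_activity",
    "wmean_activity",
    "significance_stars",
]


def prepare_profile(
    tpm_case: pd.Series | pd.DataFrame, tpm_reference: pd.Series | pd.DataFrame
) -> pd.Series:
    """Differential profile y = log2(TPM+1)_case - log2(TPM+1)_reference.

    Multi-sample inputs are averaged (in log space) within each side first;
    the result is restricted to shared genes and mean-centered.
    """

    def _collapse(x):
        lx = np.log2(np.asarray(x, float) + 1.0)
        if isinstance(x, pd.DataFrame):
            return pd.Series(lx.mean(axis=1), index=x.index)
        return pd.Series(lx, index=x.index)

    a, b = _collapse(tpm_case), _collapse(tpm_reference)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("case and reference share no genes")
    y = a[shared] - b[shared]
    return y - y.mean()


def _center_columns(S: np.ndarray) -> np.ndarray:
    return S - S.mean(axis=0, keepdims=True)


def ridge_fit(S: pd.DataFrame, y: pd.Series, alpha: float = 1e4) -> pd.Series:
    """Ridge solution beta = (S'S + alpha I)^-1 S' y on intersected genes.

    Columns of S and y are mean-centered before fitting. At alpha = 0 a
    rank-deficient S raises with a hint to use alpha > 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = S.index.intersection(y.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between response matrix and profile")
    Sm = _center_columns(S.loc[genes].to_numpy(float))
    yv = y[genes].to_numpy(float)
    yv = yv - yv.mean()
    G = Sm.T @ Sm + alpha * np.eye(Sm.shape[1])
    if alpha == 0 and np.linalg.matrix_rank(Sm) < Sm.shape[1]:
        raise np.linalg.LinAlgError(
            "response matrix is rank-deficient at alpha=0; use alpha > 0"
        )
    beta = np.linalg.solve(G, Sm.T @ yv)
    return pd.Series(beta, index=S.columns, name="beta")


def permutation_z(
    S: pd.DataFrame,
    y: pd.Series,
    alpha: float = 1e4,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ridge coefficients with permutation-based z-scores and p-values.

    SE per cytokine is the standard deviation of its coefficient over
    ``n_perm`` random permutations of y's gene labels; z = beta/SE and the
    two-sided p is (1 + #{|beta_perm| >= |beta|}) / (1 + n_perm). With
    n_perm = 0 the classical linear-model t statistic for the (ridge)
    estimator is used instead. BH-adjusted p across cytokines included.
    """
    if n_perm > 0 and seed is None:
        raise ValueError("seed is mandatory when n_perm > 0")
    genes = S.index.intersection(y.index)
    Sm = _center_columns(S.loc[genes].to_numpy(float))
    yv = y[genes].to_numpy(float)
    yv = yv - yv.mean()
    n, k = Sm.shape
    G = Sm.T @ Sm + alpha * np.eye(k)
    M = np.linalg.solve(G, Sm.T)  # k x n projection
    beta = M @ yv

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(yv) for _ in range(n_perm)], axis=1)  # n x P
        beta_perm = M @ perms  # k x P
        se = beta_perm.std(axis=1, ddof=1)
        exceed = (np.abs(beta_perm) >= np.abs(beta)[:, None]).sum(axis=1)
        p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        resid = yv - Sm @ beta
        dof = max(n - k, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * (M @ M.T)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.nan))
    degenerate = (se <= 0) & (beta != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cytokine(s) with degenerate permutation SE; "
            "z reported as missing",
            stacklevel=2,
        )
        p = np.where(degenerate, np.nan, p)
    ok = ~np.isnan(p)
    adj = np.full(k, np.nan)
    adj[ok] = bh_adjust(p[ok])
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "adj_p": adj,
            "n_perm": n_perm,
        },
        index=S.columns,
    )


def significance_stars(adj_p: float) -> str:
    """FDR tiers: *** < 0.01, ** < 0.05, * < 0.1."""
    if np.isnan(adj_p):
        return ""
    if adj_p < 0.01:
        return "***"
    if adj_p < 0.05:
        return "**"
    if adj_p < 0.1:
        return "*"
    return ""


def group_activity(
    tpm: pd.DataFrame,
    groups: dict[str, Sequence[str]],
    references: dict[str, str],
    S: pd.DataFrame,
    alpha: float = 1e4,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cytokine activity per sample group against its designated reference.

    ``groups`` maps group name -> sample ids (columns of ``tpm``);
    ``references`` maps each case group to its reference group (typically
    non-IBD of the matching tissue). Groups without a reference are
    skipped with a warning. Returns a long table (group, cytokine, beta,
    z, p, adj_p, stars) with FDR star tiers at 0.1/0.05/0.01.
    """
    out = []
    for gi, (gname, samples) in enumerate(groups.items()):
        ref = references.get(gname)
        if ref is None:
            warnings.warn(f"group {gname} has no reference; skipped", stacklevel=2)
            continue
        y = prepare_profile(tpm[list(samples)], tpm[list(groups[ref])])
        res = permutation_z(
            S, y, alpha=alpha, n_perm=n_perm, seed=None if seed is None else seed + gi
        )
        res = res.reset_index(names="cytokine")
        res.insert(0, "group", gname)
        res["stars"] = res["adj_p"].map(significance_stars)
        out.append(res)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def wmean_activity(
    X: pd.DataFrame,
    network: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Normalized weighted-mean activity per cell (rows) and cytokine.

    ``X`` is cells x genes; ``network`` has columns (cytokine, gene,
    weight). Raw score per cell = sum_g w_g x_g / sum_g |w_g| over the
    cytokine's genes present in X; the normalized score subtracts the mean
    and divides by the sd of raw scores under ``n_perm`` permutations of
    the weight-to-gene assignment. Cytokines with fewer than ``min_genes``
    genes present are skipped.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    vals = X.to_numpy(float)
    gene_pos = {g: i for i, g in enumerate(X.columns)}
    out = {}
    for cyt, sub in network.groupby("source" if "source" in network else "cytokine"):
        present = sub[sub["gene"].isin(gene_pos)]
        if len(present) < min_genes:
            continue
        idx = np.array([gene_pos[g] for g in present["gene"]])
        w = present["weight"].to_numpy(float)
        denom = np.abs(w).sum()
        raw = vals[:, idx] @ w / denom
        perm_raw = np.empty((len(vals), n_perm))
        n_genes = vals.shape[1]
        for p in range(n_perm):
            ridx = rng.choice(n_genes, size=len(idx), replace=False)
            perm_raw[:, p] = vals[:, ridx] @ w / denom
        mu = perm_raw.mean(axis=1)
        sd = perm_raw.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[cyt] = np.where(sd > 0, (raw - mu) / sd, 0.0)
    return pd.DataFrame(out, index=X.index)
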