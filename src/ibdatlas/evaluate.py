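"""Cross-modality evaluation: pairwise-complete Pearson correlation,
differential-expression threshold filtering, set-overlap summaries, and
hypergeometric over-representation analysis with fold enrichment."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteomics import bh_adjust, signature_overlap

__all__ = [
    "pearson_pairwise",
    "correlation_matrix",
    "correlation_stars",
    "de_filter",
    "set_overlap_counts",
    "ora",
]

set_overlap_counts = signature_overlap  # same Venn-partition computation


def correlation_stars(p: float) -> str:
    """Raw-p tiers: *** < 0.001, ** < 0.01, * < 0.05 (strict)."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_pairwise(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson correlation on pairwise-complete observations.

    Drops any pair with a missing value on either side; needs >= 3
    complete pairs for a defined R and p (two-sided, t transform).
    Returns {'r', 'p', 'n', 'defined'}.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return {"r": np.nan, "p": np.nan, "n": n, "defined": False}
    r, p = stats.pearsonr(x[ok], y[ok])
    return {"r": float(r), "p": float(p), "n": n, "defined": True}


def correlation_matrix(scores: pd.DataFrame, adjust: bool = False) -> dict:
    """All-pairs pairwise-complete Pearson correlation of a score table.

    ``scores`` is samples x named scores (missing allowed). Returns a dict
    with symmetric DataFrames 'r', 'p', 'n', 'stars' (diagonal R = 1);
    star tiers use raw p by default, or BH-adjusted p across the upper
    triangle with ``adjust=True``.
    """
    names = list(scores.columns)
    if len(names) < 2:
        raise ValueError("need at least two scores")
    if len(set(names)) != len(names):
        raise ValueError("score names must be unique")
    k = len(names)
    R = np.eye(k)
    P = np.full((k, k), np.nan)
    N = np.zeros((k, k), int)
    pairs = []
    for i in range(k):
        N[i, i] = scores[names[i]].notna().sum()
        for j in range(i + 1, k):
            res = pearson_pairwise(scores[names[i]], scores[names[j]])
            R[i, j] = R[j, i] = res["r"]
            P[i, j] = P[j, i] = res["p"]
            N[i, j] = N[j, i] = res["n"]
            pairs.append((i, j))
    ptier = P.copy()
    if adjust:
        upper = np.array([P[i, j] for i, j in pairs])
        ok = ~np.isnan(upper)
        adj = np.full(len(upper), np.nan)
        adj[ok] = bh_adjust(upper[ok])
        for (i, j), q in zip(pairs, adj):
            ptier[i, j] = ptier[j, i] = q
    stars = pd.DataFrame(
        [[correlation_stars(ptier[i, j]) if i != j else "" for j in range(k)] for i in range(k)],
        index=names,
        columns=names,
    )
    return {
        "r": pd.DataFrame(R, index=names, columns=names),
        "p": pd.DataFrame(P, index=names, columns=names),
        "n": pd.DataFrame(N, index=names, columns=names),
        "stars": stars,
    }


def de_filter(
    de_table: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> tuple[set, set]:
    """Split a differential-expression table into up/down significant sets.

    up = {adjusted p < alpha and log2FC > lfc_threshold}, down likewise
    with log2FC < -lfc_threshold; all inequalities strict. The table needs
    'log2FoldChange' and 'padj' columns and its index holds gene ids.
    """
    for col in ("log2FoldChange", "padj"):
        if col not in de_table.columns:
            raise KeyError(f"de_filter needs a {col!r} column")
    sig = de_table["padj"] < alpha
    up = set(de_table.index[sig & (de_table["log2FoldChange"] > lfc_threshold)])
    down = set(de_table.index[sig & (de_table["log2FoldChange"] < -lfc_threshold)])
    return up, down


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Over-representation analysis with hypergeometric upper-tail p.

    For each term with K annotated features in a universe of N, a query of
    size m overlapping the term in k features gets
    fold enrichment = (k/m) / (K/N) and p = P(X >= k) for
    X ~ Hypergeom(N, K, m); BH correction across terms. Annotated sets are
    intersected with the universe; the query must be a subset of it.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, m = len(universe), len(query)
    rows = []
    for term in sorted(annotations):
        ann = set(annotations[term]) & universe
        K = len(ann)
        k = len(ann & query)
        fe = (k / m) / (K / N) if m > 0 and K > 0 else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, m)) if K > 0 else 1.0
        rows.append({"term": term, "N": N, "K": K, "m": m, "k": k, "fold_enrichment": fe, "p": p})
    out = pd.DataFrame(rows).set_index("term")
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out
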