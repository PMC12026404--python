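"""Serum NPX differential abundance and inflammatory protein severity signatures.

Olink NPX values are log2-scale arbitrary abundance units, so a difference
in mean NPX between groups is a log2 fold change. The workflow here is: keep
proteins detected in at least 90% of samples, compare inflamed against
non-inflamed samples per protein with a Welch two-sample t-test, correct
with Benjamini-Hochberg, and collect the significantly *upregulated*
proteins into an inflammatory protein severity signature (IPSS) — computed
over all IBD samples or restricted to one entity (UC-IPSS, CD-IPSS).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "detection_filter",
    "welch_test",
    "bh_adjust",
    "SignatureSet",
    "derive_ipss",
    "signature_overlap",
    "write_gmt",
    "read_gmt",
]


def detection_filter(
    npx_long: pd.DataFrame, min_frac: float = 0.90
) -> pd.DataFrame:
    """Keep proteins detected in at least ``min_frac`` of the measured samples.

    "Detected" means not below-LOD and not missing. Operates on the long
    NPX format (sample_id, protein, npx, below_lod); protein order is
    preserved. The boundary is inclusive: detected fraction == min_frac
    is retained.
    """
    if not (0 <= min_frac <= 1):
        raise ValueError("min_frac must be in [0, 1]")
    detected = (~npx_long["below_lod"]) & npx_long["npx"].notna()
    frac = detected.groupby(npx_long["protein"], sort=False).mean()
    keep = frac.index[frac > 0] if min_frac == 0 else frac.index[frac >= min_frac]
    out = npx_long[npx_long["protein"].isin(set(keep))]
    if out.empty:
        warnings.warn("detection filter removed every protein", stacklevel=2)
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_test(
    npx_wide: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-protein Welch two-sample t-test between two sample groups.

    ``npx_wide`` is proteins x samples with NaN for missing values;
    missing values are dropped per protein (complete observations, no
    imputation). estimate = mean(group A) - mean(group B), with the
    Welch-Satterthwaite degrees of freedom and a two-sided p. Proteins
    with fewer than ``min_per_group`` observations in either group are
    flagged untestable (NaN statistics) and excluded from the BH family.
    """
    A = npx_wide[list(group_a)].to_numpy(float)
    B = npx_wide[list(group_b)].to_numpy(float)
    nA = np.sum(~np.isnan(A), axis=1)
    nB = np.sum(~np.isnan(B), axis=1)
    testable = (nA >= min_per_group) & (nB >= min_per_group)

    est = np.full(len(npx_wide), np.nan)
    t = np.full(len(npx_wide), np.nan)
    df = np.full(len(npx_wide), np.nan)
    p = np.full(len(npx_wide), np.nan)
    if testable.any():
        res = stats.ttest_ind(
            A[testable], B[testable], axis=1, equal_var=False, nan_policy="omit"
        )
        est[testable] = np.nanmean(A[testable], axis=1) - np.nanmean(B[testable], axis=1)
        t[testable] = res.statistic
        df[testable] = res.df
        p[testable] = res.pvalue

    adj = np.full(len(npx_wide), np.nan)
    adj[testable] = bh_adjust(p[testable])
    return pd.DataFrame(
        {
            "protein": npx_wide.index,
            "estimate": est,
            "t": t,
            "df": df,
            "p": p,
            "adj_p": adj,
            "n_a": nA,
            "n_b": nB,
            "testable": testable,
        }
    ).set_index("protein")


@dataclasses.dataclass
class SignatureSet:
    """An ordered protein (or gene) set with derivation metadata."""

    name: str
    members: list[str]
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"signature {self.name} contains duplicates")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def derive_ipss(
    da: pd.DataFrame,
    name: str = "IBD-IPSS",
    fdr_threshold: float = 0.05,
    direction: str = "up",
) -> SignatureSet:
    """Collect significantly regulated proteins into a severity signature.

    Inclusion: BH-adjusted p strictly below ``fdr_threshold`` and estimate
    > 0 for direction "up" (< 0 for "down"). ``da`` is the output of
    :func:`welch_test` on the inflamed-vs-non-inflamed contrast.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sig = da["adj_p"] < fdr_threshold
    sig &= da["estimate"] > 0 if direction == "up" else da["estimate"] < 0
    members = list(da.index[sig.fillna(False)])
    if not members:
        warnings.warn(f"signature {name} is empty at FDR < {fdr_threshold}", stacklevel=2)
    return SignatureSet(
        name,
        members,
        meta={"fdr_threshold": fdr_threshold, "direction": direction},
    )


def signature_overlap(sets: Sequence[SignatureSet | Iterable[str]]) -> dict:
    """Exact Venn region counts for two or more signatures.

    Returns a dict keyed by membership pattern — e.g. for three sets the
    key (True, False, True) counts elements in sets 1 and 3 but not 2 —
    in deterministic (lexicographic) key order, plus the full
    intersection under key 'common'.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    as_sets = [set(s.members if isinstance(s, SignatureSet) else s) for s in sets]
    universe = set().union(*as_sets)
    counts: dict = {}
    for pattern in itertools.product([False, True], repeat=len(as_sets)):
        region = universe.copy()
        for s, inside in zip(as_sets, pattern):
            region = region & s if inside else region - s
        counts[pattern] = len(region)
    counts["common"] = sorted(set.intersection(*as_sets))
    return counts


def write_gmt(sets: Sequence[SignatureSet], path: str | Path) -> None:
    """Write signatures in GMT format (name, description, members...)."""
    with open(path, "w") as fh:
        for s in sets:
            desc = ";".join(f"{k}={v}" for k, v in s.meta.items()) or "na"
            fh.write("\t".join([s.name, desc, *s.members]) + "\n")


def read_gmt(path: str | Path) -> list[SignatureSet]:
    """Read a GMT file into SignatureSets (description kept as metadata)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, desc, *members = line.split("\t")
            out.append(SignatureSet(name, members, meta={"description": desc}))
    return out
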