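"""Cohort data model: tissue grouping, histopathology score normalization,
tissue/date sample matching and inflammation-status labeling.

Histologic disease activity in IBD is scored with system-specific scales
(modified Naini Cortina for Crohn's disease, modified Riley for ulcerative
colitis) whose maximum attainable score depends on the tissue group
(colon-like vs ileum-like) and on the sampling method (biopsy vs resection,
resected tissue adding sub-scores for submucosal/transmural involvement).
Scores are made comparable across systems by dividing each raw score by the
maximum of its own (system, tissue group, method) cell, yielding a value on
a 0-1 scale.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "COLON_GROUP",
    "ILEUM_GROUP",
    "DEFAULT_NORMALIZATION",
    "NormalizationTable",
    "tissue_grouping",
    "max_score",
    "normalize_histo",
    "inflammation_status",
    "label_inflammation",
    "AtlasStore",
    "assemble_atlas",
    "IntegrityError",
]

COLON_GROUP = "colon_group"
ILEUM_GROUP = "ileum_group"

_TISSUE_TO_GROUP = {
    "colon": COLON_GROUP,
    "rectum": COLON_GROUP,
    "caecum": COLON_GROUP,
    "ileum": ILEUM_GROUP,
    "ileocecal valve": ILEUM_GROUP,
    "small intestine": ILEUM_GROUP,
    "anastomosis": ILEUM_GROUP,
    "pouch": ILEUM_GROUP,
}

SYSTEMS = ("NainiCortina", "Riley")
METHODS = ("biopsy", "resection")


def tissue_grouping(tissue: str) -> str:
    """Map a fine tissue label onto its coarse scoring group.

    colon/rectum/caecum form the colon group; ileum, ileocecal valve,
    small intestine, anastomosis and pouch form the ileum group.
    """
    try:
        return _TISSUE_TO_GROUP[tissue]
    except KeyError:
        raise ValueError(
            f"unknown tissue {tissue!r}; allowed: {sorted(_TISSUE_TO_GROUP)}"
        ) from None


@dataclasses.dataclass(frozen=True)
class NormalizationTable:
    """Maximum histopathology score per (system, tissue_group, method).

    The default grid holds the published maxima of the modified Naini
    Cortina and modified Riley scores for colon-group and ileum-group
    tissue, separately for biopsies and resections.
    """

    maxima: Mapping[tuple[str, str, str], int]

    def __post_init__(self) -> None:
        for key, v in self.maxima.items():
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"maximum for {key} must be a positive integer, got {v!r}")
        missing = [
            (s, g, m)
            for s in SYSTEMS
            for g in (COLON_GROUP, ILEUM_GROUP)
            for m in METHODS
            if (s, g, m) not in self.maxima
        ]
        if missing:
            raise ValueError(f"normalization table incomplete; missing cells: {missing}")

    def __getitem__(self, key: tuple[str, str, str]) -> int:
        return self.maxima[key]


DEFAULT_NORMALIZATION = NormalizationTable(
    {
        ("NainiCortina", COLON_GROUP, "resection"): 20,
        ("NainiCortina", COLON_GROUP, "biopsy"): 16,
        ("NainiCortina", ILEUM_GROUP, "resection"): 14,
        ("NainiCortina", ILEUM_GROUP, "biopsy"): 10,
        ("Riley", COLON_GROUP, "resection"): 21,
        ("Riley", COLON_GROUP, "biopsy"): 17,
        ("Riley", ILEUM_GROUP, "resection"): 16,
        ("Riley", ILEUM_GROUP, "biopsy"): 12,
    }
)


def max_score(
    system: str,
    tissue_group: str,
    method: str,
    table: NormalizationTable = DEFAULT_NORMALIZATION,
) -> int:
    """Tabulated maximum raw score for a scoring context."""
    try:
        return table[(system, tissue_group, method)]
    except KeyError:
        raise KeyError(
            f"no maximum tabulated for system={system!r}, "
            f"tissue_group={tissue_group!r}, method={method!r}"
        ) from None


def normalize_histo(
    raw: int,
    system: str,
    tissue_group: str,
    method: str,
    table: NormalizationTable = DEFAULT_NORMALIZATION,
) -> float:
    """Normalize a raw histopathology score to [0, 1].

    Divides by the context-specific maximum; raw scores outside
    [0, max] are rejected rather than clipped, since they signal
    upstream scoring errors.
    """
    if raw < 0:
        raise ValueError(f"raw score must be non-negative, got {raw}")
    m = max_score(system, tissue_group, method, table)
    if raw > m:
        raise ValueError(
            f"raw score {raw} exceeds maximum {m} for "
            f"({system}, {tissue_group}, {method})"
        )
    return raw / m


def inflammation_status(
    patient_id: str,
    tissue_group: str,
    date,
    histo: pd.DataFrame,
    window_days: int = 0,
) -> str:
    """Label a sample inflamed / non_inflamed / unknown by histology matching.

    A sample is *inflamed* if any histopathology record of the same patient
    and tissue group within ``window_days`` of the sample date has raw
    score > 0; *non_inflamed* if matching records exist and all have raw
    score 0; *unknown* if no record matches.

    ``histo`` needs columns patient_id, tissue_group, date, raw.
    """
    sub = histo[(histo["patient_id"] == patient_id) & (histo["tissue_group"] == tissue_group)]
    if len(sub) == 0:
        return "unknown"
    dd = (pd.to_datetime(sub["date"]) - pd.to_datetime(date)).abs()
    sub = sub[dd <= pd.Timedelta(days=window_days)]
    if len(sub) == 0:
        return "unknown"
    return "inflamed" if (sub["raw"] > 0).any() else "non_inflamed"


def label_inflammation(
    samples: pd.DataFrame, histo: pd.DataFrame, window_days: int = 0
) -> pd.Series:
    """Vectorised :func:`inflammation_status` over a sample table.

    ``samples`` needs patient_id, tissue_group, date columns; returns a
    Series of status labels aligned to ``samples.index``.
    """
    out = []
    for _, row in samples.iterrows():
        out.append(
            inflammation_status(
                row["patient_id"], row["tissue_group"], row["date"], histo, window_days
            )
        )
    return pd.Series(out, index=samples.index, name="inflammation_status")


class IntegrityError(RuntimeError):
    """Raised when a bundle violates referential or range constraints."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            f"{len(violations)} integrity violation(s):\n" + "\n".join(violations)
        )


@dataclasses.dataclass
class AtlasStore:
    """Joined, referentially-consistent cohort store.

    Tables: patients, samples, histo, clinical; wide matrices (NPX,
    counts, TPM) stay in their own files and are validated against the
    sample table by id.
    """

    patients: pd.DataFrame
    samples: pd.DataFrame
    histo: pd.DataFrame
    clinical: pd.DataFrame

    def export(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.tsv", sep="\t", index=False)
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        self.histo.to_csv(out / "histo.tsv", sep="\t", index=False)
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)


def _check_integrity(
    patients: pd.DataFrame,
    samples: pd.DataFrame,
    histo: pd.DataFrame,
    clinical: pd.DataFrame,
    table: NormalizationTable,
) -> list[str]:
    v: list[str] = []
    pid = set(patients["patient_id"])
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        v.append(f"patients: duplicate patient_id {dup}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        v.append(f"samples: duplicate sample_id {dup}")
    for i, row in samples.iterrows():
        if row["patient_id"] not in pid:
            v.append(f"samples row {i}: orphan patient_id {row['patient_id']!r}")
        expected = _TISSUE_TO_GROUP.get(row["tissue"])
        if expected is None:
            v.append(f"samples row {i}: unknown tissue {row['tissue']!r}")
        elif row["tissue_group"] != expected:
            v.append(
                f"samples row {i}: tissue_group {row['tissue_group']!r} "
                f"inconsistent with tissue {row['tissue']!r}"
            )
    sid = set(samples["sample_id"])
    for name, tab in (("histo", histo), ("clinical", clinical)):
        for i, row in tab.iterrows():
            if row["sample_id"] not in sid:
                v.append(f"{name} row {i}: orphan sample_id {row['sample_id']!r}")
    for i, row in histo.iterrows():
        key = (row["system"], row["tissue_group"], row["method"])
        try:
            m = table[key]
        except KeyError:
            v.append(f"histo row {i}: unknown scoring context {key}")
            continue
        if not (0 <= row["raw"] <= m):
            v.append(
                f"histo row {i}: raw score {row['raw']} out of range [0, {m}] for {key}"
            )
    return v


def assemble_atlas(
    bundle_dir: str | Path,
    table: NormalizationTable = DEFAULT_NORMALIZATION,
    strict: bool = True,
) -> AtlasStore:
    """Load a tabular cohort bundle, validate it, and return the joined store.

    Checks foreign keys (every sample's patient exists; every histo and
    clinical record's sample exists), key uniqueness, tissue-group
    consistency, and raw-score ranges against the normalization table.
    With ``strict`` (default) any violation raises :class:`IntegrityError`
    listing every offending row; otherwise violations are attached to the
    returned store as ``store.violations``.
    """
    d = Path(bundle_dir)
    patients = pd.read_csv(d / "patients.tsv", sep="\t")
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    histo = pd.read_csv(d / "histo.tsv", sep="\t")
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t")
    violations = _check_integrity(patients, samples, histo, clinical, table)
    store = AtlasStore(patients, samples, histo, clinical)
    if violations and strict:
        raise IntegrityError(violations)
    store.violations = violations  # type: ignore[attr-defined]
    return store
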