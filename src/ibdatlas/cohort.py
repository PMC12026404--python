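"""Synthetic multi-center IBD cohort generator.

Every simulated modality — histopathology scores, serum proteomics (NPX),
bulk RNA expression, per-slide tile-feature bags, and clinical/endoscopic
indices — is driven by a shared latent inflammation severity in [0, 1]
defined per (visit, tissue context). This makes every downstream stage of
the analysis testable for signal recovery and null calibration without any
external data: planted effects are recorded in ground-truth tables, and
setting every effect size to zero yields a calibrated null cohort.

Severity model: non-IBD patients have severity exactly 0. IBD patients are
in histologic remission (severity 0) with probability ``remission_prob``,
otherwise severity ~ Beta(2, 2) — a symmetric, mid-weighted distribution
covering the whole activity range.

Reproducibility: the master seed is split into one independent RNG stream
per modality via ``numpy.random.SeedSequence.spawn``, so changing one
modality's parameters never perturbs another's draws.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import (
    DEFAULT_NORMALIZATION,
    NormalizationTable,
    max_score,
    normalize_histo,
    tissue_grouping,
)

__all__ = [
    "CohortConfig",
    "LatentCohort",
    "Bag",
    "largest_remainder",
    "generate_cohort",
    "simulate_histo",
    "simulate_npx",
    "simulate_expression",
    "simulate_bags",
    "simulate_clinical",
    "simulate_all",
    "SimBundle",
    "npx_wide",
    "write_bundle",
]

_MODALITIES = ("cohort", "histo", "npx", "expr", "bags", "clinical")

# clinical/endoscopic index ranges: (min, max, applicable disease)
CLINICAL_INDEX_RANGES = {
    "UCEIS": (0, 8, "UC"),
    "PMS": (0, 9, "UC"),
    "SES-CD": (0, 56, "CD"),
    "HBI": (0, 16, "CD"),
    "Bristol": (1, 7, None),
}


@dataclasses.dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; effect sizes are the study conditions.

    npx_delta is in NPX units (log2 scale) per unit severity; gene_log2fc in
    log2-fold-change units per unit severity; lesion_shift is the Euclidean
    displacement of lesion tiles in feature space.
    """

    seed: int
    n_patients: int = 200
    disease_mix: dict = dataclasses.field(
        default_factory=lambda: {"CD": 0.4, "UC": 0.4, "nonIBD": 0.2}
    )
    center_mix: dict = dataclasses.field(default_factory=lambda: {"A": 0.6, "B": 0.4})
    remission_prob: float = 0.35
    # serum proteomics
    n_proteins: int = 200
    n_planted_proteins: int = 20
    npx_delta: float = 1.0
    npx_noise_sd: float = 0.5
    lod_quantile: float = 0.05
    # bulk expression
    n_genes: int = 2000
    n_planted_genes: int = 100
    gene_log2fc: float = 2.0
    expr_dispersion: float = 0.1
    n_cytokines: int = 8
    n_planted_cytokines: int = 3
    cyto_activity_scale: float = 1.0
    # tile-feature bags
    feature_dim: int = 64
    tiles_per_bag: tuple[int, int] = (30, 80)
    lesion_shift: float = 2.0
    bag_noise_sd: float = 1.0
    # histo / clinical
    resection_frac: float = 0.2
    clinical_noise_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, mix in (("disease_mix", self.disease_mix), ("center_mix", self.center_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, expected 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has negative proportions")
        for name in (
            "n_patients", "n_proteins", "n_genes", "feature_dim", "n_cytokines",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not set(self.disease_mix) <= {"CD", "UC", "nonIBD"}:
            raise ValueError("disease_mix keys must be within {CD, UC, nonIBD}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if seed is not None:
            raw["seed"] = seed
        if "tiles_per_bag" in raw:
            raw["tiles_per_bag"] = tuple(raw["tiles_per_bag"])
        return cls(**raw)


@dataclasses.dataclass
class LatentCohort:
    """Patients, visits and tissue contexts with the hidden severity."""

    config: CohortConfig
    patients: pd.DataFrame  # patient_id, disease, sex, age, center
    visits: pd.DataFrame  # visit_id, patient_id, date
    contexts: pd.DataFrame  # context_id, visit_id, patient_id, tissue, tissue_group, method, date, severity
    rngs: dict = dataclasses.field(repr=False, default_factory=dict)
    truth: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class Bag:
    """A slide represented as tile features plus its normalized target score."""

    slide_id: str
    features: np.ndarray  # (n_tiles, d)
    target: float
    lesion: np.ndarray | None = None  # boolean per tile (ground truth)

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("bag needs a (n_tiles >= 1, d) feature matrix")
        if not (0.0 <= self.target <= 1.0):
            raise ValueError(f"target {self.target} outside [0, 1]")


def largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Deterministic apportionment of ``total`` items over proportions.

    Hamilton / largest-remainder rule: floor the quotas, then hand the
    leftover items to the largest fractional remainders (ties broken by
    position, so the result is order-stable).
    """
    quotas = [p * total for p in proportions]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = total - sum(counts)
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:leftover]:
        counts[i] += 1
    return counts


def _spawn_rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_MODALITIES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_MODALITIES, children)}


def generate_cohort(config: CohortConfig) -> LatentCohort:
    """Draw the latent cohort: patients, one visit each, one tissue context.

    Disease and center labels are assigned by largest-remainder
    apportionment (exact, reproducible counts) and then shuffled by the
    cohort RNG stream. Tissue: CD splits between ileum and colon, UC
    between colon and rectum, non-IBD gets colon.
    """
    rngs = _spawn_rngs(config.seed)
    rng = rngs["cohort"]
    n = config.n_patients

    diseases = []
    for d, k in zip(config.disease_mix, largest_remainder(list(config.disease_mix.values()), n)):
        diseases += [d] * k
    centers = []
    for c, k in zip(config.center_mix, largest_remainder(list(config.center_mix.values()), n)):
        centers += [c] * k
    rng.shuffle(diseases)
    rng.shuffle(centers)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "disease": diseases,
            "sex": rng.choice(["F", "M"], size=n),
            "age": rng.integers(18, 80, size=n),
            "center": centers,
        }
    )

    base = pd.Timestamp("2021-01-01")
    dates = [base + pd.Timedelta(days=int(d)) for d in rng.integers(0, 1000, size=n)]
    visits = pd.DataFrame(
        {
            "visit_id": [f"V{i:04d}" for i in range(n)],
            "patient_id": patients["patient_id"],
            "date": dates,
        }
    )

    tissues = []
    for d in diseases:
        if d == "CD":
            tissues.append(rng.choice(["ileum", "colon"]))
        elif d == "UC":
            tissues.append(rng.choice(["colon", "rectum"]))
        else:
            tissues.append("colon")
    methods = np.where(rng.random(n) < config.resection_frac, "resection", "biopsy")

    severity = np.zeros(n)
    is_ibd = np.array([d != "nonIBD" for d in diseases])
    active = is_ibd & (rng.random(n) >= config.remission_prob)
    severity[active] = rng.beta(2.0, 2.0, size=int(active.sum()))

    contexts = pd.DataFrame(
        {
            "context_id": [f"C{i:04d}" for i in range(n)],
            "visit_id": visits["visit_id"],
            "patient_id": patients["patient_id"],
            "tissue": tissues,
            "tissue_group": [tissue_grouping(t) for t in tissues],
            "method": methods,
            "date": dates,
            "severity": severity,
        }
    )
    return LatentCohort(config, patients, visits, contexts, rngs=rngs)


def simulate_histo(
    cohort: LatentCohort, table: NormalizationTable = DEFAULT_NORMALIZATION
) -> pd.DataFrame:
    """Draw raw histopathology scores as Binomial(max_score, severity).

    CD contexts are scored with the modified Naini Cortina system, UC with
    the modified Riley system; non-IBD contexts are scored with both (two
    records per context), as non-IBD controls carry no disease entity to
    select a system.
    """
    rng = cohort.rngs["histo"]
    disease = cohort.patients.set_index("patient_id")["disease"]
    rows = []
    for _, ctx in cohort.contexts.iterrows():
        d = disease[ctx["patient_id"]]
        systems = {"CD": ["NainiCortina"], "UC": ["Riley"]}.get(d, ["NainiCortina", "Riley"])
        for sys_name in systems:
            m = max_score(sys_name, ctx["tissue_group"], ctx["method"], table)
            raw = int(rng.binomial(m, ctx["severity"]))
            rows.append(
                {
                    "sample_id": f"H{ctx['context_id'][1:]}{'' if len(systems) == 1 else '_' + sys_name}",
                    "patient_id": ctx["patient_id"],
                    "context_id": ctx["context_id"],
                    "system": sys_name,
                    "tissue": ctx["tissue"],
                    "tissue_group": ctx["tissue_group"],
                    "method": ctx["method"],
                    "date": ctx["date"],
                    "raw": raw,
                    "normalized": normalize_histo(
                        raw, sys_name, ctx["tissue_group"], ctx["method"], table
                    ),
                }
            )
    return pd.DataFrame(rows)


def simulate_npx(cohort: LatentCohort) -> pd.DataFrame:
    """Simulate Olink-style serum proteomics in long NPX format.

    One serum draw per visit, dated like the visit. Protein baselines are
    Normal(mu_p, npx_noise_sd) with mu_p ~ Normal(5, 1); planted proteins
    gain npx_delta x severity (severity of the visit's tissue context —
    serum reflects systemic inflammation). Values below a per-protein
    detection limit (the ``lod_quantile`` of the null distribution) are
    flagged below-LOD and reported missing. Ground truth (planted protein
    ids, per-sample severity) is stored in ``cohort.truth``.
    """
    cfg = cohort.config
    rng = cohort.rngs["npx"]
    proteins = np.array([f"PROT{j:03d}" for j in range(cfg.n_proteins)])
    planted = proteins[rng.choice(cfg.n_proteins, size=cfg.n_planted_proteins, replace=False)]
    mu = rng.normal(5.0, 1.0, size=cfg.n_proteins)
    from scipy.stats import norm

    lod = mu + cfg.npx_noise_sd * norm.ppf(cfg.lod_quantile)

    sev = cohort.contexts.set_index("visit_id")["severity"]
    rows = []
    planted_set = set(planted)
    for _, visit in cohort.visits.iterrows():
        s = float(sev[visit["visit_id"]])
        vals = mu + rng.normal(0.0, cfg.npx_noise_sd, size=cfg.n_proteins)
        shift = np.array([cfg.npx_delta * s if p in planted_set else 0.0 for p in proteins])
        vals = vals + shift
        below = vals < lod
        sample_id = f"S{visit['visit_id'][1:]}"
        for p, v, b in zip(proteins, vals, below):
            rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": visit["patient_id"],
                    "date": visit["date"],
                    "protein": p,
                    "npx": np.nan if b else v,
                    "below_lod": bool(b),
                }
            )
    cohort.truth["planted_proteins"] = pd.DataFrame({"protein": planted})
    serum_sev = pd.DataFrame(
        {
            "sample_id": [f"S{v[1:]}" for v in cohort.visits["visit_id"]],
            "severity": [float(sev[v]) for v in cohort.visits["visit_id"]],
        }
    )
    cohort.truth["serum_severity"] = serum_sev
    return pd.DataFrame(rows)


def npx_wide(npx_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot long NPX records to a proteins x samples matrix (NaN = missing)."""
    return npx_long.pivot(index="protein", columns="sample_id", values="npx")


def simulate_expression(cohort: LatentCohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate bulk RNA-seq counts and TPM (genes x samples).

    Counts are negative-binomial around a log-normal per-gene baseline.
    Planted inflammation genes gain gene_log2fc x severity on the log2
    mean. A random gene x cytokine response matrix S is drawn; planted
    cytokines have activity cyto_activity_scale x severity per sample and
    shift the log2 means by S @ a, so that ridge activity inference has a
    recoverable ground truth. TPM is computed from counts and simulated
    gene lengths, columns summing to 1e6.
    """
    cfg = cohort.config
    rng = cohort.rngs["expr"]
    genes = np.array([f"GENE{j:04d}" for j in range(cfg.n_genes)])
    planted = rng.choice(cfg.n_genes, size=cfg.n_planted_genes, replace=False)
    lengths = rng.integers(500, 5000, size=cfg.n_genes).astype(float)
    log2_mu = rng.normal(4.0, 1.5, size=cfg.n_genes)

    cytokines = np.array([f"CYT{j}" for j in range(cfg.n_cytokines)])
    S = rng.normal(0.0, 0.5, size=(cfg.n_genes, cfg.n_cytokines))
    planted_cyt = rng.choice(cfg.n_cytokines, size=cfg.n_planted_cytokines, replace=False)

    sample_ids, counts_cols, activities = [], [], []
    for _, ctx in cohort.contexts.iterrows():
        s = ctx["severity"]
        a = np.zeros(cfg.n_cytokines)
        a[planted_cyt] = cfg.cyto_activity_scale * s
        lm = log2_mu.copy()
        lm[planted] += cfg.gene_log2fc * s
        lm = lm + S @ a
        mean = np.exp2(lm)
        r = 1.0 / cfg.expr_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
        sample_ids.append(f"R{ctx['context_id'][1:]}")
        counts_cols.append(counts)
        activities.append(a)

    counts_df = pd.DataFrame(
        np.column_stack(counts_cols), index=genes, columns=sample_ids
    )
    rate = counts_df.to_numpy(float) / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    tpm_df = pd.DataFrame(tpm, index=genes, columns=sample_ids)

    cohort.truth["planted_genes"] = pd.DataFrame({"gene": genes[planted]})
    cohort.truth["response_matrix"] = pd.DataFrame(S, index=genes, columns=cytokines)
    cohort.truth["cyto_activities"] = pd.DataFrame(
        np.array(activities), index=sample_ids, columns=cytokines
    )
    cohort.truth["gene_lengths"] = pd.DataFrame({"gene": genes, "length": lengths})
    rna_sev = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "severity": cohort.contexts["severity"].to_numpy(),
        }
    )
    cohort.truth["rna_severity"] = rna_sev
    return counts_df, tpm_df


def simulate_bags(
    cohort: LatentCohort,
    histo: pd.DataFrame | None = None,
    direction: np.ndarray | None = None,
) -> list[Bag]:
    """Simulate one tile-feature bag per tissue context (one slide per visit).

    Tiles are background Gaussian noise in d dimensions; each tile is a
    lesion tile with probability = severity and lesion tiles are displaced
    by ``lesion_shift`` along a fixed unit direction. The bag target is the
    context's normalized histopathology score (from ``histo`` if given,
    primary-system record), so the MIL regressor is trained against the
    same quantity the pathology model predicts. Pass ``direction`` to reuse
    another cohort's lesion direction (e.g. an external validation center
    sharing the same lesion phenotype); by default a fresh unit direction
    is drawn from the bags stream.
    """
    cfg = cohort.config
    rng = cohort.rngs["bags"]
    if direction is None:
        direction = rng.normal(size=cfg.feature_dim)
        direction = direction / np.linalg.norm(direction)
    else:
        direction = np.asarray(direction, float)
        if direction.shape != (cfg.feature_dim,):
            raise ValueError("direction must have length feature_dim")
    cohort.truth["lesion_direction"] = pd.DataFrame({"component": direction})

    if histo is None:
        histo = simulate_histo(cohort)
    primary = histo.drop_duplicates(subset="context_id", keep="first").set_index("context_id")

    bags = []
    lo, hi = cfg.tiles_per_bag
    for _, ctx in cohort.contexts.iterrows():
        n_tiles = int(rng.integers(lo, hi + 1))
        X = rng.normal(0.0, cfg.bag_noise_sd, size=(n_tiles, cfg.feature_dim))
        lesion = rng.random(n_tiles) < ctx["severity"]
        X[lesion] += cfg.lesion_shift * direction
        target = float(primary.loc[ctx["context_id"], "normalized"])
        bags.append(
            Bag(
                slide_id=f"W{ctx['context_id'][1:]}",
                features=X,
                target=target,
                lesion=lesion,
            )
        )
    return bags


def simulate_clinical(cohort: LatentCohort) -> pd.DataFrame:
    """Simulate clinical/endoscopic indices as noisy monotone maps of severity.

    Each index value is round(min + severity * (max - min) + noise) clipped
    to its range, with noise sd = clinical_noise_frac x range. UC indices
    (UCEIS, PMS) are emitted only for UC patients, CD indices (SES-CD, HBI)
    only for CD; the Bristol stool score for everyone.
    """
    cfg = cohort.config
    rng = cohort.rngs["clinical"]
    disease = cohort.patients.set_index("patient_id")["disease"]
    rows = []
    for _, ctx in cohort.contexts.iterrows():
        d = disease[ctx["patient_id"]]
        s = ctx["severity"]
        for index, (lo, hi, entity) in CLINICAL_INDEX_RANGES.items():
            if entity is not None and d != entity:
                continue
            span = hi - lo
            noise = rng.normal(0.0, cfg.clinical_noise_frac * span)
            val = int(np.clip(round(lo + s * span + noise), lo, hi))
            rows.append(
                {
                    "sample_id": f"K{ctx['context_id'][1:]}",
                    "patient_id": ctx["patient_id"],
                    "date": ctx["date"],
                    "index": index,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SimBundle:
    """All simulated modalities of one cohort, in memory."""

    cohort: LatentCohort
    histo: pd.DataFrame
    npx: pd.DataFrame
    counts: pd.DataFrame
    tpm: pd.DataFrame
    bags: list[Bag]
    clinical: pd.DataFrame


def simulate_all(config: CohortConfig) -> SimBundle:
    """Generate the cohort and every modality with one call."""
    cohort = generate_cohort(config)
    histo = simulate_histo(cohort)
    npx = simulate_npx(cohort)
    counts, tpm = simulate_expression(cohort)
    bags = simulate_bags(cohort, histo)
    clinical = simulate_clinical(cohort)
    return SimBundle(cohort, histo, npx, counts, tpm, bags, clinical)


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> None:
    """Persist a simulated cohort as the tabular bundle format.

    TSV tables for patients/samples/histo/clinical/npx, genes x samples
    count and TPM matrices, per-slide feature matrices (.npy, named by
    slide id) with a bags_index.tsv, and ground-truth tables under truth/.
    """
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    (out / "slides").mkdir(exist_ok=True)
    c = bundle.cohort
    c.patients.to_csv(out / "patients.tsv", sep="\t", index=False)

    samples = []
    for _, h in bundle.histo.iterrows():
        samples.append((h["sample_id"], h["patient_id"], "histo", h["tissue"], h["date"]))
    tissue_of = c.contexts.set_index("context_id")
    for sid in bundle.counts.columns:
        ctx = tissue_of.loc[f"C{sid[1:]}"]
        samples.append((sid, ctx["patient_id"], "rna", ctx["tissue"], ctx["date"]))
    for sid in bundle.npx["sample_id"].unique():
        visit = c.visits.set_index("visit_id").loc[f"V{sid[1:]}"]
        ctx = c.contexts.set_index("visit_id").loc[f"V{sid[1:]}"]
        samples.append((sid, visit["patient_id"], "serum", ctx["tissue"], visit["date"]))
    for bag in bundle.bags:
        ctx = tissue_of.loc[f"C{bag.slide_id[1:]}"]
        samples.append((bag.slide_id, ctx["patient_id"], "slide", ctx["tissue"], ctx["date"]))
    for sid in bundle.clinical["sample_id"].unique():
        ctx = tissue_of.loc[f"C{sid[1:]}"]
        samples.append((sid, ctx["patient_id"], "clinical", ctx["tissue"], ctx["date"]))
    samples_df = pd.DataFrame(
        samples, columns=["sample_id", "patient_id", "modality", "tissue", "date"]
    )
    samples_df["tissue_group"] = samples_df["tissue"].map(tissue_grouping)
    samples_df.to_csv(out / "samples.tsv", sep="\t", index=False)

    bundle.histo.to_csv(out / "histo.tsv", sep="\t", index=False)
    bundle.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    bundle.npx.to_csv(out / "npx.tsv", sep="\t", index=False)
    bundle.counts.to_csv(out / "counts.tsv", sep="\t")
    bundle.tpm.to_csv(out / "tpm.tsv", sep="\t")

    index_rows = []
    for bag in bundle.bags:
        path = out / "slides" / f"{bag.slide_id}.npy"
        np.save(path, bag.features)
        index_rows.append((bag.slide_id, f"slides/{bag.slide_id}.npy", bag.target))
    pd.DataFrame(index_rows, columns=["slide_id", "path", "target"]).to_csv(
        out / "bags_index.tsv", sep="\t", index=False
    )

    for name, table in bundle.cohort.truth.items():
        table.to_csv(out / "truth" / f"{name}.tsv", sep="\t", index=True)
    c.contexts.to_csv(out / "truth" / "contexts.tsv", sep="\t", index=False)
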