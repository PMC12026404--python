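"""End-to-end drivers tying the modalities together on one cohort.

These are the joins the analysis scripts, tests and the acceptance script
share: label serum samples by tissue/date-matched histology, derive the
severity signature, score every modality per patient visit, and build the
cross-modality score table whose pairwise correlations summarize how
coherently the different severity read-outs track each other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import atlas, cohort, cytokines, evaluate, gsva, mil, proteomics

__all__ = [
    "serum_sample_status",
    "derive_signature",
    "bmis_gene_set",
    "score_table",
]


def serum_sample_status(
    bundle: cohort.SimBundle, entity: str | None = None, window_days: int = 0
) -> pd.DataFrame:
    """Serum samples with their tissue/date-matched inflammation status.

    Serum reflects the visit; each serum sample is matched to histology of
    the same patient, the visit's tissue group, and the same date (within
    ``window_days``). ``entity`` restricts to one disease (UC or CD).
    """
    ctx = bundle.cohort.contexts.set_index("visit_id")
    disease = bundle.cohort.patients.set_index("patient_id")["disease"]
    samples = bundle.npx[["sample_id", "patient_id", "date"]].drop_duplicates().copy()
    samples["tissue_group"] = [
        ctx.loc[f"V{s[1:]}", "tissue_group"] for s in samples["sample_id"]
    ]
    samples["disease"] = samples["patient_id"].map(disease)
    if entity is not None:
        samples = samples[samples["disease"] == entity]
    samples = samples.reset_index(drop=True)
    samples["status"] = atlas.label_inflammation(samples, bundle.histo, window_days).values
    return samples


def derive_signature(
    bundle: cohort.SimBundle,
    entity: str | None = None,
    fdr_threshold: float = 0.05,
    min_detect_frac: float = 0.90,
) -> tuple[proteomics.SignatureSet, pd.DataFrame, pd.DataFrame]:
    """Inflamed-vs-non-inflamed NPX contrast and the resulting IPSS.

    Returns (signature, differential-abundance table, detection-filtered
    wide NPX matrix). The signature is named by entity (IBD-IPSS for the
    pooled cohort, UC-/CD-IPSS for entity-specific contrasts).
    """
    samples = serum_sample_status(bundle, entity)
    filtered = proteomics.detection_filter(bundle.npx, min_detect_frac)
    wide = cohort.npx_wide(filtered)
    inflamed = samples.loc[samples["status"] == "inflamed", "sample_id"]
    quiescent = samples.loc[samples["status"] == "non_inflamed", "sample_id"]
    da = proteomics.welch_test(wide, list(inflamed), list(quiescent))
    name = f"{entity or 'IBD'}-IPSS"
    sig = proteomics.derive_ipss(da, name=name, fdr_threshold=fdr_threshold)
    sig.meta.update({"contrast": "inflamed_vs_non_inflamed", "entity": entity or "IBD"})
    return sig, da, wide


def bmis_gene_set(bundle: cohort.SimBundle) -> proteomics.SignatureSet:
    """Synthetic stand-in for the biopsy inflammation up-signature.

    The published bMIS gene lists are external inputs; on synthetic
    cohorts the planted inflammation genes play their role.
    """
    return proteomics.SignatureSet(
        "bMIS-up-synthetic",
        list(bundle.cohort.truth["planted_genes"]["gene"]),
        meta={"source": "synthetic ground truth"},
    )


def score_table(
    bundle: cohort.SimBundle,
    signature: proteomics.SignatureSet | None = None,
    npx_wide: pd.DataFrame | None = None,
    mil_epochs: int = 10,
    mil_seed: int = 0,
    include_mil: bool = True,
) -> pd.DataFrame:
    """Per-visit table of every severity read-out, for cross-modality study.

    One row per tissue context: normalized histology (primary scoring
    system), IPSS (serum signature score), bMIS (expression inflammation
    score), out-of-fold MIL prediction from the tile bags, a pooled
    clinical activity column (HBI for CD, PMS for UC, each scaled to its
    own range — the entity-specific indices never overlap otherwise), and
    the Bristol stool score. Severity (latent truth) is attached for
    recovery checks but is not a score column consumers should correlate
    blindly.
    """
    if signature is None or npx_wide is None:
        signature, _, npx_wide = derive_signature(bundle)
    ctx_ids = list(bundle.cohort.contexts["context_id"])
    tab = pd.DataFrame(index=pd.Index(ctx_ids, name="context_id"))

    primary = bundle.histo.drop_duplicates(subset="context_id").set_index("context_id")
    tab["histo_norm"] = primary["normalized"]

    ipss = gsva.ipss_score(npx_wide, signature)
    tab["IPSS"] = [ipss.get(f"S{c[1:]}", np.nan) for c in ctx_ids]

    log_tpm = np.log2(bundle.tpm + 1.0)
    bset = bmis_gene_set(bundle)
    bm = gsva.bmis(log_tpm, bset)
    tab["bMIS"] = [bm.get(f"R{c[1:]}", np.nan) for c in ctx_ids]

    if include_mil:
        params = mil.AttMILParams(
            feature_dim=bundle.cohort.config.feature_dim,
            epochs=mil_epochs,
            seed=mil_seed,
        )
        cv = mil.cross_validate(bundle.bags, params)
        by_slide = dict(zip((b.slide_id for b in bundle.bags), cv["oof_predictions"]))
        tab["MIL_pred"] = [by_slide.get(f"W{c[1:]}", np.nan) for c in ctx_ids]

    clin = bundle.clinical.copy()
    ranges = cohort.CLINICAL_INDEX_RANGES
    pooled, bristol = {}, {}
    for _, row in clin.iterrows():
        cid = f"C{row['sample_id'][1:]}"
        lo, hi, entity = ranges[row["index"]]
        if row["index"] == "Bristol":
            bristol[cid] = row["value"]
        elif row["index"] in ("HBI", "PMS"):
            pooled[cid] = (row["value"] - lo) / (hi - lo)
    tab["clinical"] = pd.Series(pooled)
    tab["Bristol"] = pd.Series(bristol)
    tab["severity"] = bundle.cohort.contexts.set_index("context_id")["severity"]
    return tab
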