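# ibdatlas

Multi-omic inflammation-severity analysis for inflammatory bowel disease
(IBD) cohorts, with a synthetic cohort generator so the whole pipeline runs
and is tested without any external data.

IBD disease activity is measured many ways — histopathology scores read by
pathologists, endoscopic and clinical indices, serum protein panels, tissue
RNA-seq, and H&E whole-slide images — and a central analysis question is
how coherently these read-outs track the same underlying inflammation.
`ibdatlas` implements that analysis end to end for researchers working with
multi-modal IBD cohorts:

- **Histopathology score normalization** (`ibdatlas.atlas`). Modified Naini
  Cortina (Crohn's disease, CD) and modified Riley (ulcerative colitis, UC)
  scores are divided by their context-specific maximum — e.g. 20 for Naini
  Cortina colon resections, 21 for Riley, down to 10/12 for ileal biopsies
  — mapping every score to a comparable 0–1 scale. Samples are labeled
  *inflamed* when a tissue- and date-matched histology record has raw
  score > 0.
- **Serum protein severity signatures** (`ibdatlas.proteomics`). Olink-style
  NPX values (log2 scale) are filtered to proteins detected in ≥ 90% of
  samples; inflamed vs non-inflamed samples are contrasted per protein with
  Welch's t-test and Benjamini–Hochberg correction; significantly
  upregulated proteins form the inflammatory protein severity signature
  (IBD-/UC-/CD-IPSS).
- **Single-sample gene-set scoring** (`ibdatlas.gsva`). A kernel-CDF rank
  random walk (Gaussian kernel, bandwidth s_i/4) scores a feature set per
  sample on a [−1, 1] scale — used for the biopsy molecular inflammation
  score (bMIS) on log2(TPM+1) expression and for scoring IPSS on NPX.
- **Cytokine signaling activity** (`ibdatlas.cytokines`). A differential
  expression profile y is regressed on a gene × cytokine response matrix S
  by ridge regression, β = (SᵀS + αI)⁻¹Sᵀy; z = β/SE with SE from
  gene-label permutations, plus a weighted-mean scorer for single-cell
  style data.
- **Attention-MIL histology regression** (`ibdatlas.mil`). A slide is a bag
  of tile feature vectors; tiles are embedded, pooled by learned softmax
  attention (optionally gated), and regressed on the normalized histology
  score (MSE, lr 1e-4, weight decay 0.01, batch size 1), with 5-fold
  score-stratified cross-validation, fold ensembling by arithmetic
  averaging, and attention-map extraction. Implemented in NumPy with
  explicit gradients; runs on one CPU.
- **Cross-modality evaluation** (`ibdatlas.evaluate`). Pairwise-complete
  Pearson correlation with significance tiers, DE threshold filtering
  (adj. p < 0.05, |log2FC| > 1), Venn/overlap counts, and hypergeometric
  over-representation analysis with fold enrichment (k/m)/(K/N).
- **Synthetic cohort generator** (`ibdatlas.cohort`). Every modality is
  driven by a shared latent severity in [0, 1] per patient-visit-tissue;
  planted effects are recorded as ground truth, so recovery and null
  calibration are testable properties.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (200 patients, 40% CD / 40% UC / 20% non-IBD) and write
their tables under `results/`:

```
python analysis/01_simulate_cohort.py      # write the cohort bundle
python analysis/03_serum_signatures.py     # derive IBD-/UC-/CD-IPSS
python analysis/07_cross_modality.py       # correlation structure
```

`03_serum_signatures.py` prints (seed 11):

```
IBD-IPSS: 20 proteins (20/20 planted recovered)
UC-IPSS: 19 proteins (18/20 planted recovered)
CD-IPSS: 21 proteins (20/20 planted recovered)
shared across all three signatures: 18 proteins
```

i.e. the Welch/BH contrast recovers essentially all 20 proteins whose NPX
was shifted by the latent severity, in each entity, with 18 shared across
the three signatures. `07_cross_modality.py` then shows that every severity
read-out — normalized histology, IPSS, bMIS, MIL out-of-fold predictions,
clinical activity and Bristol stool score — is mutually positively
correlated on the same visits:

```
            histo_norm  IPSS  bMIS  MIL_pred  clinical  Bristol
histo_norm        1.00  0.85  0.93      0.78      0.92     0.93
...
min off-diagonal R = 0.710, max p = 4.86e-32
```

because all of them are noisy monotone read-outs of the one latent
severity. `06_mil_histology.py` reports the histology regressor (internal
5-fold CV pooled R = 0.785; external ensemble R = 0.872 on a fresh cohort
sharing the lesion phenotype).

## Layout

```
src/ibdatlas/   library: cohort, atlas, proteomics, gsva, cytokines,
                mil, evaluate, pipeline
analysis/       numbered narrative drivers writing tables to results/
tests/          unit + property + acceptance suites (pytest)
docs/methods.md model assumptions, parameter choices, limitations
```
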