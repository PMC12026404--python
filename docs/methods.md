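# Methods

## The latent-severity cohort model

All synthetic data derive from one latent inflammation severity
s ∈ [0, 1], defined per (patient visit, tissue context). Non-IBD patients
have s ≡ 0. IBD patients are in histologic remission (s = 0) with
probability `remission_prob` (default 0.35) and otherwise draw
s ~ Beta(2, 2) — symmetric, mid-weighted, covering the full activity
range; the remission mass is what makes an inflamed vs non-inflamed
contrast *within* IBD possible, mirroring real cohorts where many sampled
visits are quiescent. One visit per patient, one tissue context per visit,
one serum draw / biopsy set / slide per visit on the same calendar date,
so tissue- and date-matching is exact by construction (the matching window
is still a parameter, exercised with perturbed dates in tests).

Disease and center labels are apportioned by the deterministic
largest-remainder rule rather than multinomial draws, so patient counts
are exact and reproducible. The master seed is split into one RNG
substream per modality (`numpy.random.SeedSequence.spawn`), so changing
one modality's parameters never shifts another's draws.

Per modality:

- **Histology.** Raw score ~ Binomial(max_score, s), with max_score from
  the normalization grid (system × tissue group × method). CD contexts are
  scored with modified Naini Cortina, UC with modified Riley; non-IBD
  contexts carry both systems (controls have no disease entity to select
  one). The binomial means the noise-free limits are exact: s = 0 ⇒ raw 0,
  s = 1 ⇒ raw = max.
- **Serum NPX.** Protein baselines Normal(μ_p, σ) with μ_p ~ Normal(5, 1)
  and σ = `npx_noise_sd` (default 0.5 NPX units); planted proteins
  (default 20 of 200) shift by `npx_delta`·s (default 1.0 NPX per unit
  severity). Values below a per-protein detection limit — the
  `lod_quantile` (default 0.05) of the null distribution — are flagged
  below-LOD and reported missing. Real Olink LOD mechanics are more
  involved (plate-specific limits, bridging); this left-censoring model is
  a stand-in and is the one thing the generator deliberately simplifies
  about NPX data.
- **Expression.** Negative-binomial counts (dispersion 0.1) around
  log-normal baselines; planted genes (default 100 of 2000) gain
  `gene_log2fc`·s (default 2.0) on the log2 mean. A random gene × cytokine
  response matrix S is drawn and planted cytokine activities a = scale·s
  shift log2 means by S·a, giving ridge inference a recoverable ground
  truth. TPM is computed from counts and simulated gene lengths; columns
  sum to 1e6 exactly.
- **Tile bags.** Background tiles ~ N(0, σ²I) in d dimensions (default
  d = 64, desk-scale; the real foundation-model dims 768–2560 are
  accepted); each tile is a lesion tile with probability s and lesion
  tiles shift by `lesion_shift` (default 2.0) along a fixed unit
  direction. The bag target is the context's normalized histology score.
  An external-center cohort can reuse another cohort's lesion direction
  (same lesion phenotype, new patients).
- **Clinical indices.** value = round(min + s·(max − min) + ε) clipped to
  the index range, ε ~ N(0, (0.1·range)²); UCEIS (0–8) and PMS (0–9) only
  for UC, SES-CD (0–56) and HBI (0–16) only for CD, Bristol (1–7) for
  everyone. Rounding makes the map non-strictly monotone — ties are
  expected.

What passing tests on this generator do show: the statistical machinery
recovers planted effects at realistic effect/noise ratios and controls its
error rates under the null. What they do not show: robustness to batch
effects, covariate confounding (age, sex, center), non-Gaussian NPX
tails, tissue composition shifts, or real histology texture — none of
which the generator emulates.

## Score normalization and matching

Normalization divides a raw score by the maximum of its own (system,
tissue group, method) cell: colon/rectum/caecum form the colon group;
ileum, ileocecal valve, small intestine, anastomosis and pouch the ileum
group. Raw scores above the tabulated maximum are rejected, not clipped —
they signal upstream scoring errors. Matching for inflammation status is
at tissue-group granularity with a default date window of 0 days (exact
date): paired specimens come from the same visit; the window is a
parameter because real endoscopy and serum draws can be days apart, and no
single value is obviously right.

## Differential abundance and the IPSS

"Detected" means not below-LOD and not missing; the ≥ 90% detection filter
is inclusive at the boundary. Welch's unequal-variance t-test runs per
protein on complete observations (no imputation — unbiased under
missingness that does not depend on the unobserved value, which is only
approximately true for LOD censoring; with ≤ 10% missingness after the
detection filter the bias is small). Proteins with fewer than 2
observations in either group are untestable and excluded from the BH
family — the family is exactly the testable, detection-filtered panel.
Signature inclusion is strict: BH-adjusted p < threshold and estimate > 0.
The default FDR threshold is 0.05, configurable to 0.1; both conventions
appear in practice and the choice is surfaced rather than resolved.

## Single-sample enrichment scoring

The kernel CDF transform uses a Gaussian kernel with per-feature bandwidth
h_i = s_i/4 (sample SD, ddof 1); a zero-variance feature is an error named
in the message, never silently perturbed. The `ecdf` kernel makes the
whole pipeline invariant under strictly increasing per-feature transforms.
Within a sample, features are ranked by z descending with ties broken by
stable feature order; rank weights |p/2 − rank|^τ (τ = 1) normalize the up
steps, non-members step down by 1/(p − |set|), and the enrichment score is
max positive excursion + min negative excursion ("difference" mode,
bounded in [−1, 1] at τ = 1) or the largest-magnitude excursion
("max_deviation"). Degenerate case: if every set member sits exactly at
rank p/2 (total weight 0), up steps are uniform. Sets are intersected with
the matrix features (dropped features logged); sets below `min_set_size`
(default 2) are skipped — a one-member walk is legal but degenerate.

How to score a protein signature per sample is genuinely open; the default
applies the same enrichment machinery to the NPX matrix, and a simpler
mean-z alternative is provided. Below-LOD NPX values are left-censored, so
for the rank-based score they are filled with the protein's observed
minimum — placing censored measurements at the bottom of the ranking,
which is what censoring means for ranks.

## Cytokine activity inference

Response-matrix columns and the differential profile are mean-centered;
gene-id intersection is mandatory. Ridge penalty default α = 1e4 — with
~genome-scale profiles the penalty mostly stabilizes, and z-scores are
scale-free in y. SE per cytokine is the SD of its coefficient over
`n_perm` (default 1000) permutations of y's gene labels; the two-sided
permutation p uses the add-one correction so p ≥ 1/(n_perm+1). With
n_perm = 0 the classical linear-model t formulation applies. β = 0 with
SE = 0 (e.g. a group contrasted against itself) reports z = 0; SE = 0 with
β ≠ 0 is flagged and reported missing. Group-level activities assign FDR
star tiers at 0.1 / 0.05 / 0.01. The weighted-mean scorer normalizes
against a permutation null over the weight-to-gene assignment.

## Attention-MIL regression

The model is tile embedding (linear + ReLU, default 64→32), attention
logits u_i = wᵀtanh(Vh_i) — optionally gated elementwise by σ(Uh_i) —
softmax pooling, and a linear head; trained with MSE, batch size 1,
learning rate 1e-4 and decoupled weight decay 0.01 under an
adaptive-moment optimizer (decay applied to weights, not biases). Written
in plain NumPy with hand-derived gradients (verified against numerical
differentiation to ~1e-9), fully deterministic given the seed. Default 25
epochs, no early stopping; the analysis scripts and tests use 10 epochs,
which already reaches held-out R ≥ 0.8 on the default 300-bag cohort.
Stratified 5-fold CV bins targets into 4 quantile bins and deals each
bin's (seeded-shuffled) bags round-robin with a carry-over counter, so
fold sizes differ by at most one overall. Predictions are unclipped during
training and clipped to [0, 1] only at reporting. Attention maps are
min-max rescaled per slide for display with a default threshold of 0.4;
(numerically) uniform attention is flagged degenerate.

**Known limitation — attention does not localize lesions here.** Because
the bag target is (a noisy read-out of) the *fraction* of lesion tiles,
the MSE-optimal pooling is uniform: the mean tile embedding is linear in
the lesion fraction, whereas attention concentrated on lesion tiles would
discard the count information the target depends on, and weight decay
pulls unused attention weights toward uniform. Accordingly, trained models
predict severity well (out-of-fold R > 0.8) while per-tile attention
stays near chance at separating lesion from background tiles (AUC ≈ 0.5;
a control experiment with a saturating, presence-like target raises this
to ≈ 0.66). On real slides the score is driven by localized morphology,
not tile counts, so attention there is informative in a way this
generator cannot emulate; attention-localization claims should not be
validated against fraction-type synthetic targets.

## Cross-modality evaluation

Correlations use pairwise-complete observations (≥ 3 pairs for a defined
p, two-sided t transform) with raw-p star tiers (*** < 0.001, ** < 0.01,
* < 0.05, strict); a BH-adjusted view is available for large matrices. The
entity-specific clinical indices never overlap across diseases (UCEIS/PMS
are UC-only, SES-CD/HBI CD-only), so the pooled score table carries one
clinical activity column — HBI for CD and PMS for UC, each rescaled to its
own range — plus Bristol, which exists for everyone. DE filtering uses
strict inequalities (adjusted p < 0.05, |log2FC| > 1). The ORA universe
defaults to all features surviving expression filtering — a choice, made
explicit and configurable, since fold enrichment depends on it.

## Problem sizes

Defaults throughout are chosen to keep every analysis desk-scale: 200
patients, 200 proteins, 2000 genes, 64-dimensional tile features, 30–80
tiles per slide, 1000 permutations, 10 training epochs. The full test
suite runs in about half a minute on one CPU; the acceptance script in
under a minute.
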