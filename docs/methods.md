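# Methods

This note records the model, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Windows and padding

All encoders consume a fixed window of W = 24 positions over the 20
canonical residues. Shorter peptides (≥ 1 residue) are padded
*downstream* with the gap symbol `-`, so window position m always refers
to residue m of the source peptide. Gaps are padding only and are never
accepted in input sequences. Sequences longer than W are rejected by
default; an explicit `truncate` flag keeps the first W residues with a
logged warning. Positions are 1-based everywhere a user sees them.

Profiles mirror this: a peptide's position-specific scoring matrix
(PSSM) has one signed log-odds row per window position, columns in fixed
alphabetical residue order, and all-zero rows for padded positions, so
padding is score-neutral in every profile-derived feature. The PSI-BLAST
ASCII parser keeps only the 20 log-odds columns and remaps them from the
producer's column order (read from the file's own header letters) to the
alphabetical order, giving stable feature names regardless of producer.

## The four encodings

**AIP (192 = W × 8).** Eight AAindex property vectors (NAKH920108,
CEDJ970104, LIFS790101, BLAM930101, MAXF760101, TSAJ990101, NOZY710101,
KLEP840101 — membrane/intracellular composition, strand and helix
propensities, volume, transfer energy, net charge). Each 20-vector is
min–max scaled to [0, 1] over the residues before use, putting all eight
properties on one scale and placing the gap contribution (0) at the
bottom of the range rather than outside it. The raw values are vendored
constants; scaling means downstream behavior depends only on the
within-index ordering and relative spacing.

**AFC (800).** For each spacing k ∈ {0, 1} and each of the 400 ordered
residue pairs, the count of window positions m where the pair occupies
(m, m+k+1) with both positions non-gap, divided by N_total = W − k − 1
(23 for k = 0, 22 for k = 1). Pairs touching a gap add nothing to
numerators while denominators stay fixed — the normalizer is a property
of the window, not of the observed pairs — so each k-block sums to
exactly 1 only for a gap-free window. Spacings beyond {0, 1} are
supported but off by default.

**PSSM (480).** Row-major flattening of the padded 24 × 20 profile, raw
log-odds scale. No sigmoid rescaling is applied anywhere: the PKAF
zero-floor below is only meaningful on signed scores.

**PKAF (800).** For each spacing and ordered pair, the sum over
occurrences of `max(min(S[m, x_i], S[m+k+1, x_j]), 0)` divided by
W − 1 = 23. The denominator is W − 1 for *both* spacings — deliberately
asymmetric with AFC's W − k − 1, following the formula as printed in the
method this package implements; a `per_k_denominator` switch selects the
W − k − 1 reading for sensitivity analysis. The zero floor makes every
PKAF feature non-negative and monotone in the profile: raising any PSSM
entry never decreases any feature.

## Feature selection

Every column is scored with a two-sample Wilcoxon rank-sum test against
the labels: midranks for ties, tie-corrected variance, and a 0.5
continuity correction on |W − E[W]|. The two-sided p-value comes from
the **exact permutation distribution** when the pooled sample has at
most 12 observations — computed by dynamic programming over doubled
midranks, so arbitrary tie structures are exact — and from the normal
approximation otherwise. The exact small-sample path exists because the
normal approximation is off by up to ~0.04 (continuity-corrected) or
~0.19 (uncorrected) at the extremes of 3-vs-3 problems, and far worse
under heavy ties; at the default cutoff the two regimes agree to well
under 0.02.

Features are ranked by |z| (descending; ties broken by lower column
index) and the top k are kept — defaults 170 (AIP), 510 (AFC), 320
(PSSM), 490 (PKAF), all overridable. The emitted mask lists the selected
columns in *ascending* |z| order; column order inside the mask does not
affect the forest. Whether importance is operationalized as |z|, raw
rank-sum or p-value changes nothing for equal class sizes without ties;
|z| was chosen because it remains well-ordered under ties.

No multiple-testing correction is applied: selection is by rank, not by
a significance threshold.

## Forests, fusion, tiers

One `RandomForestClassifier` (default 500 trees, √d features per split,
bagging, fixed seed) is trained per encoding on its selected columns.
The **RF score** is the fraction of trees voting the positive class —
computed explicitly over the trees, not the library's averaged leaf
probabilities, so the score is a vote fraction on a 1/n_trees grid.

The fusion layer is a logistic regression of the labels on the four RF
scores, in the fixed order (PSSM, AIP, PKAF, AFC). It is fit by
iteratively reweighted least squares with a ridge of 1e-8 (tolerance
1e-10, ≤ 100 Newton steps); on non-convergence or runaway coefficients
(quasi-separation) it refits with ridge 1e-3 and warns, so the fit
always terminates with finite coefficients. Class imbalance is not
reweighted.

Two leakage guards apply during training:

1. the fusion layer is fit on **out-of-fold** RF scores (stratified,
   seeded folds; each example scored by the forest trained without its
   fold), and
2. rank-sum selection is **nested inside each fold** when those
   out-of-fold scores are computed — selection on the full data would
   let chance-correlated columns leak label information into the held-out
   folds, visibly inflating a no-signal AUC. The deployed forests still
   use full-data selection.

Tier calls use `P ≥ threshold` (ties positive). Defaults are
0.485 / 0.410 / 0.360 for high / moderate / low; `calibrate_thresholds`
re-derives them as the smallest threshold reaching each target
specificity (defaults 0.866 / 0.747 / 0.636) on the fused out-of-fold
probabilities, enforcing strictly decreasing tiers with a minimal
separation of 1e-9. A target is reported unattainable if it would
require a threshold above 1. Nested tiers guarantee positive-at-high ⇒
positive-at-moderate ⇒ positive-at-low.

The sequential competitor concatenates the four encodings in the order
AFC, AIP, PSSM, PKAF (2272 columns), selects the top 380 by the same
rank-sum scheme, and trains a single forest — the baseline the fused
model is compared against.

## Evaluation

Sn, Sp, Ac and MCC follow their standard definitions, with any metric
whose denominator vanishes defined as 0 (the usual MCC convention). The
ROC is built over all distinct thresholds with the ≥ rule; tied scores
form single steps whose trapezoids contribute half credit, so the AUC
equals the tie-corrected Mann–Whitney U statistic over n₁n₂ — which is
also how it is cross-checked in the tests. Cross-validation uses
stratified seeded folds (fold sizes within one example, class ratios
within one example). AUC comparisons use two-tailed t-tests (paired or
Welch unpaired); identical paired vectors give p = 1 by convention.

The window-length sweep re-generates data at each window width (5, 10,
15, 20, 25 by default), evaluates all four encodings *without* feature
selection plus their fusion, and reports CV AUC per (length, encoding).
Positional enrichment compares per-(position, residue) indicator
frequencies between classes with an unequal-variance (Welch) two-sample
test over window positions 1–15, flagging cells with p < 0.05.

## Synthetic data

`generate_peptides` draws lengths uniformly from 5–24 and residues
per-position from class-conditional distributions: at enriched positions
3, 4, 6, 7, 8, 10, 11 a probability mass `effect_size` (default 0.3) is
moved onto one class-favored residue (P/N/Y cycling across those
positions for positives, A/H/L/M/V for negatives), the remainder scaled
proportionally; all other positions are uniform. The defaults encode the
qualitative class structure of real linear-epitope data — neutral-residue
preference in epitopes at early-window positions — at an effect size
chosen so that a few hundred peptides separate the classes well but not
trivially (single-encoding AUCs ~0.8 at n = 400).

`generate_profile` gives each non-gap position mean −1 everywhere except
the true residue (mean = `sharpness`, default 6) plus Gaussian noise
(sd 2), emulating the shape of real log-odds profiles: the evolutionary
encodings inherit exactly the sequence-level class signal, as they would
from PSI-BLAST. Profiles are written/read in the PSI-BLAST ASCII dialect
with integer rounding (PSI-BLAST prints integers); in-memory profiles
keep full precision and round-trip tests compare post-rounding.
`simulate_fusion_scores` inverts the fusion model (uniform scores,
Bernoulli labels from the logistic probability) for
parameter-recovery checks.

What passing tests on this generator do **not** show: real epitope data
have length-composition dependence, homology structure between peptides,
database-dependent profile quality and class imbalance, none of which
the generator emulates. Synthetic results validate the machinery
(encodings, selection, fusion, calibration, evaluation), not biological
performance; published-scale accuracy claims require the original
curated corpora and profile databases.

All generators, fold assignments and forests are pure functions of
their explicit seeds; every pipeline stage is bitwise reproducible and
model archives round-trip through `save`/`load` with a versioned
manifest.

## Problem sizes in the shipped tests

The test suite runs the full pipeline at a few hundred peptides with
forests of 30–200 trees and 5–10 folds, and the end-to-end benchmark at
400 peptides / 200 trees / 10 folds — sizes at which the qualitative
contracts (fused ≥ singles, null AUC band, determinism) are stable and
the whole suite runs in about a minute and a half on one core. The
library defaults (500 trees, 10 folds) are what `train_predictor` uses
when callers do not override them.
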