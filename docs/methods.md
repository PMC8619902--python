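# Methods

`corrscan` implements a pairwise feature-correlation ("redundancy") scan
over a multi-domain biomedical dataset of the ADNI type — a clinical /
biomarker table collection, a blood-microarray expression matrix, and an
image domain tabularized by convolutional autoencoders — together with
the preprocessing, multiple-testing control, redundancy summaries and
stratified revalidation built around it.  Everything is exercised end to
end on synthetic data with known planted structure; nothing in this
package reads or requires the real ADNI database.

## The scan

Given an analysis-ready dataset of `m` typed features over `n` patients,
every unordered pair (excluding self-comparisons, `m(m−1)/2` pairs in
total) is compared with a test chosen from the two features' types and,
for numeric data, their normality:

| pair              | condition                              | test           |
|-------------------|----------------------------------------|----------------|
| numeric–numeric   | both samples normal                    | Pearson        |
| numeric–numeric   | at least one non-normal                | Spearman       |
| nominal–nominal   | any contingency cell < 5               | not performed  |
| nominal–nominal   | all contingency cells ≥ 5              | χ² (no Yates)  |
| numeric–nominal   | every category's values normal         | one-way ANOVA  |
| numeric–nominal   | some category non-normal               | Kruskal–Wallis |

Normality is the D'Agostino–Pearson omnibus skew/kurtosis test at
α = 0.05.  Samples smaller than 8 are deemed non-normal: the omnibus
statistic is undefined there and the non-parametric branch is the safe
default.  A consequence worth knowing is that ANOVA is unreachable for
total sample sizes below 16 (two categories of ≥ 8), and the χ² branch is
unreachable below n = 20 (four cells of ≥ 5); tiny-sample pairs always go
through the rank tests or are skipped.

Family-wise error is controlled by Bonferroni: the base α (default 0.05)
is divided by the full planned family `m(m−1)/2`.  The divisor counts
*all* planned comparisons, including pairs the contingency rule later
skips — at the published scale this is 0.05 / 355,229,668,828 =
1.40754 × 10⁻¹³.  Only pairs with p ≤ α are stored.  p-values that
underflow double precision (p ≤ 5 × 10⁻³²⁴, the smallest positive
subnormal) are kept with an explicit underflow marker and called
"maximally significant"; exact duplicate columns reach this level for
n in the hundreds.

Statistical primitives come from `scipy.stats`; the test suite checks
their dispatch and p-values against an independent R implementation
(`cor.test`, `chisq.test(correct = FALSE)`, `aov`, `kruskal.test`) to
10⁻¹⁰, and against Monte-Carlo permutation nulls at n = 12 with a
tolerance of 0.05 + 3 Monte-Carlo standard errors — the 0.05 allowance is
for the large-sample character of the analytic p-values at such a small
n, fixed before the comparisons were run.  χ² has no n ≤ 12 regime (see
above), so its permutation check is vacuous and omitted.

Design choices where the procedure was genuinely open:

* **Observed, not expected, cell counts** drive the χ²-minimum-cell rule;
  the plain reading of "frequencies in the contingency table".
* **Spearman** uses average ranks for ties and the large-sample
  t approximation for p.
* **ANOVA gating** tests each category's sample independently; any
  failure routes to Kruskal–Wallis.
* **Canonical pair order** is lexicographic on feature name; the scan
  enumerates pairs in that order, chunks them, and is bit-identical for
  any worker count because chunk boundaries are fixed and results are
  concatenated in chunk order.

## Preprocessing

The clinical-style domain is built from raw visit-level tables:

1. **Headers uppercased**, tables joined on a patient-ID column
   (recognized names configurable, default `RID`/`PTID`/`PATIENT_ID`);
   tables without one are skipped with a warning.
2. **Longitudinal collapse**: per feature, the value from the latest
   dated visit at which the feature is known; a known earlier value beats
   an unknown later one.  Undated rows lose to dated rows; among undated
   rows and exact date ties the first occurrence in input order wins —
   the "arbitrary" choice made reproducible.  Cross-table column
   collisions are resolved the same way: most recent record wins, first
   table wins among undated, and a known value always beats a missing one.
3. **Typing**: number-valued columns are numeric unless they have fewer
   than 10 distinct observed values (then nominal); text columns are
   nominal unless they exceed 20 distinct observed values (then dropped
   as identifier-like).  Unknown markers never count as a distinct value,
   and mixed text/number columns are treated as text (the conservative
   reading).  The 20-distinct-value cap is applied after the longitudinal
   collapse.
4. **Filtering**, in a fixed order with one logged reason per dropped
   column: fewer than 2 distinct observed values; known fraction below
   0.80; nominal with any observed category under 20 patients.  The
   filter is idempotent and precedes imputation.
5. **Imputation**: numeric unknowns by scikit-learn's iterative imputer
   with a Bayesian-ridge regressor over the other numeric features
   (10 rounds, seeded, deterministic); nominal unknowns by the modal
   observed category, ties broken lexicographically.  Known cells are
   bit-identical before and after.

The expression domain arrives features-as-rows and is transposed;
columns with no header and columns whose values are not fully numeric
(metadata) are stripped.  The three domains are then assembled on the
intersection of their patients, with per-domain feature counts recorded
and the total defined as their sum.

## Image tabularization

Each slice index across patients gets its own small symmetric
convolutional autoencoder: min-max normalization of each slice to [0, 1],
then stride-2 3×3 convolutions (8, 16, 32, … channels) halving the
spatial dimensions until ≤ 8×8, a dense map to the latent vector, and a
mirrored decoder of transposed convolutions ending in a sigmoid.
Training minimizes mean-squared reconstruction error with Adam
(lr 10⁻³, β = 0.9/0.999).  The per-slice latents are concatenated
slice-major (`SLICE{i}_L{j}`) into the image domain; at the published
configuration of 124 slices × 6,400 latent features this layout declares
124 × 6400 = 793,600 columns, and the desk-scale default used throughout
the tests is 4 slices × 16 latents on 16×16 images, ≤ 5 epochs.

The network is written directly in numpy (im2col convolutions with
hand-derived gradients).  This keeps the dependency set small and the
training exactly reproducible for a fixed seed; the gradients are
verified against central-difference numerical differentiation in the test
suite, and the published-scale architecture remains available through the
spec object.  The appendix-level details of the original architecture
(layer counts, filter sizes, loss) are not public in the text this
package works from; the implementation is the smallest standard design
meeting "deep convolutional autoencoder", with MSE chosen as the loss.

## Synthetic data: what it emulates and what it does not

The generator fabricates the study's input *shapes* with known ground
truth: numeric correlation blocks drawn from a multivariate normal with
compound-symmetric correlation (so the expected within-block Pearson r
equals the requested ρ exactly); nominal features with optional
mean-shifted numeric partners (what ANOVA/Kruskal–Wallis detect);
bit-identical duplicate columns under slightly different names;
identifier-like metadata columns; per-feature missingness at declared
fractions (unknowns are NaN in memory, empty fields in CSV); optional
longitudinal duplication with integer-day visit dates; sex (F/M) and a
four-level dementia-rating column (0 / 0.5 / 1 / 2 at probabilities
0.40 / 0.30 / 0.20 / 0.10); an expression matrix with planted correlated
probe pairs plus injected metadata and headerless rows; and image stacks
containing elliptical blobs whose geometry drifts smoothly per patient
and slice, with 3% pixel noise — smooth content, because pure noise gives
an autoencoder nothing to compress.

It does **not** emulate real MRI intensity distributions, scanner
metadata, microarray normalization artefacts, or realistic clinical
covariance beyond the planted structure.  Passing tests therefore
demonstrate that the machinery is correct — dispatch, error control,
accounting, determinism — not that any biological conclusion transfers.

## Stratified revalidation

Five subsets are formed: female, male, CDR = 0, CDR = 0.5, CDR ≥ 1 (the
boundaries read literally).  Every maximally significant full-data pair
is re-tested inside each subset with dispatch fully re-evaluated there
(normality changes with the sample).  Each pair is classified as
retained (p ≤ 5 × 10⁻³²⁴ again), lost to untestability (a feature with
fewer than two distinct values in the subset, or failed test
preconditions), or lost to reduced significance; the three classes
partition the pairs exactly, per feature and in aggregate.  Per-feature
loss means and SDs are computed over features having at least one
maximally significant full-data pair.  The maximal-significance criterion
makes the question of a subset-specific Bonferroni family moot for this
analysis; for the configurable-α path the full-data α is reused.

## Summaries

Frequency records count, per feature, its stored significant partners
split by the partner's domain; each stored pair increments both
endpoints ("handshake" accounting), so within-domain column sums are
twice the within-domain pair count.  Summaries report mean, population
standard deviation, minimum and maximum per (feature-domain,
correlate-domain) cell; means/SDs are rounded half-away-from-zero to 2
decimals and percentages to 3 (`percent_of_domain` computes in exact
decimal arithmetic before rounding).  The feature→correlates mapping is
restricted to the clinical and expression domains — autoencoder features
carry no direct biological meaning.  Representative selection is a greedy
cover (repeatedly keep the feature covering the most not-yet-covered
features, ties lexicographic), a scalable heuristic rather than a
minimum-cover solver.

## Problem sizes and determinism

The package reproduces the published *arithmetic* exactly (family sizes,
corrected α, percentage identities, feature-count identities) and
replicates the *behaviour* of the scan at desk scale: 40-feature datasets
at n = 100–500 for calibration and recovery experiments (20 seeds each),
and a ~106-feature three-domain dataset at n = 120–400 for the end-to-end
runs.  The 355-billion-comparison production run and the real-data
frequency tables are out of scope by design.  Every stage is
deterministic for a fixed seed: generators and training use
`numpy.random.default_rng`, imputation is seeded, and the pipeline's
written artefacts are byte-identical across runs and worker counts.

Known limitations: the iterative imputer is O(features²) and meant for
the clinical domain, not for hundreds of thousands of columns; the greedy
cover gives no optimality guarantee; χ² p-values at cells near the
minimum-cell threshold are asymptotic; and the per-slice autoencoders are
trained independently, so latent features are comparable within but not
across slices.
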