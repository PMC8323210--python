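# Methods

This note documents the models and procedures `emrsim` implements, the
parameters that matter, the synthetic data the tests run on, and the numerical
and design choices made where the design was genuinely open.

## Feature-level similarity

Each unordered patient pair gets a 12-vector in the fixed order
`[age, sex, drug_allergy, admission_source, text_1..text_5, comorbidity,
labs, text_set]`.

**Age** is `min/max` of the two ages; two equal ages (including the degenerate
0/0) score 1, and the pairing of a zero age with a positive one scores 0.

**Binary features** (sex, drug-allergy history, admission source, and the five
independent report findings) score 1 on exact agreement, 0 otherwise.

**Comorbidity.** ICD-10 codes are normalized to a leading letter plus up to
three digits (`C78.7 → C787`), and the outcome-defining codes (C22 and its
extensions, C787, D180, K760) are stripped before anything downstream so the
features cannot leak the prediction target. The fragment corpus counts, for
each code occurrence in any patient's list, all its prefixes of length 1–4;
`p(f)` is a fragment's share of the total count. The IC of a code pair is
`−ln p(NCA)` of their longest common prefix, 0 when the leading letters
differ; a prefix can never be rarer than its extension, so a longer shared
prefix is never less informative. The pair-level comorbidity similarity is the
mean IC over all m·n cross pairs of the two code sets. Natural logarithm
throughout (the base is a positive rescaling and is absorbed by the
normalization below).

*Normalization.* The mean IC is unbounded while the 11 other components live
in [0, 1], so it is min-max normalized over all pairs of the cohort — a
monotone transform that preserves pair ordering. Conventions for degenerate
inputs: both code sets empty → 1 (identical information), exactly one empty →
0, and when every pair in a cohort shares the same raw value the component
maps to 1 if that value is positive, else 0.

**Set features.** Abnormal-lab sets and report-phrase sets use Jaccard
similarity; the undefined 0/0 case is fixed as both-empty → 1, one-empty → 0,
matching the binary-feature convention that identical information is maximal
similarity.

**Text schema.** Reports arrive as pre-tokenized phrase sets (no segmentation
is attempted; the source free text is out of scope). Phrases are ranked by a
corpus-level TF-IDF score `Σ_d tf(t, d) · ln(N / df(t))` with raw counts and
an unsmoothed idf — the simplest corpus-level aggregate, chosen because only
the ranking matters; ties break lexicographically. The top r = 44 phrases form
the schema; five clinically designated findings are independent binaries and
the remaining 39 form the set feature. Presence semantics: token order and
multiplicity are ignored.

**Laboratory preprocessing.** Values are binarized against closed normal
intervals ([low, high] → 0, outside → 1); the closed-interval convention is a
documented choice, not a given. Missing values are imputed beforehand,
per-feature, by a single CART-family decision tree (classification for binary
features, regression otherwise) fitted on complete cases with all other lab
features plus the four demographics as predictors; `min_samples_leaf = 5`,
default Gini / squared-error criteria, fixed random state. Features are
imputed independently from the pre-imputation values of the others, so the
result does not depend on feature processing order.

## Metric learning

Expert scores on the labeled pairs are ranked and split into thirds —
cannot-link (bottom), general-link, must-link (top) — with ties broken by
input index and group sizes differing by at most one; whether the original
tertile cutoffs acted on scores or ranks is unknowable from the available
description, and the rank rule is the deterministic choice. All-equal scores
trigger a degeneracy warning.

Within- and between-class scatter matrices sum `(v_p − v_q)(v_p − v_q)ᵀ` over
same- and different-constraint sample pairs respectively — exact enumeration
over all C(n, 2) pairs, computed by the algebraically identical closed form
`n Σ v vᵀ − (Σ v)(Σ v)ᵀ` per group (the 435 labeled pairs induce ~94k sample
pairs; closed form makes this instant).

The metric is `C = AᵀA` with A the row-orthonormal r×d projection minimizing
`tr(A S_w Aᵀ) / tr(A S_b Aᵀ)`. The decomposed Newton iteration on the
quotient value λ: A_t is the eigenbasis of the r smallest eigenvalues of
`S_w − λ_t S_b`, then `λ_{t+1} = tr(A_t S_w A_tᵀ) / tr(A_t S_b A_tᵀ)`.
Initialization λ₀ = 0 makes the first iterate the minimum-within-scatter
subspace; from the first achieved quotient onward the sequence is
non-increasing, bounded below by 0, and converges to the global optimum of
this quotient class. Stopping: |Δλ| < 1e−8 or 100 iterations (warning + best
iterate). Eigenvector signs are canonicalized (first non-negligible component
positive) for determinism. Directions with zero total scatter (components
constant over the labeled samples) leave the quotient 0/0-undefined, so the
problem is solved within the span of `S_w + S_b` and embedded back, as in
discriminant analysis. Projection rank defaults to r = 2 (constraint classes
minus one, the discriminant-analysis convention); r = d is disallowed because
a square row-orthonormal A forces C = I.

## Snowball propagation

With C fixed, Mahalanobis distance equals Euclidean distance on the
`A`-projected coordinates, so each pair vector is projected once. Every round,
each unlabeled pair's distance to its nearest labeled pair is maintained
incrementally; the `batch_size` unlabeled pairs with the smallest such
distance (most confident first — the batch-membership rule is a documented
choice) copy their nearest labeled neighbor's score and join the labeled set.
Scores are copied, never averaged, so the final score multiset is a subset of
the initial expert scores; provenance (source pair, round) is recorded for
every propagated label, and ties break by canonical pair order, making the
run byte-reproducible. The default batch size follows the stated percentage
rule — 0.15% of the unlabeled samples, half-up rounded, floored at 1 (1048 at
the original scale of 698,718 unlabeled pairs); the literal batch size 1153
used originally remains available as an explicit override. The metric is
never re-learned during propagation.

## Personalized kNN and evaluation

For each index patient in a leave-one-out loop, the training subset is
`round(M% · |pool|)` samples (half-up rounding, floored at k with a warning;
a pool smaller than k errors) chosen at random (seeded per index patient), by
highest propagated similarity, or by smallest Euclidean distance on the
numeric representation. Neighbors are the top k (default 10) by propagated
similarity or Euclidean distance; class probabilities are vote fractions;
predicted-label ties break by larger summed neighbor affinity, then canonical
class order. At M = 100% training selection is vacuous, so R+L ≡ E+L and
R+E ≡ L+E exactly.

The numeric representation concatenates text binaries (44), binarized labs
(57), popular-comorbidity binaries (occurrence strictly above 5%, optionally
truncated to the 26 most frequent), and four demographics; age is min-max
scaled to [0, 1] over the cohort so one continuous column does not dominate
Euclidean distances.

Metrics: micro-averaged one-vs-rest AUC (one-vs-rest label/score pairs pooled
over classes, Mann-Whitney with half-ties); micro F1 (equals accuracy for
single-label multiclass — the averaging mode is an interpretation, macro is
available behind a flag); mean cross-entropy `−mean ln p(true)` with
probabilities clipped at 1e−15, since vote fractions can be exactly zero.

## Synthetic cohorts and the expert oracle

The default generator emulates the motivating liver cohort: 1183 patients in
four classes (cancer 153, hemangioma 178, NAFLD 403, normal 449), per-class
age means (66.6 / 57.2 / 51.4 / 51.8 years, SD 12, clipped to [18, 95]),
male / drug-allergy / outpatient rates, and six common comorbidities with
published per-class prevalences (coronary heart disease, diabetes with and
without complication, essential hypertension, lipid-metabolism disorders,
other GI disorders). Each class additionally leans on a family of eight
related ICD-10 codes (in-class prevalence 0.30, 0.02 elsewhere — high enough
that family codes clear the 5% popularity threshold, giving a
popular-comorbidity list of about the study's width of 26). Patients carry
1–11 codes (per-code Bernoulli draws, padded with one class-weighted code
when empty, truncated at 11). Labs are 57 Bernoulli binaries: published rates
for the six reported urine tests, background 0.08, and a few class-leaning
tests at 0.30. Report tokens are Bernoulli draws of 5 independent findings
plus 39 set phrases with class-leaning probabilities. Hidden class labels are
returned separately and touched only by the evaluation harness.

The expert oracle scores a pair as `clip(Σ w_k v_k + ε, 0, 1)`,
ε ~ N(0, noise_sd), seeded. Default weights put 60% of the mass on the three
set-valued components (comorbidity 0.30, labs 0.15, text set 0.15) and spread
the rest evenly; noise_sd defaults to 0.05. Clipping after noise keeps the
scores in the expert's [0, 1] range. The noise model is an artifact choice —
nothing is known about the human scorer's error structure.

Two presets serve specific experiments:

- `hierarchical_signal_config`: class signal lives almost entirely in the
  ICD-10 hierarchy (per-class families of eight codes sharing a rare
  two-character prefix, each individual code below the popularity threshold),
  while labs, text, and demographics are class-independent noise. Euclidean
  distance on the numeric representation is nearly blind here; the learned
  similarity is not — the configuration that separates the two neighbor
  metrics.
- `score_recovery_config`: a class-flat cohort (identical feature
  distributions across classes, a class-independent code pool with graded
  prevalences so the IC component still varies). With an oracle concentrated
  on three components, no other component correlates with the score, so trace
  concentration of the learned C on the scored block measures recovery of the
  scoring rule itself rather than incidental class structure — the standard
  identifiability design.

What passing tests on these cohorts do **not** show: realistic comorbidity
co-occurrence, lab correlation structure, report language, longitudinal
structure, or the real cohort's headline predictive performance — the original
EMR data and expert scores are unavailable, so real-data AUC/F1/CE values are
out of reach by construction and are not reproduced here.

## Problem sizes used by the shipped experiments

The test suite and acceptance script run the full pipeline at n = 200
(equivalence and headline statistics), n = 150 (ordering experiments), and
n = 80 over 10 seeds (recovery experiments), with 30 expert-labeled patients
(435 labeled pairs) in each — the labeled-set size of the original design —
chosen as comfortable desk-scale cohorts that keep every stage exercised,
including multi-round snowballing (hundreds of rounds at the default batch
rule).

## Known limitations

- The comorbidity normalization couples a pair's similarity to the cohort it
  was computed in; scores from different cohorts are not directly comparable.
- 1-NN label copying cannot produce scores outside the expert's initial set;
  propagated scores are piecewise constant.
- The trace-quotient solver returns a rank-r metric; r is a modeling choice,
  not estimated from data.
- The kNN harness assumes the propagated similarity covers every patient
  pair; adding a new patient requires recomputing pairs involving them and
  re-propagating.
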