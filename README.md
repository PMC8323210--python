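# emrsim

Learning-based patient similarity for heterogeneous electronic medical record
(EMR) data, with personalized k-nearest-neighbor (kNN) disease-status
prediction.

## The problem

EMR data mixes data types — continuous demographics, binary flags, hierarchical
ICD-10 comorbidity codes, binarized laboratory panels, and phrases extracted
from free-text radiology reports — so no single off-the-shelf distance treats
all of them sensibly. `emrsim` implements a two-stage answer for a cohort of
hospitalizations with four liver conditions (liver cancer, hemangioma, NAFLD,
normal liver):

1. **Feature-level similarity.** Every unordered patient pair (i, j) gets a
   12-component similarity vector:
   - age: `min(age_i, age_j) / max(age_i, age_j)`;
   - sex, drug-allergy history, admission source, and five independent report
     findings: exact-match similarity (1 if equal, else 0);
   - comorbidities: the mean information content (IC) over all cross pairs of
     the two ICD-10 code sets, `IC(c1, c2) = −ln p(NCA)`, where the NCA is the
     longest common code prefix and `p` its frequency in the *fragment corpus*
     (all prefixes of all code occurrences in the cohort). Codes with different
     leading letters share nothing and score 0; sharing a *rare* ancestor
     counts for more than sharing a common one. The component is min-max
     normalized to [0, 1] over the cohort's pairs;
   - abnormal-lab sets and report-phrase sets: Jaccard similarity
     `|A∩B| / |A∪B|`.
2. **Semi-supervised patient similarity.** A small expert-scored pair set
   (all 435 pairs among 30 patients) is split into must-link / general-link /
   cannot-link constraint classes by score tertiles. A Mahalanobis metric
   `d(x, y) = √((x−y)ᵀ C (x−y))` over pair vectors is learned by minimizing the
   trace quotient `tr(A S_w Aᵀ) / tr(A S_b Aᵀ)` over row-orthonormal
   projections A (C = AᵀA), via Newton iteration on the quotient value. Scores
   are then *snowballed* to all remaining pairs: each round, the batch of
   unlabeled pairs nearest to the labeled set copies its nearest labeled
   neighbor's score and joins the labeled set.

The propagated pair scores form a full patient-similarity matrix used by a
personalized kNN classifier (k = 10 by default): for each index patient,
training samples are M% of the pool picked at random (R), by learned
similarity (L), or by Euclidean distance (E) on a flat 131-feature numeric
representation (44 text + 57 lab + 26 popular-comorbidity + 4 demographic
columns), and the k nearest neighbors under the learned (L) or Euclidean (E)
metric vote. The four combinations R+L, R+E, L+E, E+L are evaluated by
leave-one-out micro-averaged AUC, micro F1, and cross-entropy loss.

Because no real cohort ships with the package, a first-class synthetic
generator emulates one: four latent classes with class-specific ICD-10 code
families, lab abnormality rates, report-phrase probabilities, and
demographics, plus an expert-score oracle (a clipped noisy weighted sum of the
12 feature similarities) standing in for the human scorer.

## Worked example

```python
import numpy as np
import emrsim as es

patients, labels = es.generate_cohort(es.CohortConfig(n_patients=200, seed=1))
res = es.run_similarity_pipeline(patients, n_labeled_patients=30, seed=1,
                                 max_popular=26)
print(f"pairs: {len(res.pair_table)}, expert-labeled: {res.labeled_mask.sum()}")
print(f"trace quotient: {res.learner.quotient_:.4f} "
      f"after {res.learner.n_iter_} Newton steps")
print(f"propagation: {res.propagator.n_rounds_} rounds "
      f"of batch size {res.propagator.batch_size_}")

lab = {p.id: l for p, l in zip(patients, labels)}
y = np.array([lab[i] for i in res.ids])
grid, _ = es.run_combination_grid(y, ["R+L", "R+E", "L+E", "E+L"], [25, 100],
                                  k=10, seed=1, S=res.similarity_matrix,
                                  X=res.numeric.to_numpy())
print(grid.round(3).to_string(index=False))
```

prints

```
pairs: 19900, expert-labeled: 435
trace quotient: 0.2414 after 7 Newton steps
propagation: 672 rounds of batch size 29
combination   M   auc    f1    ce
        R+L  25 0.821 0.615 1.620
        R+L 100 0.913 0.740 1.199
        R+E  25 0.935 0.825 0.710
        R+E 100 0.986 0.940 0.593
        L+E  25 0.980 0.895 0.499
        L+E 100 0.986 0.940 0.593
        E+L  25 0.944 0.825 1.094
        E+L 100 0.913 0.740 1.199
```

Reading the output: the 200-patient cohort yields 200·199/2 = 19,900 pairs, of
which the 435 pairs among the 30 "expert-scored" patients are labeled; the
metric learner reaches a within/between scatter quotient of 0.24; snowballing
labels the other 19,465 pairs in 672 rounds of 29. At M = 100% training
selection is vacuous, so R+L equals E+L and R+E equals L+E row-for-row. On
this default cohort much of the class signal is linearly encoded in the
numeric features, so Euclidean neighbors do well; cohorts whose signal lives
in the code hierarchy (see `hierarchical_signal_config`) reverse the ordering
in favor of the learned similarity.

A command-line interface mirrors the stages:

```
emrsim synth --n 200 --seed 1 --out cohort.jsonl --labels-out labels.csv
emrsim pairs --cohort cohort.jsonl --out pairs.csv
emrsim learn-metric --pairs pairs.csv --labeled expert.csv --out C.csv
emrsim propagate --pairs pairs.csv --labeled expert.csv --metric C.csv --out scores.csv
emrsim predict --cohort cohort.jsonl --labels labels.csv --scores scores.csv --out results.csv
```

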