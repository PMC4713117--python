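# Methods

## The model

`gaeoc` treats ensemble construction as a subset-selection problem.  A
pool of k heterogeneous base classifiers is fixed and ordered; an ensemble
is a non-empty bitmask over the pool, fused by unweighted majority voting
(one vote per member, exact ties resolved uniformly at random).  The
objective is the mean Matthews correlation coefficient (MCC) of the fused
predictions over a stratified 10-fold cross-validation of the training
set.  MCC is chosen over accuracy because it uses all four cells of the
confusion matrix and stays meaningful under class imbalance; a constant
predictor scores 0 by the zero-denominator convention.

The search assumes nothing about the base learners beyond their producing
binary predictions: every classifier is trained once per training fold
before the search starts and its validation-fold predictions are cached,
so evaluating a mask is a lookup-and-vote, never a retraining.  The
genetic algorithm is therefore pool-agnostic, and the default pool — 20
scikit-learn estimators mixing Bayes variants, linear models, an RBF SVM,
1-nearest-neighbour, several tree/rule learners, boosting-style and
forest models, and a majority-class baseline — is a pluggable convention,
not a dependency of the method.  Two of the Bayes entries behave
identically on purpose: keeping near-duplicates as distinct bits
preserves the intended 20-bit search space.

## Search parameters

| parameter | default | rationale |
|---|---|---|
| population size | min(5k, 12·2^k) → 100 at k = 20 | sizing heuristic scaling with the chromosome length, capped for tiny pools |
| crossover rate R_χ | 0.60 | probability that a mating performs a uniform ½-mix; otherwise the fitter parent is cloned |
| mutation rate R_μ | max(0.01, 1/n) → 0.01 at n = 100 | random *bit replacement*, so a hit redraws the bit uniformly (expected flips per hit = ½) |
| tournament size | 10 | parents are the fittest of 10 distinct uniform draws |
| elitism m | 1 | the single best individual is copied verbatim; makes the best-fitness trajectory non-decreasing |
| termination | 1000 generations / 50 stagnant generations / fitness ≥ 1.0 | whichever occurs first |

"Stagnant" means the best-so-far fitness changed by less than 1e-12
between generations.  The crossover sentence in the source method
description conflates a per-mating and a per-gene reading of the 60%
rate; the per-mating reading (uniform mix with probability R_χ, else
clone the fitter parent) is the conventional meaning and is the default,
with `crossover_mode="per_gene"` available for the other reading.

All-zero chromosomes (empty ensembles, for which the vote is undefined)
are repaired by setting one uniformly chosen bit — at initialisation and
after mutation — rather than penalised, so every evaluated individual is
meaningful.  Duplicated individuals are not deduplicated.  One offspring
is produced per mating, and the two tournament-selected parents may
coincide, in which case crossover degenerates to cloning.

### Randomness and reproducibility

Three independent seeded streams drive a run: the search stream
(initial population, selection, variation), the model-training stream
(per-(classifier, fold) estimator seeds derived via `SeedSequence`), and
the vote-tie stream.  The tie stream is seeded per bitmask from
`(tie_seed, mask_int)`, which makes fitness a pure function of
(store, mask, tie_seed): memoized values equal recomputations exactly,
the exhaustive enumeration oracle reproduces the same landscape the GA
sees, and whole runs replay bit-for-bit.  The tie seed is deliberately
*not* derived from the search seed — otherwise "the optimum" would be a
different number for every run and runs could not be compared against a
single enumerated optimum.

## Preprocessing

**Balancing.**  For an imbalanced binary dataset the minority class is
set aside, the majority class is shuffled (seeded) and split into
q = round(n_maj/n_min) near-equal chunks (half-up rounding, at least 1;
remainder rows distributed one per chunk), and each chunk is paired with
the full minority class.  Every majority sample is used exactly once
across replicates.  Chunk sizes within a call differ by at most one, but
the replicate ratio itself is only as close to 1:1 as rounding permits —
it lies in (2/3, 3/2], e.g. chunks of 229 against 241 minority samples at
the 1.90 ratio.  Already-balanced inputs pass through unchanged.

**Discretisation/filtering.**  Per feature, cut points are chosen
recursively to minimise the weighted class entropy of the induced
partition; a cut is accepted only if its information gain exceeds the
minimum-description-length threshold (log₂(N−1) + Δ)/N with
Δ = log₂(3^c − 2) − [c·Ent(S) − c₁·Ent(S₁) − c₂·Ent(S₂)].  Features with
no accepted cut are discarded.  Only value order matters, so the filter
is invariant to strictly monotone transforms.

**(α,β)-k selection** operates on the discrete codes: a feature
"distinguishes" an inter-class pair if their codes differ and "supports"
an intra-class pair if they agree.  The greedy solver repeatedly adds
the feature covering the most unsatisfied pair-constraints (each
inter-class pair needs α covering features, each intra-class pair β),
ties broken towards the lowest feature index; the exhaustive solver
(capped at 20 features) certifies minimum cardinality.  Infeasible
(α,β) settings are reported with the violating pair and the maximum
feasible α — never silently relaxed.  Defaults are α = 1, β = 0; the
values used in the original biomarker studies are not published with the
method description, so they are exposed as configuration rather than
guessed.

**Consolidation across balanced replicates**: UAB selects per replicate,
takes the union, and runs one more selection pass on the union-reduced
data (applied to the first replicate, as the replicates share the
feature universe); IAB intersects the per-replicate selections and
stops; UEAB applies the MDL *filter* per replicate before selection and
takes the union.

## Evaluation protocol

The winning mask's members are retrained on the full training set and
the majority-vote ensemble is scored once on held-out test data
(accuracy, precision, recall, F-measure, MCC, plus the confusion
matrix).  Repeated runs use consecutive seeds with the fold split and
model store held fixed, isolating search stochasticity; summaries report
mean/stdev of MCC and accuracy and the number of distinct winning masks,
and are recomputable from the per-run records.  When balancing produced
several replicates, runs are reported per replicate and averaged.
Baseline comparisons (bagging, AdaBoost, random forest) call
scikit-learn with library-default hyperparameters.

## Synthetic data and what it shows

The generators stand in for the study's data:

* `gen_imbalanced_gaussian` — two spherical unit-variance Gaussians at a
  chosen mean separation and imbalance ratio.  It emulates the *shape* of
  imbalanced tables (e.g. 90 vs 360 at the 1:4 ratio) but not feature
  correlations, heavy tails, or label noise of real biomarker data, so a
  passing pipeline test shows plumbing and search correctness, not
  clinical performance.
* `gen_mock_pool` — classifiers *as* fixed per-fold prediction vectors
  with chosen marginal error rates and a shared-latent error correlation
  (with probability ρ a member consults a shared uniform draw, preserving
  marginals while coupling errors).  Fitness is then exactly computable
  and the optimal subset is certified by enumerating all 2^k − 1 masks
  with the same evaluator the search uses.
* `gen_planted_mock_pool` — the certification fixture for search
  optimality: a planted subset of diverse members (disjoint
  member-specific error blocks plus a small common block, so their
  majority errs exactly on the common block) with strongly correlated
  high-error distractors.  Random unplanted pools produce a dense
  near-tie top — the search reliably reaches it but the exact argmax is
  decided by tie luck — whereas the planted construction has a flat,
  clearly separated optimum, which is the structure a certification
  fixture needs.  The optimum is still taken from enumeration, never
  assumed.
* `gen_redundant_strong_pool` — demonstrates the diversity effect: the
  member with the best individual accuracy errs inside two other
  members' error sets, so the unique optimal ensemble (fitness exactly
  1.0) excludes it, while three individually weaker but
  disjointly-erring members form the optimum.
* `gen_toy_abk_instance` — small discrete instances whose minimum
  (α,β)-feasible set is certified by subset enumeration.

## Problem sizes

Tests and the acceptance script run at desk scale by design: Gaussian
tables of 40–700 rows, mock pools with k ∈ {4, …, 12} and 10 folds of
20–30 validation samples, 20 search runs per certification pool, and a
single 20-classifier × 10-fold store (200 cached models) on a 60-row
table.  These sizes keep every certified optimum enumerable; the search
itself scales to k = 20 (≈10⁶ masks) as in the worked example.

## Known limitations

* Base learners are scikit-learn analogues of the original WEKA pool;
  behavioural parity with WEKA is not promised, and published scores on
  the UCI/Alzheimer's/face-recognition datasets are reproducible only
  approximately (fold randomisation and learner internals differ).
* Feature matrices must be numeric and complete; nominal attributes and
  missing-value imputation are out of scope (ARFF nominal *labels* are
  accepted).
* The exhaustive (α,β)-k solver and mock-pool certification are capped
  (20 features, k = 16) — they are oracles, not production paths.
* Hyperparameter tuning of base learners and non-vote fusion rules
  (weighted voting, probability averaging) are intentionally absent.
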