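# gaeoc — genetic-algorithm selection of heterogeneous classifier ensembles

`gaeoc` builds a good *ensemble of classifiers* (EoC) for binary
classification — especially on class-imbalanced tables such as clinical
biomarker panels — by searching the subsets of a pool of heterogeneous base
learners instead of using the whole pool.

Given a pool ⟨C⟩ₖ of k base classifiers, each candidate ensemble is a k-bit
mask I, where bit i selects Cᵢ.  The ensemble's decision for a sample is
the unweighted majority vote of its members, with exact ties broken
uniformly at random.  Candidate quality is the mean Matthews correlation
coefficient over a stratified 10-fold cross-validation of the training
data,

    fit(I) = (1/10) · Σ_f  MCC(E_I on fold f),
    MCC    = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC defined as 0 when a denominator factor vanishes (a constant
predictor scores 0).  Because 2^k − 1 subsets are too many to enumerate
for k = 20, a genetic algorithm searches the mask space: population size
min(5k, 12·2^k) (= 100 at k = 20), tournament selection with a pool of
10, uniform crossover at rate 0.60, random-bit-replacement mutation at
rate max(0.01, 1/n), single-individual elitism, and termination at 1000
generations, 50 stagnant generations, or a perfect fitness of 1.0.
Every pool classifier is trained once per training fold up front (200
cached models for 20 classifiers × 10 folds), so fitness evaluation is a
pure lookup-and-vote.

Preprocessing mirrors the workflow the search was designed for:

* **Class-distribution balancing** — the shuffled majority class is
  partitioned into near-minority-sized chunks, each paired with the full
  minority class, yielding several balanced replicates (e.g. a 1:4
  dataset becomes 4 balanced ones).
* **Feature selection** — Fayyad–Irani entropy/MDL discretisation drops
  uninformative features, then the (α,β)-k method picks a minimum feature
  set on which every inter-class sample pair differs on ≥ α features and
  every intra-class pair agrees on ≥ β; union/intersection consolidation
  (UAB/IAB/UEAB) combines selections across balanced replicates.
* **One-vs-all decomposition** for multiclass inputs.

The winning mask is finally retrained on the full training set and scored
once on held-out test data; repeated seeded runs are summarised by
mean/stdev and the number of distinct winning ensembles.

## Worked example

```python
from gaeoc import EnsembleSelectionModel, gen_imbalanced_gaussian

train = gen_imbalanced_gaussian(30, 30, 4, separation=4.0, seed=17)
test  = gen_imbalanced_gaussian(15, 15, 4, separation=4.0, seed=18)

model = EnsembleSelectionModel(train, n_folds=10)   # default 20-learner pool
res = model.fit(seed=23)
print(res.summary())
rec, cm = res.evaluate(test)
print("test MCC:", round(rec.mcc, 4), "accuracy:", round(rec.accuracy, 4))
```

prints

```
Ensemble selection results
======================================================
Training dataset:         gauss(sep=4.0,min=30,maj=30)
Pool size (k):            20
Population size:          100
Folds:                    10
Seed:                     23
------------------------------------------------------
Best fitness (mean MCC):  0.9707
Best mask:                11110010100100110000
Members:                  bayes_net, naive_bayes, naive_bayes_updateable, lib_svm, simple_logistic, ibk, oner, rep_tree, zero_r
Generations run:          51
Termination:              stagnation
Fitness evaluations:      932
------------------------------------------------------
Per-fold MCC: 1.000 1.000 0.707 1.000 1.000 1.000 1.000 1.000 1.000 1.000
======================================================
test MCC: 0.9354 accuracy: 0.9667
```

The best fitness is the mean of the ten per-fold MCCs of the selected
ensemble's majority vote (0.9707 here: nine perfect folds, one fold at
0.707).  The mask reads left to right over the pool, so this run selected
9 of the 20 learners.  The search stopped because the best fitness had not
improved for 50 consecutive generations, and only 932 of the ~10⁶
possible masks were ever evaluated (fitness values are memoized).  On the
held-out table, the retrained ensemble mislabels one negative sample
(tp=15, fp=1, tn=14, fn=0 → MCC 0.935).

A command-line interface exposes the same stages
(`gaeoc simulate | balance | select | folds | train | search | run |
evaluate`); see `gaeoc --help`.

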