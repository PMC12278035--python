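# Methods

## Problem and model

Enzymes adapted to acidic (optimal pH < 5) versus alkaline (pH > 9)
environments show systematic compositional differences. The package casts
discrimination as binary classification of protein sequences (acid = 0,
alkaline = 1; the positive class is alkaline, which is the majority class in
the motivating 54/68 data composition — this is configurable in spirit, and
every metric is reported alongside the full confusion counts so either
orientation can be derived).

## The 188-dimensional descriptor

For a sequence of length *L* over the 20 standard amino acids:

* **Amino-acid composition (20)** — `n_i / L` per residue, alphabetical
  order `ACDEFGHIKLMNPQRSTVWY`.
* **Per-property block (21 × 8)** — each physicochemical property partitions
  the alphabet into three ordered groups (group 2 = "medium"):
  * *composition* (3): fraction of residues in each group;
  * *distribution* (15): for each group occurring at 1-based positions
    `p_1 < … < p_n`, the values `p_1/L`, `p_ceil(0.25n)/L`, `p_ceil(0.5n)/L`,
    `p_ceil(0.75n)/L`, `p_n/L`; an absent group contributes five zeros.
    The `ceil` quantile rule and division by full length *L* are the common
    conventions of this descriptor family and make the values deterministic;
  * *bivalent frequency* (3): counts of adjacent residue pairs whose members
    fall in different groups — pairs {1,2}, {1,3}, {2,3}, order within a
    pair ignored (the only reading that yields exactly three values) — each
    over `L − 1`. Requires `L ≥ 2`.

The eight default partitions (hydrophobicity, normalized van der Waals
volume, polarity, polarizability, charge, surface tension,
secondary-structure propensity, solvent accessibility) are the canonical
tables of the CTD descriptor literature and live in
`enzyph/properties.py`; alternative tables can be loaded from YAML. The
property order is fixed with normalized van der Waals volume **second**, so
that 1-based index 43 of the vector is the composition of its medium group
`NVEQIL` — the key feature the analysis isolates. Group display labels are
not interpreted; only membership matters.

Invariants (enforced by tests): all 188 values lie in [0, 1]; the AAC block
and each composition triple sum to 1; the 1-based index of composition
feature *g* of property *k* is `20 + 21(k−1) + g`.

## Cross-covariance features

Residues are mapped to numeric profiles by per-residue index tables; for an
ordered pair of distinct indices and lag `lg`,

    CC(u1, u2, lg) = Σ_{i=1}^{L−lg} (P_u1(R_i) − m_u1)(P_u2(R_{i+lg}) − m_u2) / (L − lg)

with `m_u` the index mean over the *whole sequence* (so CC is invariant to
adding a constant to a table). The block enumerates all ordered pairs and
lags 1..LG: `N(N−1)·LG` features.

Defaults: N = 2 tables — Kyte–Doolittle hydropathy and Hopp–Woods
hydrophilicity, each standardised to zero mean / unit population SD over
the 20 residues — and LG = 6. This is the smallest-N configuration whose
block size (12) combines with the 188D block to a 200-dimensional vector,
the dimensioning the analysis assumes; both the tables and LG are
configurable.

## MRMD feature ranking and subset selection

Per feature column *i*:

* relevance `MR_i = |PCC(f_i, C)|` — absolute value because a strong
  negative correlation is equally discriminative; a zero-variance column
  gets 0 with a warning, never a silent drop;
* distance `MD_i = ED_i + COS_i + TC_i`, the mean Euclidean distance,
  cosine distance (1 − cosine similarity) and Tanimoto distance
  (1 − a·b/(‖a‖² + ‖b‖² − a·b)) from column *i* to every other column,
  computed on min-max-normalised columns. Maximising mean distance to the
  other features penalises redundancy. Pairs whose similarity is undefined
  (cosine with an all-zero column; Tanimoto between two zero columns)
  contribute distance 0, with a warning; a zero-vs-nonzero Tanimoto is
  defined (similarity 0, distance 1) and counted normally.

MR and MD are on incomparable scales, so each is min-max scaled to [0, 1]
across features before summation; features are ranked by descending
combined score, ties broken by lower column index. A single-column matrix
has MD ≡ 0.

Subset choice is a forward wrapper: prefixes of the ranked list are scored
by stratified k-fold cross-validated accuracy (default 10 folds, logistic
evaluator) and the smallest prefix attaining the maximum wins. For wide
matrices the prefix grid is all k ≤ 10 plus ~15 geometrically spaced sizes
up to M (every k when M ≤ 25); this bounds the number of CV runs while
still resolving the small-k region where the planted-signal optimum lies.

## Evaluation

Stratified, seeded k-fold cross-validation; out-of-fold predictions are
pooled into one confusion matrix (every instance predicted exactly once),
from which Sn = TP/(TP+FN), Sp = TN/(FP+TN), ACC and MCC are computed. Any
metric with a zero denominator is reported as 0 with a warning so a
degenerate fold cannot abort a run. Ranking quality is the ROC AUC (rank
statistic, ties half-credited) and the step-integrated precision-recall AUC
of the pooled class-1 scores.

Classifier specs: `rf` — random forest, 100 trees, unlimited depth, seeded;
`logistic` — logistic regression with only a weak ridge (C = 10⁴) for
numerical stability, since the reference setup is effectively
unregularised. A single-feature model whose column is constant falls back
to a majority vote (accuracy exactly the majority rate, AUC 0.5).

## Synthetic data and its Bayes oracle

The generator emulates exactly one statistical property of real data: the
alkaline class is enriched in medium-volume residues. Each residue is drawn
independently — with probability `p_medium` uniformly from `NVEQIL`,
otherwise uniformly from the other 14 residues; lengths are uniform on a
range. Defaults: 54 acid / 68 alkaline sequences (the study's class
composition), lengths 100–400, `p_medium` 0.25 (acid) vs 0.40 (alkaline).
Uniform within-pool draws keep the class-conditional medium-residue count
exactly Binomial(L, p_medium), so the optimal accuracy of the composition
statistic has a closed form: with class priors proportional to class sizes,
`Σ_k max(w_a·Binom(k; L, p_a), w_b·Binom(k; L, p_b))`, evaluated by exact
enumeration at a representative length (default: the range midpoint).

What passing tests on this generator do **not** show: real enzymes have
correlated residues, non-uniform background composition, secondary
structure and homology structure; the 0.15 probability gap is an idealised
effect. Recovery results here demonstrate the pipeline's correctness and
statistical behaviour, not real-data accuracy; in particular the ~99%
single-feature accuracy on synthetic data is a property of the planted
effect size, deliberately strong enough to exercise the
"one-good-feature" regime while remaining imperfect.

## Numerical and design choices

* All randomness (generation, fold shuffling, forest seeding) flows from
  one master seed; reports contain no timestamps, so identical config +
  seed reproduces every output byte for byte.
* Non-standard residues: strict mode rejects the record naming it and the
  residue; lenient mode drops the residues with a warning. How ambiguous
  residues were handled in the original data is unknown, so both are
  offered; strict is the default.
* Sequences shorter than 100 residues are dropped before analysis
  (configurable); the generator's minimum length is 2 (bivalent
  frequencies need `L − 1 ≥ 1`, cross-covariance needs `L > LG`).
* The "best single feature" reported by the pipeline is the selected-subset
  member with the highest single-feature CV accuracy, ties broken by MRMD
  rank — the ranking criterion and the wrapper already define both orders,
  so no new tunable is introduced.
* Problem sizes used by the test-suite simulations: 100 replicates of
  n = 60 + 60 for planted-feature ranking recovery, 10 replicates for the
  Bayes-oracle comparison, 25 for null controls, and one 122-sequence run
  for pipeline-level checks — sizes at which the binomial expectations are
  sharp while the whole suite stays fast.

## Known limitations

* The ≤25%-pairwise-identity redundancy filter used to curate the original
  data is out of scope; inputs are assumed pre-deduplicated.
* The non-hydrophobicity property partitions and the CC index tables are
  canonical reconstructions — the configuration the dimensioning implies —
  not values printed in the motivating study; results on real data can
  shift with other tables (all are overridable from YAML).
* No attempt is made to reproduce Weka's tree construction or its exact
  reported numbers; classifier behaviour follows scikit-learn.
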