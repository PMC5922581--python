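# Methods

## Problem setting

Two-class expression studies routinely pair very few samples
(N ≈ 50–150) with very many features (d ≈ 10,000–55,000). `rpgp`
implements a two-stage classifier for this regime:

1. **Random projection (RP).** The d-dimensional expression profiles are
   mapped through the origin to a k-dimensional latent space (k ≪ d) with
   a random matrix R ∈ ℝ^{k×d}:

       X_rp = R · X,        X ∈ ℝ^{d×N}

   The default scheme draws R's entries i.i.d. standard normal and
   rescales every column to unit Euclidean length; a sparse
   Achlioptas-style scheme (entries √3·{+1, 0, −1} with probabilities
   1/6, 2/3, 1/6) is available as an alternative. R depends only on
   (k, d, seed, scheme), never on the data, so one R may be applied to
   the training and test samples of a fold without information leakage.
   With unit-norm columns, E‖Ru‖² = ‖u‖², so pairwise distances are
   approximately preserved without any rescaling factor
   (Johnson–Lindenstrauss behaviour; the relative spread of distance
   ratios is ≈ √(2/k)).

2. **Genetic-programming (GP) classifier.** A program is an arithmetic
   expression tree: internal nodes from {+, −, ×, ÷}, leaves are feature
   indices (constructed RP features or raw features). A sample is
   assigned the positive class iff the program output is ≥ 0. Programs
   are evolved generationally; the fitness of a program is the
   standardized Matthews correlation coefficient of its training-set
   predictions:

       MCC = (Ntp·Ntn − Nfp·Nfn) / √((Ntn+Nfn)(Ntn+Nfp)(Ntp+Nfn)(Ntp+Nfp))
       fitness = (1 + MCC) / 2 ∈ [0, 1]

   with MCC defined as exactly 0 when the denominator vanishes. MCC is
   the Pearson correlation of the 0/1 prediction and truth vectors, which
   makes it robust to class imbalance — important because several of the
   motivating datasets are strongly imbalanced (e.g. 64 vs 12).

## Evolutionary loop

* **Initialization** — ramped half-and-half: ramp depths cycle uniformly
  over 2–8; within each depth level individuals alternate between the
  *full* method (all leaves at the ramp depth) and the *grow* method
  (internal node with probability 0.5 per node, re-drawn until the tree
  reaches at least depth 2).
* **Selection** — tournament of size 7 drawn uniformly with replacement;
  ties broken uniformly at random.
* **Variation** — per offspring an exclusive choice: subtree crossover
  with probability 0.8, subtree mutation with probability 0.2, else
  reproduction. Crossover children deeper than the cap are rejected and
  redrawn up to 10 times, then the first parent is copied. Mutation grows
  the replacement subtree within the remaining depth budget, so its
  output always respects the cap.
* **Elitism** — the single best individual (ties broken uniformly) is
  copied unchanged, making the best-fitness trace non-decreasing.
* **Termination** — a fixed number of generations. `evolve` evaluates the
  initial population and then performs `max_generations` generational
  updates; the trace has `max_generations + 1` entries.

Default configuration: population 1024, tournament 7, crossover/mutation
0.8/0.2, tree depth 2–8 at initialization and as a hard cap, one elite,
50 generations. The depth range doubles as initialization ramp and hard
cap; with binary nodes this bounds programs at 2⁹−1 = 511 nodes. A
reduced profile (`DESK_PROFILE`: population 256, 30 generations) is
bundled for desk-scale experiments and is what the test-suite and the
acceptance script use; the full profile is the default for real runs.

Numerical conventions (closure): division is protected — a ÷ b = 1
whenever |b| < 1e-9, the canonical GP convention that keeps every program
total; non-finite intermediates arising from float overflow (possible in
deep × chains) propagate and the final program output is mapped
NaN → 0, ±inf → ±1e300, so classification is always defined. All
randomness in a run flows from a single seeded generator; identical
configuration and seed reproduce the identical best program bit for bit.
Fitness values are memoised by tree identity and subtree outputs are
memoised per generation — pure optimizations that do not affect results.

## Performance measures

Following the convention of the benchmark design this package
reproduces:

* training accuracy = MCC × 100 (may be negative; it is *not* a percent
  correct — a plain `percent_correct` is exposed separately for sanity
  checks);
* test accuracy = balanced accuracy × 100 = 50·(Ntp/(Ntp+Nfn) +
  Ntn/(Ntn+Nfp)), which requires both classes in every test fold —
  hence stratified folds are mandatory in the harness.

## Experimental harness

Stratified 10-fold cross-validation (delegated to scikit-learn's
`StratifiedKFold`, shuffled and seeded: per-fold class counts are within
one of proportional), repeated `n_repeats` times; repeat r uses seed
`base_seed + r`. Per repeat one projection matrix per target dimension is
built from the repeat seed and shared by all folds (R never sees the
data; per-fold regeneration is available by flag). Baselines — decision
tree, Gaussian naive Bayes, k-nearest neighbours (k = 3), SVM (RBF),
random forest — use scikit-learn defaults otherwise. Every
(classifier, rp_dim, repeat, fold) record is retained so all summaries
(mean ± sample SD pooled over repeats and folds) are recomputable from
the raw records.

## Synthetic data generator

The generator emulates the shape of two-class microarray studies without
modelling probe-level artifacts: a d×N matrix of i.i.d. Gaussian
background noise N(0, noise_sd²), optionally in correlated blocks
(within-block correlation 0.5, marginal variance preserved), with a
planted class signal:

* `linear_shift` — each of `n_informative` randomly chosen features gains
  a mean shift of `effect_size · noise_sd` in the positive class
  (`effect_size` is therefore a per-feature standardized effect, Cohen's
  d). `effect_size = 0` yields the null model: labels independent of the
  data.
* `nonlinear_ratio` — labels are derived from three informative features
  as class = [x_a/x_b − x_c ≥ 0] (same protected-division convention as
  the evaluator), so the ÷ primitive is genuinely required, not just
  linear recovery.

Defaults (n = 100, d = 10,000, 1% informative at effect 1.0, balanced
classes, unit noise) represent a typical moderate two-class contrast.

**What the generator does and does not show.** Gaussian backgrounds keep
closed-form checks possible (e.g. the Bayes error of the shift model is
Φ(−effect·√n_informative/2)), but they deliberately omit properties of
real expression data: heavy-tailed, strictly positive intensities
spanning orders of magnitude; co-expression covariance; batch effects.
This has a consequence worth stating plainly. Under i.i.d. Gaussian
noise, a data-independent projection to k of d dimensions retains in
expectation only k/d of the squared Mahalanobis class separation, and a
projected feature's individual discriminability is
effect·√(n_informative/d)·|z| — never better on average than the raw
informative features it mixes. In this model family, GP on the full
feature set therefore matches or beats GP on projected features at equal
budget, and the package's own experiments on synthetic data reproduce
exactly that. The advantage of projected features reported on real
microarray data must rest on the real-data properties listed above;
passing tests on this generator validate the machinery (projection
geometry, fitness, CV design, reproducibility), not that RP features
improve GP on arbitrary data.

## Design choices and limitations

* Class decision threshold 0 on a signed expression; a constant-zero
  program maps to the positive class (boundary inclusive).
* Orientation of matrices on disk is always explicit, never guessed;
  missing values are a hard error unless per-feature mean imputation is
  requested.
* Generator parameters used in tests and the acceptance script are
  desk-scale (d ≤ 5000, reduced GP budget) so a complete run stays in the
  minutes range on one core; the statistics scale up unchanged.
* Binary classification only; no ephemeral random constants, typed GP or
  multi-class MCC. Heavy-tailed/resampled backgrounds are future work.
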