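# rpgp — random-projection features + genetic-programming classification

`rpgp` classifies high-dimensional, small-sample expression data
(microarray-style matrices with d ≈ 10⁴–10⁵ features and N ≈ 50–150
samples) by first *constructing* a small number of features with a random
projection and then *evolving* an arithmetic program tree that separates
the two classes.

* **Random projection.** X_rp = R·X with a seeded random k×d matrix R
  whose columns have unit length (k ≪ d). R never sees the data, so the
  same R is safely applied to training and test folds.
* **GP classifier.** Programs are trees over {+, −, ×, ÷} with feature
  indices as leaves; a sample is positive iff the program output is ≥ 0.
  Fitness is the standardized Matthews correlation coefficient,
  fitness = (1 + MCC)/2, with MCC := 0 when its denominator vanishes.
* **Benchmark harness.** Stratified 10-fold cross-validation, repeated
  seeded runs, and five reference classifiers (decision tree, naive
  Bayes, 3-NN, SVM, random forest). Training performance is reported as
  MCC×100 and test performance as balanced accuracy×100.
* **Synthetic data generator.** Microarray-shaped datasets with planted
  linear or ratio-rule signal, so the whole pipeline is testable without
  any downloads.

See `docs/methods.md` for the model, conventions (protected division,
depth caps, elitism) and the generator's scope and limitations.

## Worked example

```python
import rpgp
from rpgp.gp import DESK_PROFILE

# synthetic two-class study: 60 samples x 500 genes, 20 informative
m, y, truth = rpgp.generate(rpgp.SyntheticSpec(
    n_samples=60, n_features=500, n_informative=20,
    effect_size=1.5, seed=3))

model = rpgp.RPGPClassifier(m, y, n_components=25, gp_config=DESK_PROFILE)
res = model.fit(seed=0)
print(res.summary())
```

```
RP-GP binary classifier results
===============================================
samples:              60
features:             500
projected dimension:  25
projection scheme:    gaussian_unit_columns
positive class:       case
seed:                 0
generations:          30
population size:      256
-----------------------------------------------
best training fitness ((1+MCC)/2): 0.8550
training MCC:                      0.7099
training accuracy (MCC x 100):     70.99
confusion (tp, tn, fp, fn):        (28, 23, 7, 2)
-----------------------------------------------
best program:
  (sub (add (div x2 x24) (div (add (div x22 (mul (add x10 (add x11 x19)) (add x11 x0))) x16) (sub (div x0 x9) x24))) x24)
```

The fitted program misclassifies 9 of 60 training samples (MCC 0.710)
after projecting 500 genes onto 25 constructed features;
`res.predict(new_matrix)` applies the stored projection and program to
new samples, and `res.trace` holds the per-generation best-fitness curve
(`res.plot_fitness_trace()` plots it if matplotlib is installed).

The same pipeline runs from the shell:

```bash
rpgp simulate --n-samples 100 --n-features 5000 --n-informative 500 \
    --effect-size 0.6 --seed 1 --out data/
rpgp run --matrix data/matrix.tsv --labels data/labels.tsv \
    --positive-class case --rp-dims 50,100,150 \
    --classifiers GP,DT,NB,KNN,SVM,RF --folds 10 --repeats 30 \
    --seed 1 --gp-profile desk --out results/
```

`results/` then contains `records.tsv` (every classifier × dimension ×
repeat × fold), `summary.tsv` (mean ± SD per cell), the best evolved
programs as S-expressions, and `run.log`.

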