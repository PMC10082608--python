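# Methods

## Problem and model

Given a matrix of steady-state expression values `x[s, g]` for `S` samples
and `G` genes, the goal is a directed, confidence-ranked list of regulatory
edges TF → target, where the candidate regulators are a supplied list of
transcription factors (or, absent such a list, all genes). Inference is
decomposed gene by gene: for each target `g`, predict its expression from
the candidate TFs (excluding `g` itself — self-regulation is never scored)
and read each candidate's importance in that regression as the confidence
of the corresponding edge. No assumptions are made about dynamics or
perturbation design; time information is not used, and edge direction
beyond the TF → gene restriction is not identifiable from steady-state
data alone.

Three importance scores are computed per (candidate, target) pair:

1. **Random-forest Shapley** `phi(R)` — fit a random-forest regressor
   (mean-squared-error split criterion), then compute per-sample Shapley
   values of each candidate and summarize them as the mean absolute value
   across samples.
2. **Extra-trees Shapley** `phi(E)` — the same with an
   extremely-randomized-trees regressor.
3. **Subsampled linear-SVR coefficients** `C(SV)` — tune `(C, epsilon)`
   once per target by Bayesian optimization of 5-fold cross-validated MSE,
   then repeat 200 times: draw `r` rows uniformly between 20% and 80% of
   the samples without replacement, standardize features and response on
   the subsample, fit a linear epsilon-insensitive SVR, and add the
   absolute coefficients of the 5 highest-|coefficient| candidates to a
   running total.

Each method's regulator × target matrix is min-max normalized to [0, 1]
and the three are combined elementwise by the weighted mean

    R = (w1 * phi(R) + w2 * phi(E) + w3 * C(SV)) / (w1 + w2 + w3),

with default weights `(1, 0.5, 0.1)`; a weighted mean is invariant to
rescaling all weights, so the 10 : 5 : 1 ratio is the same configuration.
A two-method mode drops the SVR branch (and its weight) entirely when its
cost is unwanted. Final scores are z-scored over the population of
candidate edges — `(R - mu) / sigma` with the population (n-denominator)
standard deviation, a monotone transform that aids interpretation without
altering the ranking — and the edges are sorted descending, ties broken
lexically by (regulator, target), truncated to the top 100 000.

## Shapley values: exact interventional computation

The Shapley value of feature `j` for a model `f` at a point `x` is

    phi_j = sum over S subseteq F\{j} of
            |S|! (p - |S| - 1)! / p! * (nu(S + j) - nu(S)),

with the interventional value function
`nu(S) = mean_b f(x_S, b_{S^c})` over an empirical background `b` (the
training rows, capped at 50 evenly spaced rows by default). For tree
models this package computes `phi` **exactly** rather than by sampling:
for a single (x, b) pair, the game decomposes over leaves; a leaf is
reachable iff every feature on its root-to-leaf path is satisfied by `x`
or by `b`, and its indicator game depends only on the counts `k` (features
satisfied by `x` alone) and `m` (by `b` alone), giving per-feature weights
`(k-1)! m! / (k+m)!` for x-side features and `-k! (m-1)! / (k+m)!` for
b-side features. A numba kernel walks each tree once per (sample,
background) pair, pruning branches neither point can enter; factorial
ratios are precomputed in log space so arbitrarily deep trees cannot
overflow. Forest attributions are the mean of per-tree attributions,
matching the ensemble's mean prediction, and satisfy the efficiency
identity `sum_j phi_j + mean_b f(b) = f(x)` to float round-off.

A brute-force enumeration oracle (`agrn.shapley.exact_shapley`, feasible
to p = 12) evaluates the same game through `model.predict` on composite
rows; the test suite holds the kernel to within 1e-6 of it.

The per-candidate summary of the signed per-sample values is
`mean(|phi|)` by default (the standard global-importance reduction, and
nonnegative as the ranking requires); `mean` and `max(|.|)` are available
behind the `aggregation` configuration key.

## SVR branch details

The linear SVR is scikit-learn's libsvm-based `SVR(kernel="linear")`,
i.e. the epsilon-insensitive dual formulation; coefficients enter the
score as absolute values, since the ranking concerns edge confidence,
not sign. Features and the response are standardized inside every
subsample fit — linear-SVR coefficients are scale-dependent, and
standardization makes them comparable across candidates. The same
standardization (of the full data) is applied for the hyperparameter
search objective. Solver effort is capped at `max_iter = 100 000`
iterations per fit: at large `C` with tiny `epsilon` the dual solver's
convergence time grows without useful gain in the coefficient ranking.

The `(C, epsilon)` search is a small in-package sequential model-based
optimizer: a Gaussian-process surrogate (Matern 5/2, normalized inputs
and outputs) with expected-improvement acquisition over random candidate
draws, run in log10 space over `C in [1e-2, 1e3]`,
`epsilon in [1e-3, 1]`, 20 objective evaluations. The anchor point
`(C=1, epsilon=0.1)` is always evaluated first, so the returned pair is
never worse than the anchor on the same folds; a constant response
returns the anchor with a warning. Ties in the top-5 coefficient cut are
broken by candidate identifier for determinism.

## Seeding and parallelism

A master seed governs the run. Each target's seed is derived by hashing
(master seed, target name), and every stochastic element of that target's
scoring (forest fitting, subsample draws, optimizer draws) streams from
it. Results are therefore independent of the order in which targets are
processed and of the worker count; `simulate → infer → evaluate` is
byte-reproducible under a fixed seed. One caveat, inherited from the
delegated CART implementation: the tree learner breaks split ties by a
randomized feature visit order, so tree importances are equivariant under
candidate column permutation only statistically (same winner, close
values), while the SVR branch is equivariant to solver round-off.

## Evaluation protocol

The pair universe is every (TF, gene) pair with TF ≠ gene. Gold-standard
pairs labeled 1 are positives; explicit 0 rows and absent pairs are
treated identically as negatives. Edges missing from a prediction list
rank strictly below all predicted edges as one exchangeable group:
unretrieved positives depress recall and cap the ROC curve's final
ascent, so truncation cannot inflate either metric. AUROC is computed in
Mann-Whitney form with midranks (tied scores step jointly — the average
over tied orderings). AUPR is the average-precision step sum
`sum_i (R_i - R_{i-1}) * P_i` over tied groups with no interpolation,
because trapezoidal PR area is a known overestimate. Both metrics are
oracle-checked against a concordant-pair count and a hand step sum.

## Synthetic data generator

The generator emulates multifactorial steady-state expression: a sparse
directed acyclic network whose regulated genes are noisy linear functions
of their regulators. Genes are ordered; the first `n_tfs` are TFs; each
eligible (TF u, gene v) pair with index(u) < index(v) receives an edge
independently with probability `edge_density`, weighted ±uniform(0.5, 1.5)
× `effect_scale`. Root genes draw i.i.d. standard-normal values; a
regulated gene is the weighted sum of its parents plus Gaussian noise of
s.d. `noise_sd`. One topological pass simulates a sample, so a unit-weight
edge with noise s.d. σ has population correlation 1/√(1+σ²) — an
analytically checkable signal used in the tests.

Defaults — 20 genes, 5 TFs, density 0.3, effect scale 1, noise s.d. 0.1,
200 samples — describe a small network whose structure is recoverable but
not trivial (correlated TFs, indirect paths, reversed-direction decoys).
What the generator does **not** emulate: nonlinear or saturating
kinetics, feedback loops, ODE-based dynamics, measurement-specific noise
(counts, dropout), or the connectivity statistics of curated benchmark
networks. Passing the recovery tests therefore shows the pipeline
recovers linear-Gaussian structure at moderate noise — not that it
attains any particular accuracy on real or mechanistically simulated
expression data.

## Numerical and design choices

* **Normalization before combination.** Shapley summaries and summed SVR
  coefficients live on incommensurate scales; without per-method min-max
  normalization the ensemble weights would be meaningless. This global
  (whole-matrix) rescaling is a documented choice; pass
  `normalize=False` to `infer_network` for sensitivity analysis.
* **Population standard deviation in the z-score** — the scores form a
  complete finite population, and the ranking is unaffected either way.
* **Gold standards with positives only** — absent pairs are implied
  negatives; explicit 0 rows are accepted and equivalent.
* **Constant inputs** degrade softly: a constant response yields zero
  importances with a warning; a constant importance matrix normalizes to
  zeros with a warning; a zero-spread ensemble matrix cannot be ranked
  and raises.
* **Degenerate subsample bounds** (too few samples for the 20–80% window)
  raise with the minimum sample count named.
* **Problem sizes in the test suite and acceptance script** — recovery
  runs use the default study conditions above, median over 5 replicate
  seeds; oracle checks use 50-sample single trees of depth ≤ 3 with
  p ≤ 5, where enumeration is exact and fast.

## Known limitations

* Steady-state data cannot orient edges between correlated TFs; reversed
  pairs of true edges are the dominant false positives.
* The exact Shapley kernel's cost grows with background size × samples ×
  leaves; for thousands of genes, lower `shap_background` and `n_trees`
  or use the two-method mode with fewer trees first.
* The GP optimizer proposes from random candidate draws; with 20
  evaluations on a 2-D box this is adequate, but it is not a general
  global optimizer.
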