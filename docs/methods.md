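# Methods

## The optimizer

ALA maintains `N` agents in a box `[lb, ub] ⊂ R^dim` and minimises a
black-box objective over `Tmax` iterations. Per agent and iteration an
energy factor `E = 4 (1 − t/Tmax) ln(1/rand)` is drawn (the degenerate
`rand = 0` draw is resampled); while `E > 1` the agent explores — with
probability 0.3 a migration step
`z_best + F·BM ⊙ [R ⊙ (z_best − z_i) + (1 − R) ⊙ (z_i − z_a)]`
(`BM` standard normal, `R` uniform on [−1, 1], `z_a` a random agent),
otherwise a digging step `z_i + F·L·(z_best − z_b)` with
`L = rand·(1 + sin(t/2))` — and once `E ≤ 1` it exploits: with
probability 0.5 a spiral foraging step `z_best + F·spiral·rand·z_i`
(`spiral = r·(sin 2πθ + cos 2πθ)` on the radius `r = ‖z_best − z_i‖`),
otherwise a Lévy-flight evasion step `z_best + F·G·Levy ⊙ (z_best − z_b)`
with escape coefficient `G = 2 (1 − t/Tmax)`. The direction flag `F` is ±1
with equal probability. Lévy steps use the Mantegna sampler with exponent
β = 1.5 (σ ≈ 0.6966): normal numerator over `|normal|^(1/β)`, scaled by
0.01. A config switch `levy_uniform_uv` instead draws the two factors
uniform on [0, 1] — an alternative literal reading of the sampler that
loses the sign symmetry — and is off by default because the σ constant is
specific to the normal-draw scheme.

Positions are clamped to the box after every move (the simplest boundary
rule; it preserves best-so-far monotonicity). Agents adopt their new
position unconditionally while the global best is tracked greedily with
strict-improvement ties broken toward the incumbent; a
`greedy_agent_update` flag switches to per-agent greedy acceptance for
sensitivity checks. Initialisation is the standard uniform draw
`lb + rand (ub − lb)`. Non-finite objective values are treated as +∞.

**AHALA.** Every `k`-th iteration the incumbent best (default; `n_elite`
top agents optionally) is refined by adaptive hill climbing: `M` trials of
`x' = x + α δ ⊙ (ub − lb)`, `δ ~ U(−1, 1)`, strict-improvement acceptance,
`α ← β α` on rejection, `α` reset to `α₀` at each invocation. The step is
scaled per dimension by the bound range because the search spaces of
interest span ranges as different as [0.0001, 0.01] and [64, 512]; an
absolute step would be meaningless across them. Defaults: `k = 10`,
`M = 10`, `α₀ = 0.01`, `β = 0.9` (the decay value is a free choice,
exposed in config). Budget accounting is exact:
`N (Tmax + 1)` evaluations for ALA plus `⌊Tmax/k⌋ · M · n_elite` for the
refinements, and with `k > Tmax` the hybrid consumes no extra random draws,
so its trace is bit-identical to plain ALA under a shared seed.

One seeded `numpy` generator drives each run; multi-run experiments use
seeds `base + run index` (base 42 by convention) so trials are paired
across algorithms.

## Comparison statistics

The signed-rank test is exact: zeros are discarded, absolute differences
receive average ranks under ties, and the null distribution of the
positive-rank sum is enumerated by dynamic programming over all 2^n sign
assignments, conditioned on the observed rank multiset, in exact integer
arithmetic. The two-sided p is `min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. With
all n differences of one sign this gives `2·2⁻ⁿ` — 1.86×10⁻⁹ at n = 30,
0.0020 at n = 10 — values a normal approximation cannot reproduce. An
all-zero difference vector raises an error rather than reporting a
degenerate p. Friedman mean ranks are computed per function (rank 1 =
best, minimisation, ties averaged) and averaged across functions.

"Diversity" is defined here as the mean Euclidean distance of agents from
the population centroid, with exploration% = 100·div/running-max and
exploitation% its complement; this is the package's own definition of an
otherwise loosely specified diagnostic, not a reproduction of any
particular one.

**Equal-budget comparisons.** When the hybrid is compared to plain ALA "at
equal budget" the total number of objective evaluations is fixed and the
hybrid's iteration count is reduced to fit under it (e.g. ALA at
Tmax = 200 spends 6030 evaluations; AHALA at Tmax = 193 with k = 10,
M = 10 spends 6010). The hybrid is never granted more evaluations than the
baseline, so any advantage it shows is conservative.

## The subtyping pipeline

Raw expression must be nonnegative. Preprocessing drops zero-variance
genes and applies `log2(x + 1)`; an optional low-variance quantile filter
exists but is off by default. Differential expression runs one contrast
per unordered class pair (10 for five classes): per gene, log2FC is the
mean difference on the log2 scale and the p-value comes from Welch's
unequal-variance two-sample t; Benjamini–Hochberg is applied within each
contrast and a gene is selected when adjusted p < 0.05 and |log2FC| > 1 in
at least one contrast (union across contrasts). This self-contained
statistic is a deliberate design choice; a moderated empirical-Bayes
linear model shares variance information across genes and can select a
slightly different gene set on identical thresholds, so selected-gene
counts from this package are not expected to match analyses built on such
models. Genes whose statistic is undefined (both groups constant) get
p = 1.

The split is stratified 80/20 with labels encoded 0..K−1 in lexicographic
order (cross-run stability) and standardisation fitted on the training
portion only. On the 231-sample study shape this yields 184 train / 47
test with every class's training share within one sample of 80%.

**Classifier and fitness.** The classifier is a feed-forward network:
three fully connected extractor layers of widths (h, h/2, h/4) with ReLU,
then a two-layer head (h/4 → h/4 → K). The widths and activation are a
fixed design choice exposed in the training code. Training uses Adam with
cross-entropy, minibatches of the decoded batch size (capped at the
training-set size), at most 100 epochs, early stopping on validation
log-loss with patience 10 and best-weight restoration. The AHALA fitness
of a hyperparameter vector (learning rate ∈ [0.0001, 0.01] continuous;
batch size ∈ [16, 128] and hidden size ∈ [64, 512] rounded to integers
after clamping) is the validation accuracy, negated internally for the
minimisation convention. The fitness uses a single stratified validation
fold (20% of the training portion) rather than k-fold cross-validation —
one training per evaluation keeps the tuning budget linear in `N·Tmax`.
If the narrowest layer h/4 would fall below the class count, h is widened
with a warning. The held-out test set is touched once, after tuning.

Evaluation is one-vs-rest per class: TPR, FPR, precision, F1 from the
confusion matrix, overall accuracy as the trace fraction, per-class ROC
AUC and average precision with macro averages, and a micro-averaged PRC
over the flattened one-hot scores. Classes absent from the true labels
report NaN. Feature importance is permutation importance — the mean
validation-accuracy drop over repeated shuffles of one feature — chosen as
a simple model-agnostic ranking. External cohorts missing some features
are completed by label-specific median imputation from the reference
cohort (each missing cell gets the median of that feature over reference
samples of the same class).

## Synthetic data

The generator emulates the study-shaped table: five classes with counts
86/39/24/41/41 (231 samples) by 588 features. On the log2 scale each value
is `baseline + shift + N(0, dispersion)` where each class owns a disjoint
block of `n_informative` genes (default 20) shifted by ±`effect` with
alternating sign; values are back-transformed by `2^v − 1` floored at
zero. Since the pipeline re-applies `log2(x + 1)`, planted fold changes
survive the round trip exactly except for the rare floor truncation.
Defaults: baseline 6.0 (a typical log2 expression level), effect 2.0 and
dispersion 0.5 ("strong" preset — separable classes), with "null"
(effect 0) and "paper-shape" (effect 1.5, dispersion 1.0) presets. The
log-normal-style model gives analytic control of the planted log2FC; it
does not emulate count overdispersion, platform batch effects,
inter-feature correlation or microarray/RNA-seq distribution shift, so
passing recovery tests demonstrate correctness of the machinery, not
expected performance on real cohorts.

## Problem sizes in the shipped checks

The test suite and the acceptance script keep runs deliberately small: the
2-D sphere with N = 30 and Tmax ≈ 200 over 10 matched seeds for
convergence checks, the 231 × 588 synthetic table for pipeline checks, and
a reduced tuning budget (population 10, 20 iterations ⇒ 230 network
trainings) for the end-to-end run. These sizes were chosen so a complete
verification pass finishes in minutes on one CPU while still exercising
every stage at the study's data shape.

## Known limitations

* The Welch-t differential expression is not a moderated model (see
  above); with very few samples per class its variance estimates are
  noisier.
* Hill climbing refines only around the incumbent best; on landscapes
  where the best basin is thin its `M` trials may all be rejected and the
  refinement contributes nothing (its cost is still spent).
* The fitness is plain validation accuracy, which can be insensitive
  under heavy class imbalance; the post-hoc one-vs-rest report is the
  balance check.
* `MLPClassifier`-based training is single-threaded and CPU-only; very
  large hidden sizes are supported but slow.
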