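# Methods

## Problem and model

driverank estimates, for every gene altered in a tumor or cohort, the
probability that it is a cancer driver in a specific cancer type. The
estimate comes from a multi-task logistic classification model — one
task per cancer type — over 26 gene-level features, with joint lasso
regularization so tasks share a sparse feature support:

    min_W  Σᵢ L(Wᵢ | Xᵢ, Yᵢ) + λ₁ ‖W‖₁ + λ₂ ‖W‖²_F

`W` is p × t (features × tasks), `L` the logistic loss over a task's
genes with labels +1 (driver) / −1 (non-driver). The λ₁ term induces
exact zeros shared across tasks; the λ₂ term stabilizes the solution
and bounds it when classes are (near-)separable.

### Conventions the equation leaves open

These are explicit `MTLConfig` options; defaults in bold.

- **Per-task mean loss** (not sum), so tasks with unequal gene counts
  contribute comparably to the joint objective.
- **Intercept on**: a constant-1 column is appended per task; its row is
  exempt from the L1 penalty but kept in the Frobenius term. Driver
  labels are heavily imbalanced (~15% positives), and without an
  intercept the fit forces feature coefficients to act as a
  pseudo-intercept, which roughly halved held-out AUC in our cohort
  simulations. With the intercept disabled the objective is exactly the
  displayed equation.
- **No feature standardization** by default; a switch enables z-scoring
  with parameters stored on the model.

## Solver

Monotone accelerated proximal gradient (FISTA with backtracking line
search). The smooth part (losses + Frobenius term) is handled by
gradient steps from the extrapolated point; the L1 part by its
closed-form prox, the soft threshold sign(x)·max(|x|−τ, 0). If the
accelerated candidate would increase the objective, the iteration falls
back to a plain proximal step from the current iterate, so accepted
iterates never increase the objective. The step size shrinks by halving
until the quadratic majorization holds and is allowed to grow again
between iterations.

Convergence requires both a relative objective change below `tol`
(default 1e-10) and a sup-norm proximal-gradient mapping below `gtol`
(default 1e-7). The objective-change test alone can trigger on flat
directions while coefficients are still moving; the gradient-mapping
test makes the stop a genuine first-order criterion. On a 200 × 26
logistic task this yields agreement with an L-BFGS fit of the same loss
to ~1e-4 in sup-norm. Near-separable fits with tiny λ₂ may legitimately
hit the iteration cap (default 10 000); the model then carries a
non-convergence warning rather than raising — predictions are accurate
long before coefficient drift stops.

`lambda1_max` computes the smallest λ₁ at which the penalized block is
exactly zero: the sup-norm of the smooth-part gradient at W = 0, after
first optimizing the (unpenalized) intercept row alone when present.

## Penalty selection

- λ₂: grid search maximizing pooled AUC on a held-out validation task
  set; ties go to the smaller value.
- λ₁: tenfold cross-validation, stratified within each task. Per fold,
  one model per grid value is fit on the training portions and held-out
  predictions are pooled across tasks into a single AUC. The shipped
  selection applies the **one-standard-error rule**: the largest λ₁
  whose mean fold AUC is within one SE of the maximum. The
  AUC-maximizing λ₁ systematically under-penalizes — held-out ranking
  is nearly insensitive to small coefficients on noise features — and
  keeps ~20 of 21 noise features in our recovery simulations, whereas
  the 1-SE choice recovers the true support with ≤ 1 false feature.
  `rule="max"` restores the literal argmax.
- Default grid: 10⁻⁶…10² at three points per decade. Shipped defaults
  when selection is skipped: λ₁ = 10⁻⁵, λ₂ = 10⁻⁴.

Per-task probability thresholds are selected on validation genes by
exhaustive scan over the unique predicted probabilities, their
midpoints, and {0, 1}, maximizing accuracy; ties break toward the
larger threshold (fewer driver calls). Classification is driver iff
probability ≥ threshold (inclusive).

## Features

Fixed 26-column order, serialized with every model:
`max_coding_impact`, `max_noncoding_impact`, `scna_proxy_density`,
`hotspot_or_double_hit`, `prior_gene_score`, then 21 pathway
memberships in gene-set file order.

Threshold semantics (config-overridable defaults):

| rule | default | strictness |
|---|---|---|
| segment coverage of gene for an SCNA call | 0.25 | ≥ (non-strict) |
| amplitude filter on gene-level \|log2\| | 0.25 | dropped only when strictly below |
| hotspot catalogue occurrence | 5 | strictly greater |
| homozygous loss gene-level log2 | −1 | strictly below |

The loss rule is often quoted in the literature as "|log2 ratio| < −1",
which is unsatisfiable as written; it is implemented as log2 < −1. Coverage is
overlap length divided by gene length. The gene-level log2 is that of
the covering segment with maximum |log2| (ties: first in genomic
order). Genes on sex chromosomes are excluded from SCNA calls. When
several direction-matched minimal common regions overlap a gene, the
one with the largest overlap wins (ties: genomic order). Missing score
features fill with 0 — absence of evidence maps to the minimum of each
score's range. Scores enter models raw; the prior gene score and Phred
columns are not rescaled.

Double-hit semantics in batch mode default to the cohort-level
conjunction (any patient's non-synonymous variant plus any patient's
homozygous loss); a config switch restricts both hits to the same
patient, which is also the natural semantics in personalized mode. The
gene universe is the altered genes (variants or retained SCNA calls);
unaltered genes are not scored.

Coordinates: intervals are 0-based half-open internally (SEG and MCR
tables are 1-based inclusive on disk and converted on read/write);
variant positions stay 1-based points. Missing cells read as "." or
"NA", written as ".".

## Metapredictor

Six families (logistic, Gaussian naive Bayes, linear and RBF SVM,
random forest, gradient boosting) behind one interface; random forest
is the default. Hyperparameter grids are deliberately small (2–4
configurations per family) to keep repeated CV affordable; selection
uses tenfold 3-times-repeated stratified CV maximizing AUC, then a
refit on the full training set. Class imbalance is left unweighted and
scores unscaled. A variant with any missing score gets a missing
prediction — the feature builder, not the metapredictor, decides the
fallback (fill 0 at the gene level).

## Evaluation

AUC is rank-based (Mann–Whitney with average ranks), so ties count
half; it equals brute-force pair counting to 1e-12 and is invariant
under strictly monotone score transforms. Negatives are all scored
genes outside the truth set. Units where only one class is present
(common in per-patient evaluation, where a patient's few altered genes
may all be known drivers) have an undefined AUC: reported as NaN,
excluded from medians, and counted in a degenerate tally.

## Synthetic data

The generators provide every pipeline input with controlled structure;
one root seed derives fixed per-generator substreams, so adding a
generator never perturbs existing fixtures.

- **Metapredictor benchmark shape**: 12 scores from a one-factor model
  (loadings 0.40–0.80 on a latent pathogenicity trait), labels from a
  logistic model on a weighted score combination with an intercept
  giving roughly a 6:1 non-neutral:neutral balance (~950 usable rows
  of 1100 at the default 2% cell missingness), plus a 10% "uncertain"
  class to exercise the training-set filter.
- **Genomics cohort** (defaults: 200 genes, 20 patients, 3 cancer
  types, 15% driver genes): drivers receive — in proportion to a single
  `signal_strength` dial s — an elevated latent pathogenicity on coding
  variants (+2.5 s SD), higher non-coding Phred scores (+8 s), larger
  occurrence counts (Poisson 0.5 + 5 s), more frequent high-amplitude
  copy-number events whose direction matches an overlapping minimal
  common region with probability s, larger prior scores, and enriched
  pathway membership (0.08 + 0.15 s). At s = 0 every mechanism
  collapses to the passenger rates: drivers and passengers are
  exchangeable, the null against which the pipeline should score at
  chance.
- **Multi-task datasets**: standard-normal features, a shared 5-feature
  support with ±20% task-specific jitter (sign-preserving), labels
  from sigmoid(Xw / noise_sd).

What the generators do **not** emulate: real mutational signatures,
gene-length and pathway-size distributions, correlated copy-number
geometry along chromosomes, annotation errors, or cohort batch
effects. Passing tests therefore demonstrate correctness of the
machinery and recoverability of a planted signal — not clinical
performance on real tumors.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale defaults: metapredictor runs on
the 1100-variant benchmark shape; solver-oracle comparisons on one
200 × 26 task; support recovery on 5 tasks × 500 genes; end-to-end
cohort runs on 1000 genes × 20 patients × 3 cancer types (the larger
gene universe keeps the null-AUC sampling error near 0.04, so
chance-level behavior is a meaningful assertion); personalized
evaluation over 20 patients.

## Known limitations

- The prior gene-score stage and variant annotation are consumed as
  inputs, never computed; garbage in, garbage out.
- Only the lasso multi-task structure is implemented (no L21, trace
  norm, or graph regularizers).
- Thresholds maximizing accuracy can sit at 1.0 when validation
  positives are rare and inseparable — then no gene is called driver,
  which is the correct reading of "no call clears the bar".
- No genome-build liftover; all inputs must share one build.
- `stratified_split` uses round-half-even on the per-class train count.
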