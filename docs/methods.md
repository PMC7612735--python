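# Methods

## Model

`sctyper` annotates single cells with types from a controlled vocabulary using
multinomial (softmax) logistic regression on log-normalized expression. For a
cell with expression vector x over G genes and K candidate types, the class
probabilities are

    P(y = k | x) = softmax(W x + b)_k,

and training minimizes the penalized objective

    L(W, b) = (1/n) Σ_i cross-entropy(y_i, softmax(W x_i + b)) + (λ/2) ‖W‖²,

with unpenalized intercepts b. The multinomial form (rather than one-vs-rest)
was chosen so each cell gets a single normalized probability vector — the
row-sums-to-one invariant is checked in the tests and drives the "Unassigned"
confidence thresholding. One-vs-rest would give uncalibrated, non-competing
scores per class.

### Optimization

The objective is minimized by mini-batch stochastic gradient descent: cells
are reshuffled every epoch (seeds derived deterministically from the run
seed), cut into consecutive blocks of `batch_size`, and one gradient step is
taken per block. The remainder block is kept — dropping cells to make batches
exactly equal would discard data for no statistical gain. The step size
follows the inverse-scaling schedule η_t = η0 / (1 + λ·η0·t) over the global
update count t (a constant schedule is available).

Defaults: `batch_size = 1000`, `epochs = 100`, `λ = 1e-4`, `η0 = 0.02`.
At λ = 1e-4 the schedule decays very slowly, so η0 effectively sets a constant
step size and must sit below the stability limit of the loss curvature.
log1p-CP10K rows of a few-thousand-gene panel have squared norms in the
thousands, which makes η0 = 0.1 divergent (the per-update loss grows without
bound); η0 = 0.02 converges on every dataset scale exercised here, and 100
epochs bring the SGD iterate close enough to the full-batch optimum that
argmax predictions agree with an L-BFGS reference minimizer of the identical
objective on ≥ 99% of cells (checked in the acceptance suite). Both are
ordinary config fields, not constants.

### Two-round training and markers

Training runs twice. Round 1 fits on all genes. For each class, the genes with
the `n_top_genes` (default 300) largest **signed** weights are taken — signed,
not absolute, because a marker is a gene whose *elevated* expression
characterizes the type; large negative weights mark genes whose absence is
informative, which is not what "marker" means in this field. The union of the
per-class top genes, kept in original gene order, becomes the feature set for
round 2, and the round-2 model is what is serialized and used for prediction.
Ties in the ranking are broken by gene order and argmax ties by class order,
so every code path is deterministic. The same per-class ranking, restricted to
the final model, is exposed as `extract_markers`.

### Prediction across gene universes

A query dataset rarely shares the training gene universe. Queries are
reindexed onto the model's feature list: shared genes keep their values,
model genes missing from the query are zero-filled, extra query genes are
dropped. The overlap fraction |query ∩ model| / |model| is logged, warns below
0.5, and errors at 0 — zero-filling a handful of genes degrades gracefully
(the robustness test quantifies this), but predicting with no shared genes is
meaningless. Gene identifiers are matched by exact string equality; symbol
harmonization is a curation problem upstream of this package.

### Model update

`update_model` retrains the two-round fit on the concatenation of the old
corpus and newly curated cells, after validating the new labels against the
label hierarchy. The old corpus's gene universe is kept as the reference and
the new corpus is reindexed onto it (zero-filling genes it lacks), so a
model's feature space stays stable across versions. The version counter
increments and a provenance string is appended on every update, including
no-op updates (an empty new corpus still retrains and re-versions, so the
provenance trail has no silent gaps).

## Preprocessing

QC removes cells with fewer than 1,000 total UMIs or fewer than 600 detected
genes (both thresholds exclusive: a cell exactly at a threshold is retained,
since the rule is "fewer than"). Normalization is counts-per-10,000 followed
by ln(1 + x), applied per cell; all-zero cells are left at zero and flagged
rather than dropped, because dropping is QC's job. The transform is invariant
to uniform scaling of a cell's counts, which is what makes prediction robust
to sequencing-depth differences. No highly-variable-gene restriction or
per-gene standardization is applied before training: feature restriction is
the classifier's own two-round selection, and weights are interpretable on
the shared log1p-CP10K scale.

## Evaluation

Per-class precision, recall and F1 come from the confusion table with the
conventions P = 0 (resp. R, F1) when the denominator is zero. The summary
statistic is the **median** of per-class F1 over classes with nonzero support;
the macro mean is reported alongside. "Unassigned" predictions count as false
negatives for the cell's true class and appear in no class's precision
denominator. The learning curve evaluates the in-progress model on a held-out
stratified split (default fraction 0.1) at every epoch boundary of both
rounds; stratification keeps rare classes evaluable, and classes absent from
the split are excluded from the median with a warning.

## Tissue composition statistics

Counts n(type, tissue, donor) are summarized two ways.

**Proportions.** Within each tissue j (donors pooled), p(t, j) =
n(t, j) / N(j); each type's row is then rescaled to sum to 1 across tissues,
q(t, j) = p(t, j) / Σ_j' p(t, j'). The within-tissue step removes unequal
tissue sampling; the across-tissue step makes types comparable on one scale.

**Enrichment.** For each (type, tissue) pair, the target tissue is compared
against all remaining tissues pooled, with the donor-stratified Poisson model

    log E[n(d, g)] = β0 + γ_d + β1·1[g = target] + log N(d, g),

where g indexes the two groups, N(d, g) is the donor's total cell count in
the group (an offset), and γ_d are donor fixed effects that absorb per-donor
abundance scale so the comparison is within-donor. β1 is the log rate ratio;
the test is one-sided Wald for β1 > 0 (two-sided by flag). Donors with zero
exposure in either group are dropped; fewer than two usable donors makes the
pair not testable. Tissues enter the screen only if at least `min_donors`
(default 2) donors each contribute strictly more than `min_cells` (default
50) cells of the analyzed compartment. All testable pairs in one screen are
Benjamini–Hochberg corrected jointly — one screen is one hypothesis family —
and a pair is flagged when adjusted p < α (default 0.05) with β1 > 0.

**Separation.** When a type is entirely absent from the target group, or
present exclusively in it, the Wald statistic degenerates (|β1| → ∞ with an
exploding standard error). Conditioning on each donor's type total reduces
the model at β1 = 0 to independent binomials Bin(n_d, π_d) with π_d =
N(d, target)/N(d, total), whose one-sided tail is exact at the two boundary
outcomes: p = 1 when the type never occurs in the target, and
p = Π_d π_d^{n_d} when it only occurs there. These exact values replace the
Wald p in the boundary cases, and β1 is reported as the pooled
continuity-corrected log rate ratio. A fully tissue-restricted type — the
planted case in the benchmark — is only detectable at all because of this.

A caution on the donor fixed effects: they absorb donor *scale* in the sense
that donors with identical composition but different sizes yield the same β1;
on heterogeneous tables, rescaling one donor reweights its contribution to
the pooled MLE and β1 moves. This is inherent to maximum likelihood, not a
defect of the stratification.

## Synthetic data generator

The generator emulates the structure the classifier and the composition
statistics assume: each of `n_types` cell types owns a disjoint block of
`markers_per_type` marker genes whose mean is `2^log2_fold_change` times the
shared `base_mean`; counts are gamma-Poisson (negative binomial) with
dispersion α, variance μ + αμ²; cells are laid out by (type, tissue, donor)
with per-combination cell counts; and every donor carries a multiplicative
per-gene lognormal nuisance factor (sd `donor_logfc_sd` in log2 units) so the
composition statistics' donor stratification is exercised against real
between-donor variation. A round-robin two-level hierarchy groups the fine
types. Everything is drawn from a single seeded generator in sorted
combination order, so outputs are byte-reproducible.

The benchmark configuration — the conditions under which the package's
performance numbers are measured — is 10 types in 3 coarse groups, 2,000
genes, 20 markers/type at log2 fold-change 2, dispersion 0.5, base mean 0.5,
3 tissues × 3 donors with 50 cells per (type, tissue, donor), and one type
present only in the spleen as a planted enrichment. That is ~4,200 cells:
large enough for mini-batching and donor stratification to be non-trivial,
small enough that the full suite trains in seconds. These sizes are the
package's own benchmark choice.

What the generator does **not** model: library-size variation between cells,
zero inflation beyond the negative binomial, ambient RNA, doublets, batch
effects, correlated gene programs, or continuous/transitional cell states.
Passing tests therefore demonstrate correctness of the algorithms under a
clean generative model with planted truth — not performance on real tissue
atlases, where label noise, overlapping programs and compositional imbalance
are all harder.

## Numerical choices and degenerate inputs

- Softmax is computed with row-max subtraction; probability rows sum to 1
  within 1e-9.
- Weights initialize at zero; the first SGD step therefore moves along the
  class-mean contrasts, which is why argmax predictions stabilize long before
  the loss fully converges.
- Very large λ shrinks weights multiplicatively by (1 − η_t λ) each step, so
  probabilities collapse toward 1/K as expected from the penalty-dominated
  limit.
- Single-class training data, NaN features, duplicate identifiers, negative
  or fractional counts, and zero gene overlap are all hard errors; all-zero
  cells after normalization and all-cells-removed QC are warnings, not errors.
- Model files are a single JSON object; weights are base64-encoded
  little-endian float64 row-major blocks with the shape recorded, so
  round-trips are bit-exact and independent readers need no binary framing.

## Known limitations

- The enrichment screen's BH family is one screen; running many screens and
  comparing flags across them is uncorrected.
- The Wald test is asymptotic in per-donor counts; with very few cells per
  donor the permutation null (provided as `permute_tissue_within_donor`) is
  the safer reference.
- `update_model` keeps the original gene universe forever; genes measured
  only in later corpora never enter the model.
- Mini-batch SGD with the inverse-scaling schedule at small λ is effectively
  constant-step and will not reach the optimum to arbitrary precision; it is
  an annotation tool, not a convex-optimization benchmark.
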