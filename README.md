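# sctyper

Automated cell-type annotation for single-cell RNA-seq, with cross-tissue
composition statistics.

Annotating cells in large scRNA-seq datasets — especially immune cells, whose
types recur across every tissue — is slow and expert-bound when done by
cluster-and-inspect. `sctyper` trains a multinomial logistic-regression
classifier on a reference corpus of labeled cells and transfers those labels
to new datasets, then asks where each predicted cell type is over-represented
across tissues while controlling for donor-to-donor variation.

The core pieces:

- **Two-round mini-batch SGD logistic regression.** The model minimizes
  softmax cross-entropy + (λ/2)‖W‖² (intercepts unpenalized) by mini-batch
  SGD over shuffled cells. Round 1 fits on all genes; the union of each
  class's top-300 positively weighted genes becomes the feature set for
  round 2. Per-class weights double as data-driven marker genes, and the
  summary accuracy statistic is the median of per-class F1.
- **Donor-stratified Poisson enrichment.** For each (cell type, tissue) pair,
  log E[n(d,g)] = β0 + γ_d + β1·1[g=target] + log N(d,g) over donors d and
  groups g ∈ {target tissue, remaining tissues}; one-sided Wald test for
  β1 > 0 with Benjamini–Hochberg correction across the screen.
- **A seeded synthetic generator** (negative-binomial counts with planted
  marker programs, tissues, donors, and a planted tissue-restricted type)
  that serves as the verifiable test bed for everything above.

The classifier is exposed as a scikit-learn-style estimator
(`CellTypeClassifier`: `fit` / `predict` / `predict_proba`,
`get_params`/`set_params`), so it composes with sklearn pipelines and model
selection; module-level functions wrap it for work on the package's own
containers and portable JSON model files.

## Worked example

Generate the benchmark dataset (10 types × 3 tissues × 3 donors, 2,000 genes,
20 planted markers per type, one type restricted to the spleen), train on a
stratified 70% split, evaluate on the rest, and screen tissue composition:

```python
import numpy as np
from sklearn.model_selection import train_test_split
from sctyper import (generate_dataset, normalize_log1p, TrainingConfig,
                     train_two_round, predict_probabilities, evaluate_labels,
                     extract_markers, CompositionTable, enrichment_screen)
from sctyper.preprocessing import NormalizedMatrix
from sctyper.synthetic_data import default_benchmark_config

cfg = default_benchmark_config(seed=0)
counts, ann, hierarchy, truth = generate_dataset(cfg)
X = normalize_log1p(counts)                       # log1p counts-per-10k
labels = np.asarray(ann.labels.loc[counts.cell_ids], dtype=object)
idx_tr, idx_te = train_test_split(np.arange(X.n_cells), test_size=0.3,
                                  stratify=labels, random_state=0)
Xtr = NormalizedMatrix(X.values[idx_tr], [X.cell_ids[i] for i in idx_tr], X.gene_ids)
Xte = NormalizedMatrix(X.values[idx_te], [X.cell_ids[i] for i in idx_te], X.gene_ids)

model, history = train_two_round(Xtr, labels[idx_tr], TrainingConfig(seed=0))
pred = predict_probabilities(model, Xte)
report = evaluate_labels(list(labels[idx_te]), pred.predicted_label)
print(f"held-out median F1 = {report.median_f1:.4f}")
print("top markers of type01:", [g for g, w in extract_markers(model, "type01", 5)])

screen = enrichment_screen(CompositionTable.from_annotations(ann))
print(screen[screen.enriched][["cell_type", "tissue", "beta1", "p_adj"]].to_string(index=False))
```

Output:

```
held-out median F1 = 0.9852
top markers of type01: ['g0013', 'g0002', 'g0001', 'g0018', 'g0020']
cell_type tissue    beta1        p_adj
   type10 spleen 6.294897 2.531725e-66
```

The median per-class F1 of 0.9852 says the two-round model recovers nearly
every planted type on held-out cells; the listed markers are drawn from
type01's planted block (g0001–g0020); and the screen flags exactly the
planted spleen-restricted type, with β1 the log rate ratio of its abundance
in spleen versus the remaining tissues.

The same pipeline is available from the shell:

```sh
sctyper simulate --out data --seed 0
sctyper train --counts data/counts --annotations data/annotations.tsv \
    --hierarchy data/hierarchy.tsv --out-model model.json --skip-qc
sctyper predict --model model.json --counts data/counts --out pred.tsv
sctyper enrich --annotations data/annotations.tsv --out enrichment.tsv
```

## Documentation

`docs/methods.md` describes the model, the optimizer and its defaults, the
enrichment statistics (including exact handling of complete separation), the
synthetic generator, and known limitations.
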