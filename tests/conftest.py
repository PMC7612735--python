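"""Shared fixtures: the benchmark synthetic dataset and a trained model.

Session-scoped because generation and two-round training are the expensive
steps shared by the evaluation, robustness and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from sctyper.classifier import TrainingConfig, train_two_round
from sctyper.preprocessing import NormalizedMatrix, normalize_log1p
from sctyper.synthetic_data import SimConfig, default_benchmark_config, generate_dataset

BENCHMARK_SEED = 0


@pytest.fixture(scope="session")
def benchmark_dataset():
    cfg = default_benchmark_config(seed=BENCHMARK_SEED)
    counts, ann, hierarchy, truth = generate_dataset(cfg)
    return {"cfg": cfg, "counts": counts, "ann": ann, "hierarchy": hierarchy, "truth": truth}


@pytest.fixture(scope="session")
def benchmark_split(benchmark_dataset):
    """Stratified 70/30 split of the normalized benchmark data."""
    counts = benchmark_dataset["counts"]
    ann = benchmark_dataset["ann"]
    X = normalize_log1p(counts)
    labels = np.asarray(ann.labels.loc[counts.cell_ids], dtype=object)
    idx_tr, idx_te = train_test_split(
        np.arange(X.n_cells), test_size=0.3, stratify=labels, random_state=BENCHMARK_SEED
    )
    Xtr = NormalizedMatrix(X.values[idx_tr], [X.cell_ids[i] for i in idx_tr], X.gene_ids)
    Xte = NormalizedMatrix(X.values[idx_te], [X.cell_ids[i] for i in idx_te], X.gene_ids)
    return {"Xtr": Xtr, "ytr": labels[idx_tr], "Xte": Xte, "yte": labels[idx_te]}


@pytest.fixture(scope="session")
def benchmark_model(benchmark_split):
    config = TrainingConfig(seed=BENCHMARK_SEED)
    model, history = train_two_round(
        benchmark_split["Xtr"], benchmark_split["ytr"], config
    )
    return {"model": model, "history": history, "config": config}


@pytest.fixture()
def small_separable():
    """A tiny, clearly separable 3-type dataset for fast classifier checks."""
    cfg = SimConfig(
        n_types=3, n_genes=60, markers_per_type=10, log2_fold_change=3.0,
        cells_per_combo=20, tissues=["t1"], donors=["d1"], donor_logfc_sd=0.0,
        seed=11,
    )
    counts, ann, hierarchy, truth = generate_dataset(cfg)
    X = normalize_log1p(counts)
    labels = np.asarray(ann.labels, dtype=object)
    return {"X": X, "labels": labels, "truth": truth, "hierarchy": hierarchy, "cfg": cfg}
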