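"""Two-round mini-batch SGD logistic regression for cell-type annotation.

The model is multinomial (softmax) logistic regression minimizing

    L(W, b) = mean-over-cells cross-entropy + (lambda/2) * ||W||^2

with unpenalized intercepts, trained by mini-batch stochastic gradient descent
over seeded shuffles of the cells. Training runs in two rounds: round 1 fits on
all genes; the top ``n_top_genes`` positively weighted genes of each class are
pooled and round 2 refits on that union, which becomes the model's feature set.
Per-class top weights double as data-driven marker genes.

``CellTypeClassifier`` is a scikit-learn-compatible estimator (fit /
predict / predict_proba, ``get_params``/``set_params``); the module-level
functions (``fit_round``, ``train_two_round``, ...) are thin wrappers that
work directly on :class:`~sctyper.preprocessing.NormalizedMatrix` containers
and produce portable :class:`ClassifierModel` files.
"""

from __future__ import annotations

import base64
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .data_model import LabelHierarchy, ValidationError, align_genes, validate_hierarchy
from .preprocessing import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "ClassifierModel",
    "PredictionResult",
    "TrainingHistory",
    "CellTypeClassifier",
    "make_minibatches",
    "fit_round",
    "select_top_features",
    "train_two_round",
    "predict_probabilities",
    "extract_markers",
    "update_model",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1
UNASSIGNED = "Unassigned"


@dataclass
class TrainingConfig:
    """Hyperparameters of the two-round SGD fit.

    ``l2_strength`` is the ridge penalty lambda; ``learning_rate0`` the initial
    step size eta0; the default schedule decays as eta_t = eta0/(1+lambda*eta0*t)
    over global update count t. ``n_top_genes`` is the per-class feature budget
    for round 2 (300 by default).
    """

    batch_size: int = 1000
    epochs: int = 100
    l2_strength: float = 1e-4
    learning_rate0: float = 0.02
    lr_schedule: str = "inverse"  # or "constant"
    n_top_genes: int = 300
    seed: int = 0
    validation_fraction: float = 0.1
    unassigned_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.epochs <= 0 or self.n_top_genes <= 0:
            raise ValidationError("batch_size, epochs and n_top_genes must be positive")
        if self.l2_strength <= 0 or self.learning_rate0 <= 0:
            raise ValidationError("l2_strength and learning_rate0 must be positive")
        if self.lr_schedule not in ("inverse", "constant"):
            raise ValidationError(f"unknown lr_schedule {self.lr_schedule!r}")
        if not (0 < self.validation_fraction < 1):
            raise ValidationError("validation_fraction must be in (0, 1)")
        if self.unassigned_threshold is not None and not (
            0 <= self.unassigned_threshold <= 1
        ):
            raise ValidationError("unassigned_threshold must be in [0, 1]")


@dataclass
class ClassifierModel:
    """A trained model: per-class weights over a selected gene list plus metadata."""

    class_names: list[str]
    feature_genes: list[str]
    weights: np.ndarray  # K x G
    intercepts: np.ndarray  # K
    normalization: dict = field(default_factory=lambda: {"target_sum": 10000.0, "transform": "log1p"})
    hierarchy_level: str = "low"
    version: int = 1
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.intercepts = np.asarray(self.intercepts, dtype=np.float64)
        K, G = len(self.class_names), len(self.feature_genes)
        if self.weights.shape != (K, G):
            raise ValidationError(f"weight matrix shape {self.weights.shape} != ({K}, {G})")
        if self.intercepts.shape != (K,):
            raise ValidationError("intercept vector length does not match classes")
        if len(set(self.class_names)) != K or len(set(self.feature_genes)) != G:
            raise ValidationError("class names and feature genes must be unique")
        if K < 2:
            raise ValidationError("a classifier needs at least 2 classes")
        if self.version < 1:
            raise ValidationError("model version must be >= 1")


@dataclass
class PredictionResult:
    cell_ids: list[str]
    class_names: list[str]
    probabilities: np.ndarray  # cells x K
    predicted_label: list[str]
    confidence: np.ndarray  # cells


@dataclass
class TrainingHistory:
    """Per-update loss records; iteration indices are global and strictly increasing."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        if self.records and kw["iteration"] <= self.records[-1]["iteration"]:
            raise ValidationError("history iterations must be strictly increasing")
        self.records.append(kw)

    def extend(self, other: "TrainingHistory") -> None:
        for rec in other.records:
            self.append(**rec)


# ---------------------------------------------------------------------------
# SGD core
# ---------------------------------------------------------------------------

def make_minibatches(n_cells: int, batch_size: int, seed: int) -> list[np.ndarray]:
    """Seeded uniform shuffle of ``range(n_cells)`` cut into consecutive blocks
    of ``batch_size``; the final remainder block is kept."""
    if batch_size <= 0:
        raise ValidationError("batch_size must be positive")
    if n_cells <= 0:
        raise ValidationError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    return [order[i : i + batch_size] for i in range(0, n_cells, batch_size)]


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    np.exp(Z, out=Z)
    Z /= Z.sum(axis=1, keepdims=True)
    return Z


def penalized_loss(W: np.ndarray, b: np.ndarray, X: np.ndarray, y_idx: np.ndarray,
                   l2_strength: float) -> float:
    """Mean cross-entropy plus (lambda/2)*||W||^2 — the objective both the SGD
    path and any full-batch reference optimizer must share."""
    Z = X @ W.T + b
    Z -= Z.max(axis=1, keepdims=True)
    logp = Z - np.log(np.exp(Z).sum(axis=1, keepdims=True))
    ce = -logp[np.arange(len(y_idx)), y_idx].mean()
    return float(ce + 0.5 * l2_strength * (W ** 2).sum())


def _epoch_seeds(seed: int, epochs: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(epochs)
    return [int(s) % (2**31) for s in state]


def _sgd_fit(
    X: np.ndarray,
    y_idx: np.ndarray,
    n_classes: int,
    config: TrainingConfig,
    seed: int,
    epoch_callback: Optional[Callable[[int, np.ndarray, np.ndarray], Optional[float]]] = None,
    start_iteration: int = 0,
    round_tag: int = 1,
) -> tuple[np.ndarray, np.ndarray, TrainingHistory]:
    """Mini-batch SGD on the softmax cross-entropy + ridge objective.

    One update per mini-batch; cells are reshuffled every epoch with seeds
    derived deterministically from ``seed``. ``epoch_callback(epoch, W, b)``
    runs at each epoch boundary and may return a validation score recorded in
    the history.
    """
    n, G = X.shape
    K = n_classes
    W = np.zeros((K, G))
    b = np.zeros(K)
    lam, eta0 = config.l2_strength, config.learning_rate0
    history = TrainingHistory()
    t = 0
    for epoch, ep_seed in enumerate(_epoch_seeds(seed, config.epochs)):
        for idx in make_minibatches(n, config.batch_size, ep_seed):
            Xb, yb = X[idx], y_idx[idx]
            loss = penalized_loss(W, b, Xb, yb, lam)
            P = _softmax(Xb @ W.T + b)
            P[np.arange(len(yb)), yb] -= 1.0
            grad_W = P.T @ Xb / len(yb) + lam * W
            grad_b = P.mean(axis=0)
            eta = eta0 if config.lr_schedule == "constant" else eta0 / (1.0 + lam * eta0 * t)
            W -= eta * grad_W
            b -= eta * grad_b
            t += 1
            history.append(round=round_tag, epoch=epoch, iteration=start_iteration + t,
                           loss=loss, val_median_f1=None)
        if epoch_callback is not None:
            score = epoch_callback(epoch, W, b)
            if score is not None:
                history.records[-1]["val_median_f1"] = float(score)
    return W, b, history


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class CellTypeClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style estimator wrapping the two-round SGD fit.

    Parameters mirror :class:`TrainingConfig`; ``two_round=False`` falls back
    to a single round on all features. ``X`` passed to :meth:`fit` and
    :meth:`predict` is a dense cells x genes array of log-normalized
    expression (a :class:`NormalizedMatrix` ``.values``).

    Attributes set by :meth:`fit`
    -----------------------------
    classes_ : ndarray of class labels in probability-column order
    coef_ : (K, n_selected) weight matrix
    intercept_ : (K,) intercepts
    feature_indices_ : column indices (into the fit-time X) of the selected genes
    history_ : TrainingHistory of per-update losses
    """

    def __init__(
        self,
        batch_size: int = 1000,
        epochs: int = 100,
        l2_strength: float = 1e-4,
        learning_rate0: float = 0.02,
        lr_schedule: str = "inverse",
        n_top_genes: int = 300,
        two_round: bool = True,
        unassigned_threshold: Optional[float] = None,
        random_state: int = 0,
    ):
        self.batch_size = batch_size
        self.epochs = epochs
        self.l2_strength = l2_strength
        self.learning_rate0 = learning_rate0
        self.lr_schedule = lr_schedule
        self.n_top_genes = n_top_genes
        self.two_round = two_round
        self.unassigned_threshold = unassigned_threshold
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            batch_size=self.batch_size,
            epochs=self.epochs,
            l2_strength=self.l2_strength,
            learning_rate0=self.learning_rate0,
            lr_schedule=self.lr_schedule,
            n_top_genes=self.n_top_genes,
            seed=self.random_state,
            unassigned_threshold=self.unassigned_threshold,
        )

    def fit(self, X, y, epoch_callback=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValidationError("X must be 2-D with one row per label")
        if np.isnan(X).any():
            raise ValidationError("X contains NaN")
        config = self._config()
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValidationError("need at least 2 distinct labels to train")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        history = TrainingHistory()

        W1, b1, h1 = _sgd_fit(X, y_idx, len(classes), config, seed=config.seed,
                              epoch_callback=epoch_callback, round_tag=1)
        history.extend(h1)
        if self.two_round:
            sel = _top_feature_indices(W1, config.n_top_genes)
            cb2 = None
            if epoch_callback is not None:
                cb2 = lambda ep, W, b: epoch_callback(ep, W, b, sel)  # noqa: E731
            W2, b2, h2 = _sgd_fit(
                X[:, sel], y_idx, len(classes), config,
                seed=(config.seed + 1) % (2**31),
                epoch_callback=cb2,
                start_iteration=history.records[-1]["iteration"],
                round_tag=2,
            )
            history.extend(h2)
            self.coef_, self.intercept_, self.feature_indices_ = W2, b2, sel
        else:
            self.coef_, self.intercept_ = W1, b1
            self.feature_indices_ = np.arange(X.shape[1])
        self.history_ = history
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        return X[:, self.feature_indices_] @ self.coef_.T + self.intercept_

    def predict_proba(self, X):
        return _softmax(self.decision_function(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        labels = self.classes_[np.argmax(proba, axis=1)]
        if self.unassigned_threshold is not None:
            labels = np.where(
                proba.max(axis=1) < self.unassigned_threshold, UNASSIGNED, labels
            )
        return labels


def _top_feature_indices(W: np.ndarray, n_top: int) -> np.ndarray:
    """Union over classes of the ``n_top`` largest signed weights, returned in
    original column order. Ties broken by column order (stable mergesort on -w)."""
    K, G = W.shape
    take = min(n_top, G)
    chosen: set[int] = set()
    for k in range(K):
        order = np.argsort(-W[k], kind="stable")
        chosen.update(order[:take].tolist())
    return np.array(sorted(chosen), dtype=int)


# ---------------------------------------------------------------------------
# Container-level API
# ---------------------------------------------------------------------------

def _check_labels(X: NormalizedMatrix, labels: Sequence[str]) -> np.ndarray:
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != X.n_cells:
        raise ValidationError("one label per cell required")
    if any(not lab for lab in labels):
        raise ValidationError("labels must be non-empty")
    return labels


def fit_round(
    X: NormalizedMatrix,
    labels: Sequence[str],
    config: TrainingConfig,
    feature_subset: Optional[Sequence[str]] = None,
    hierarchy_level: str = "low",
) -> tuple[ClassifierModel, TrainingHistory]:
    """One round of mini-batch SGD on all genes (or on ``feature_subset``)."""
    labels = _check_labels(X, labels)
    if feature_subset is not None:
        X, _ = align_genes(X, feature_subset)
    est = CellTypeClassifier(
        batch_size=config.batch_size, epochs=config.epochs,
        l2_strength=config.l2_strength, learning_rate0=config.learning_rate0,
        lr_schedule=config.lr_schedule, n_top_genes=config.n_top_genes,
        two_round=False, random_state=config.seed,
    )
    est.fit(X.values, labels)
    model = ClassifierModel(
        class_names=[str(c) for c in est.classes_],
        feature_genes=list(X.gene_ids),
        weights=est.coef_,
        intercepts=est.intercept_,
        normalization={"target_sum": X.target_sum, "transform": "log1p"},
        hierarchy_level=hierarchy_level,
    )
    return model, est.history_


def select_top_features(model: ClassifierModel, n_top: int) -> list[str]:
    """Per class, the ``n_top`` genes with the largest signed weights; the
    union is returned in the model's original gene order."""
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    idx = _top_feature_indices(model.weights, n_top)
    return [model.feature_genes[i] for i in idx]


def train_two_round(
    X: NormalizedMatrix,
    labels: Sequence[str],
    config: TrainingConfig,
    hierarchy_level: str = "low",
    provenance: Optional[list[str]] = None,
) -> tuple[ClassifierModel, TrainingHistory]:
    """Round 1 on all genes, per-class top-gene selection, round 2 restricted
    to the selected union, which becomes the returned model's feature set."""
    labels = _check_labels(X, labels)
    est = CellTypeClassifier(
        batch_size=config.batch_size, epochs=config.epochs,
        l2_strength=config.l2_strength, learning_rate0=config.learning_rate0,
        lr_schedule=config.lr_schedule, n_top_genes=config.n_top_genes,
        two_round=True, unassigned_threshold=config.unassigned_threshold,
        random_state=config.seed,
    )
    est.fit(X.values, labels)
    feature_genes = [X.gene_ids[i] for i in est.feature_indices_]
    model = ClassifierModel(
        class_names=[str(c) for c in est.classes_],
        feature_genes=feature_genes,
        weights=est.coef_,
        intercepts=est.intercept_,
        normalization={"target_sum": X.target_sum, "transform": "log1p"},
        hierarchy_level=hierarchy_level,
        provenance=list(provenance or []),
    )
    return model, est.history_


def predict_probabilities(
    model: ClassifierModel,
    X: NormalizedMatrix,
    unassigned_threshold: Optional[float] = None,
) -> PredictionResult:
    """Softmax class probabilities for each cell; the query is aligned onto the
    model's feature genes first (missing genes zero-filled, overlap logged)."""
    aligned, overlap = align_genes(X, model.feature_genes)
    logger.info("query/model gene overlap: %.3f", overlap)
    Z = aligned.values @ model.weights.T + model.intercepts
    proba = _softmax(Z)
    conf = proba.max(axis=1)
    arg = proba.argmax(axis=1)
    labels = [model.class_names[a] for a in arg]
    if unassigned_threshold is not None:
        labels = [
            UNASSIGNED if c < unassigned_threshold else lab
            for lab, c in zip(labels, conf)
        ]
    return PredictionResult(
        cell_ids=list(X.cell_ids),
        class_names=list(model.class_names),
        probabilities=proba,
        predicted_label=labels,
        confidence=conf,
    )


def extract_markers(model: ClassifierModel, class_name: str, k: int) -> list[tuple[str, float]]:
    """Top-``k`` marker genes of a class by descending signed weight."""
    if class_name not in model.class_names:
        raise ValidationError(f"unknown class {class_name!r}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    row = model.weights[model.class_names.index(class_name)]
    order = np.argsort(-row, kind="stable")[: min(k, len(row))]
    return [(model.feature_genes[i], float(row[i])) for i in order]


def update_model(
    old_model: ClassifierModel,
    old_corpus: tuple[NormalizedMatrix, Sequence[str]],
    new_corpus: Optional[tuple[NormalizedMatrix, Sequence[str]]],
    hierarchy: LabelHierarchy,
    config: TrainingConfig,
    note: str = "",
) -> ClassifierModel:
    """Retrain on the old corpus plus newly curated cells.

    The old corpus's gene universe is the reference: the new corpus is aligned
    onto it (shared genes kept, absentees zero-filled). New labels must be
    covered by the hierarchy. The returned model's version is incremented and
    its provenance extended.
    """
    old_X, old_labels = old_corpus
    old_labels = _check_labels(old_X, old_labels)
    if new_corpus is not None and new_corpus[0].n_cells > 0:
        new_X, new_labels = new_corpus
        new_labels = _check_labels(new_X, new_labels)
        report = validate_hierarchy(hierarchy, set(new_labels))
        if not report.passed:
            raise ValidationError(f"new labels missing from hierarchy: {report.missing}")
        new_X, _ = align_genes(new_X, old_X.gene_ids)
        X = NormalizedMatrix(
            np.vstack([old_X.values, new_X.values]),
            list(old_X.cell_ids) + list(new_X.cell_ids),
            list(old_X.gene_ids),
            target_sum=old_X.target_sum,
        )
        labels = np.concatenate([old_labels, new_labels])
        prov_note = note or f"update: +{new_X.n_cells} cells"
    else:
        X, labels = old_X, old_labels
        prov_note = note or "update: no new cells (no-op retrain)"
    model, _ = train_two_round(
        X, labels, config,
        hierarchy_level=old_model.hierarchy_level,
        provenance=list(old_model.provenance) + [prov_note],
    )
    return replace(model, version=old_model.version + 1)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _encode(arr: np.ndarray) -> str:
    return base64.b64encode(np.ascontiguousarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _decode(s: str, shape: tuple[int, ...]) -> np.ndarray:
    return np.frombuffer(base64.b64decode(s), dtype="<f8").reshape(shape).copy()


def save_model(model: ClassifierModel, path: str) -> None:
    """Write a model as one JSON object: metadata in clear text, the weight
    matrix and intercepts as base64-encoded little-endian float64 blocks
    (row-major, shape recorded alongside)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "class_names": model.class_names,
        "feature_genes": model.feature_genes,
        "normalization": model.normalization,
        "hierarchy_level": model.hierarchy_level,
        "version": model.version,
        "provenance": model.provenance,
        "weights_shape": list(model.weights.shape),
        "weights_b64": _encode(model.weights),
        "intercepts_b64": _encode(model.intercepts),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str) -> ClassifierModel:
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"cannot parse model file {path}: {exc}") from exc
    found = payload.get("format_version")
    if found != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model format version mismatch: expected {MODEL_FORMAT_VERSION}, found {found}"
        )
    shape = tuple(payload["weights_shape"])
    return ClassifierModel(
        class_names=payload["class_names"],
        feature_genes=payload["feature_genes"],
        weights=_decode(payload["weights_b64"], shape),
        intercepts=_decode(payload["intercepts_b64"], (shape[0],)),
        normalization=payload["normalization"],
        hierarchy_level=payload["hierarchy_level"],
        version=payload["version"],
        provenance=payload["provenance"],
    )
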