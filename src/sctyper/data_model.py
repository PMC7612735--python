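"""Core containers and I/O for count matrices, cell annotations and label hierarchies.

All in-memory matrices are cells x genes. On-disk Matrix Market files follow the
10x convention of genes x cells with sidecar ``features``/``barcodes`` line-per-id
lists; readers transpose so a single orientation holds everywhere downstream.
"""

from __future__ import annotations

import copy
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "CountMatrix",
    "CellAnnotations",
    "LabelHierarchy",
    "HierarchyReport",
    "read_counts",
    "write_counts",
    "read_annotations",
    "write_annotations",
    "read_hierarchy",
    "write_hierarchy",
    "align_genes",
    "validate_hierarchy",
]


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Data violates a container invariant (duplicates, negatives, mismatches)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class CountMatrix:
    """Raw UMI counts, cells x genes, with unique cell and gene identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-D")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.values, 1), 0)):
                raise ValidationError("count matrix contains non-integer entries")
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class CellAnnotations:
    """Per-cell labels with optional tissue and donor columns.

    Wraps a DataFrame indexed by ``cell_id``; absence of the optional columns is
    recorded explicitly so downstream composition analyses can refuse inputs
    that lack them instead of silently treating "" as a tissue.
    """

    table: pd.DataFrame
    has_tissue: bool = True
    has_donor: bool = True

    def __post_init__(self) -> None:
        df = self.table
        if "cell_id" in df.columns:
            df = df.set_index("cell_id")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate cell_id in annotations: {dup!r}")
        if "label" not in df.columns:
            raise FormatError("annotations require a 'label' column")
        self.has_tissue = "tissue" in df.columns
        self.has_donor = "donor" in df.columns
        keep = ["label"] + [c for c in ("tissue", "donor") if c in df.columns]
        df = df[keep]
        for col in keep:
            bad = df[col].isna() | (df[col].astype(str).str.len() == 0)
            if bad.any():
                raise ValidationError(
                    f"empty value in column {col!r} for cell {df.index[bad][0]!r}"
                )
        self.table = df

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def require_composition_columns(self) -> None:
        if not (self.has_tissue and self.has_donor):
            missing = [
                c for c, ok in (("tissue", self.has_tissue), ("donor", self.has_donor)) if not ok
            ]
            raise ValidationError(
                f"composition analysis needs tissue and donor columns; missing: {missing}"
            )

    def subset(self, cell_ids: Sequence[str]) -> "CellAnnotations":
        return CellAnnotations(self.table.loc[list(cell_ids)].copy())


@dataclass
class LabelHierarchy:
    """Two-level label vocabulary: each fine (low) label maps to one coarse (high) label."""

    low_to_high: dict[str, str]

    def __post_init__(self) -> None:
        self.low_to_high = dict(self.low_to_high)
        for low, high in self.low_to_high.items():
            if not low or not high:
                raise ValidationError("hierarchy entries must be non-empty strings")

    @property
    def high_labels(self) -> set[str]:
        return set(self.low_to_high.values())

    def to_high(self, low_labels: Iterable[str]) -> list[str]:
        out = []
        for lab in low_labels:
            if lab not in self.low_to_high:
                raise ValidationError(f"low label {lab!r} missing from hierarchy")
            out.append(self.low_to_high[lab])
        return out


@dataclass
class HierarchyReport:
    missing: list[str] = field(default_factory=list)
    unused: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.missing


def validate_hierarchy(hierarchy: LabelHierarchy, labels_in_use: Iterable[str]) -> HierarchyReport:
    """Report labels in use that the hierarchy does not cover, and unused mapping keys."""
    in_use = set(labels_in_use)
    keys = set(hierarchy.low_to_high)
    return HierarchyReport(
        missing=sorted(in_use - keys),
        unused=sorted(keys - in_use),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_id_list(path: str, what: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise FormatError(f"empty {what} list: {path}")
    return ids


def read_counts(path: str, format: str = "mtx") -> CountMatrix:
    """Read a count matrix.

    ``format="mtx"``: *path* is a directory holding ``matrix.mtx`` (genes x cells,
    Matrix Market coordinate), ``barcodes.tsv`` and ``features.tsv``.
    ``format="csv"``: dense CSV, gene ids in the header, cell ids in the first column.
    """
    if format == "mtx":
        mtx_path = os.path.join(path, "matrix.mtx")
        try:
            mat = spio.mmread(mtx_path)
        except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
            raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}") from exc
        genes = _read_id_list(os.path.join(path, "features.tsv"), "feature")
        cells = _read_id_list(os.path.join(path, "barcodes.tsv"), "barcode")
        mat = sparse.coo_matrix(mat)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix header declares {mat.shape[0]} genes x {mat.shape[1]} cells "
                f"but sidecar lists have {len(genes)} features and {len(cells)} barcodes"
            )
        dense = np.asarray(mat.todense()).T  # -> cells x genes
        return CountMatrix(dense, cells, genes)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])
    raise ValueError(f"unknown counts format: {format!r}")


def write_counts(matrix: CountMatrix, path: str, format: str = "mtx") -> None:
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        coo = sparse.coo_matrix(matrix.values.T)  # genes x cells on disk
        spio.mmwrite(os.path.join(path, "matrix.mtx"), coo, field="integer")
        for name, ids in (("features.tsv", matrix.gene_ids), ("barcodes.tsv", matrix.cell_ids)):
            with open(os.path.join(path, name), "w", encoding="utf-8") as fh:
                fh.write("\n".join(ids) + "\n")
        return
    if format == "csv":
        pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids).to_csv(path)
        return
    raise ValueError(f"unknown counts format: {format!r}")


def read_annotations(path: str) -> CellAnnotations:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise FormatError("annotation TSV must contain a 'cell_id' column")
    if "label" not in df.columns:
        raise FormatError("annotation TSV must contain a 'label' column")
    return CellAnnotations(df)


def write_annotations(ann: CellAnnotations, path: str) -> None:
    ann.table.rename_axis("cell_id").reset_index().to_csv(path, sep="\t", index=False)


def read_hierarchy(path: str) -> LabelHierarchy:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "low" not in cols or "high" not in cols:
        raise FormatError("hierarchy TSV must have 'low' and 'high' columns")
    low, high = df[cols["low"]], df[cols["high"]]
    if low.duplicated().any():
        raise ValidationError(f"low label mapped twice: {low[low.duplicated()].iloc[0]!r}")
    return LabelHierarchy(dict(zip(low, high)))


def write_hierarchy(hierarchy: LabelHierarchy, path: str) -> None:
    pd.DataFrame(
        {"low": list(hierarchy.low_to_high), "high": list(hierarchy.low_to_high.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene alignment
# ---------------------------------------------------------------------------

#: below this overlap fraction, alignment is refused outright
MIN_OVERLAP = 1e-9
#: below this, alignment proceeds but a warning is logged
WARN_OVERLAP = 0.5


def align_genes(matrix, feature_list: Sequence[str]):
    """Reindex a matrix onto ``feature_list``: shared genes keep their values,
    genes missing from the input are zero-filled, extra genes are dropped.

    Returns ``(aligned_matrix, overlap_fraction)`` where the overlap fraction is
    ``|input genes ∩ feature_list| / |feature_list|``. Works on any container
    with ``values``/``cell_ids``/``gene_ids`` and returns the same type.
    """
    feature_list = list(feature_list)
    _check_unique(feature_list, "feature-list gene")
    pos = {g: j for j, g in enumerate(matrix.gene_ids)}
    shared = [g for g in feature_list if g in pos]
    overlap = len(shared) / len(feature_list) if feature_list else 0.0
    if overlap <= MIN_OVERLAP:
        raise ValidationError("no genes shared between matrix and feature list")
    if overlap < WARN_OVERLAP:
        logger.warning(
            "low gene overlap with feature list: %d/%d (%.1f%%); missing genes zero-filled",
            len(shared), len(feature_list), 100 * overlap,
        )
    out = np.zeros((matrix.values.shape[0], len(feature_list)), dtype=matrix.values.dtype)
    for j, g in enumerate(feature_list):
        if g in pos:
            out[:, j] = matrix.values[:, pos[g]]
    aligned = copy.copy(matrix)
    aligned.values = out
    aligned.gene_ids = feature_list
    return aligned, overlap
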