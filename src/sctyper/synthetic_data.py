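"""Seeded synthetic scRNA-seq generator with planted marker programs.

Each cell type carries a disjoint block of marker genes whose mean expression
is raised by a configurable log2 fold-change over a shared baseline; counts are
drawn from a negative binomial (gamma-Poisson) with a shared dispersion.
Cells are organized by tissue and donor, with a per-donor multiplicative
lognormal nuisance factor on every gene so that donor stratification in the
composition statistics has something real to absorb. A two-level label
hierarchy groups the fine types into coarse groups.

The generator is the test bed for every other module: its defaults
(:func:`default_benchmark_config`) define the benchmark conditions under which
classifier performance, marker recovery and enrichment detection are measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .data_model import CellAnnotations, CountMatrix, LabelHierarchy, ValidationError

__all__ = [
    "SimConfig",
    "generate_dataset",
    "default_benchmark_config",
    "simulate_composition_counts",
]

CellTable = Union[int, Mapping[tuple[str, str, str], int]]


@dataclass
class SimConfig:
    """Full parameterization of one synthetic dataset.

    ``cells_per_combo`` is either a scalar (cells for every
    (type, tissue, donor) combination) or a mapping from such triples to
    counts; absent triples mean zero cells. ``nb_dispersion`` is the
    gamma-Poisson dispersion alpha with variance mu + alpha * mu^2.
    ``donor_logfc_sd`` is the standard deviation of the per-(donor, gene)
    log2 nuisance factor.
    """

    n_types: int = 10
    markers_per_type: int = 20
    log2_fold_change: float = 2.0
    base_mean: float = 0.5
    nb_dispersion: float = 0.5
    n_genes: int = 2000
    cells_per_combo: CellTable = 50
    tissues: list[str] = field(default_factory=lambda: ["spleen", "lung", "liver"])
    donors: list[str] = field(default_factory=lambda: ["D1", "D2", "D3"])
    donor_logfc_sd: float = 0.1
    hierarchy_groups: Optional[dict[str, str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.markers_per_type < 1 or self.n_genes < 1:
            raise ValidationError("n_types, markers_per_type and n_genes must be positive")
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValidationError(
                "disjoint marker blocks need n_types * markers_per_type <= n_genes"
            )
        if self.base_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("base_mean and nb_dispersion must be positive")
        if self.log2_fold_change < 0 or self.donor_logfc_sd < 0:
            raise ValidationError("log2_fold_change and donor_logfc_sd must be >= 0")
        if isinstance(self.cells_per_combo, int) and self.cells_per_combo < 0:
            raise ValidationError("cells_per_combo must be non-negative")

    @property
    def type_names(self) -> list[str]:
        return [f"type{i + 1:02d}" for i in range(self.n_types)]

    def cells_for(self, cell_type: str, tissue: str, donor: str) -> int:
        if isinstance(self.cells_per_combo, int):
            return self.cells_per_combo
        return int(self.cells_per_combo.get((cell_type, tissue, donor), 0))

    def hierarchy(self) -> LabelHierarchy:
        if self.hierarchy_groups is not None:
            return LabelHierarchy(dict(self.hierarchy_groups))
        # default: round-robin into 3 coarse groups
        groups = [f"group{(i % 3) + 1}" for i in range(self.n_types)]
        return LabelHierarchy(dict(zip(self.type_names, groups)))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
             size: tuple[int, int]) -> np.ndarray:
    """Gamma-Poisson: lambda ~ Gamma(1/alpha, scale=mean*alpha), counts ~ Poisson(lambda)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.broadcast_to(mean * dispersion, size))
    return rng.poisson(lam)


def generate_dataset(cfg: SimConfig):
    """Draw one dataset.

    Returns ``(CountMatrix, CellAnnotations, LabelHierarchy, truth)`` where
    ``truth`` maps each cell type to its planted marker gene list. Fully
    determined by ``cfg.seed``; combinations are generated in sorted order so
    the byte layout is reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{j + 1:04d}" for j in range(cfg.n_genes)]
    types = cfg.type_names
    m = cfg.markers_per_type
    truth = {t: gene_ids[i * m : (i + 1) * m] for i, t in enumerate(types)}
    marker_idx = {t: np.arange(i * m, (i + 1) * m) for i, t in enumerate(types)}

    # per-(donor, gene) multiplicative nuisance, shared by all of a donor's cells
    donor_factor = {
        d: np.exp2(rng.normal(0.0, cfg.donor_logfc_sd, cfg.n_genes)) for d in cfg.donors
    }
    fold = 2.0 ** cfg.log2_fold_change

    blocks, ann_rows = [], []
    cell_counter = 0
    for t in types:
        for tissue in cfg.tissues:
            for donor in cfg.donors:
                n = cfg.cells_for(t, tissue, donor)
                if n == 0:
                    continue
                mean = cfg.base_mean * donor_factor[donor]
                mean = mean.copy()
                mean[marker_idx[t]] *= fold
                blocks.append(_nb_draw(rng, mean, cfg.nb_dispersion, (n, cfg.n_genes)))
                for _ in range(n):
                    cell_counter += 1
                    ann_rows.append({
                        "cell_id": f"cell{cell_counter:06d}",
                        "label": t,
                        "tissue": tissue,
                        "donor": donor,
                    })
    if not blocks:
        raise ValidationError("configuration yields zero cells")
    values = np.vstack(blocks)
    cell_ids = [r["cell_id"] for r in ann_rows]
    counts = CountMatrix(values, cell_ids, gene_ids)
    annotations = CellAnnotations(pd.DataFrame(ann_rows))
    return counts, annotations, cfg.hierarchy(), truth


BENCHMARK_RESTRICTED_TYPE = "type10"
BENCHMARK_RESTRICTED_TISSUE = "spleen"


def default_benchmark_config(seed: int = 0) -> SimConfig:
    """The benchmark conditions used throughout the test suite: 10 types in
    3 coarse groups, 2000 genes, 20 markers/type at log2 fold-change 2,
    negative-binomial dispersion 0.5, 3 tissues x 3 donors with 50 cells per
    (type, tissue, donor) — except ``type10``, present only in the spleen,
    which plants a detectable tissue enrichment."""
    cfg = SimConfig(seed=seed)
    table: dict[tuple[str, str, str], int] = {}
    for t in cfg.type_names:
        for tissue in cfg.tissues:
            if t == BENCHMARK_RESTRICTED_TYPE and tissue != BENCHMARK_RESTRICTED_TISSUE:
                continue
            for donor in cfg.donors:
                table[(t, tissue, donor)] = 50
    cfg.cells_per_combo = table
    return cfg


def simulate_composition_counts(
    n_types: int = 5,
    tissues: tuple[str, ...] = ("spleen", "lung", "liver"),
    donors: tuple[str, ...] = ("D1", "D2", "D3"),
    base_cells: float = 100.0,
    enriched: Optional[tuple[str, str, float]] = None,
    donor_scale_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Composition-level simulator (no expression): Poisson counts per
    (type, tissue, donor) around ``base_cells`` with a lognormal per-donor
    size factor; ``enriched=(cell_type, tissue, fold)`` multiplies one cell's
    rate. Returns the long-format count table used by the composition module."""
    rng = np.random.default_rng(seed)
    types = [f"type{i + 1:02d}" for i in range(n_types)]
    donor_scale = {d: float(np.exp(rng.normal(0.0, donor_scale_sd))) for d in donors}
    rows = []
    for t in types:
        for tissue in tissues:
            for donor in donors:
                rate = base_cells * donor_scale[donor]
                if enriched is not None and (t, tissue) == enriched[:2]:
                    rate *= enriched[2]
                rows.append({
                    "cell_type": t, "tissue": tissue, "donor": donor,
                    "n": int(rng.poisson(rate)),
                })
    df = pd.DataFrame(rows)
    df["n"] = df["n"].astype(np.int64)
    return df
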