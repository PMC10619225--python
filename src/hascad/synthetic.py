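"""Seeded multi-batch scRNA-seq simulator.

Stands in for multi-chemistry PBMC references so that the whole
deconvolution pipeline (batch correction, pseudo-bulk simulation, model
training, evaluation) is testable without downloads. Each cell type
up-regulates a disjoint block of marker genes over a shared baseline;
each batch perturbs every gene by its own multiplicative (log-normal)
factor; counts are Poisson (optionally negative-binomial) at a per-cell
library size, followed by Bernoulli dropout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .vocabulary import CellTypeVocabulary, DEFAULT_VOCABULARY

__all__ = ["SyntheticDesign", "CellMatrix", "generate_cells", "split_holdout"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the synthetic multi-batch reference.

    cells_per_type_per_batch may be a single count (shared by every
    batch/type stratum) or an (n_batches, 15) matrix.
    """

    n_batches: int = 3
    cells_per_type_per_batch: int | np.ndarray = 50
    n_genes: int = 1200
    program_effect_size: float = 4.0
    batch_effect_sd: float = 1.0
    dropout_rate: float = 0.3
    library_size_range: tuple[float, float] = (1000.0, 5000.0)
    count_model: str = "poisson"
    nb_dispersion: float = 2.0
    seed: int = 0

    def cell_counts(self, n_types: int = 15) -> np.ndarray:
        c = np.asarray(self.cells_per_type_per_batch)
        if c.ndim == 0:
            c = np.full((self.n_batches, n_types), int(c))
        if c.shape != (self.n_batches, n_types):
            raise ValueError(
                f"cells_per_type_per_batch has shape {c.shape}, "
                f"expected ({self.n_batches}, {n_types})"
            )
        return c.astype(int)

    def validate(self) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        c = self.cell_counts()
        if (c <= 0).any():
            raise ValueError("all cells_per_type_per_batch entries must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.program_effect_size <= 0:
            raise ValueError("program_effect_size must be positive")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be non-negative")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be a positive interval")
        if self.count_model not in ("poisson", "nb"):
            raise ValueError(f"unknown count_model {self.count_model!r}")


@dataclass
class CellMatrix:
    """Genes x cells expression with per-cell batch and type labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    batch_labels: np.ndarray
    type_labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.batch_labels = np.asarray(self.batch_labels)
        self.type_labels = np.asarray(self.type_labels)
        g, n = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match count rows")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if not (len(self.cell_ids) == len(self.batch_labels) == len(self.type_labels) == n):
            raise ValueError("per-cell label vectors must have one entry per cell")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def batch_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.batch_labels:
            seen.setdefault(str(b))
        return list(seen)

    def subset_cells(self, idx: np.ndarray) -> "CellMatrix":
        idx = np.asarray(idx)
        return CellMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            batch_labels=self.batch_labels[idx],
            type_labels=self.type_labels[idx],
        )

    def subset_batches(self, batches) -> "CellMatrix":
        keep = np.isin(self.batch_labels, list(batches))
        return self.subset_cells(np.flatnonzero(keep))


def _type_programs(design: SyntheticDesign, n_types: int, rng: np.random.Generator) -> np.ndarray:
    """Per-type relative expression profiles (genes x types), columns sum to 1."""
    base = rng.lognormal(mean=0.0, sigma=1.0, size=design.n_genes)
    block = max(3, design.n_genes // (2 * n_types))
    profiles = np.tile(base[:, None], (1, n_types))
    for t in range(n_types):
        lo = t * block
        hi = min(design.n_genes, lo + block)
        profiles[lo:hi, t] *= 2.0 ** design.program_effect_size
    return profiles / profiles.sum(axis=0, keepdims=True)


def generate_cells(
    design: SyntheticDesign,
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
    seed: int | None = None,
) -> CellMatrix:
    """Draw a seeded multi-batch reference with known type/batch labels.

    Deterministic given (design, seed): identical inputs give bit-identical
    counts. ``seed`` overrides ``design.seed`` when given.
    """
    design.validate()
    n_types = len(vocab)
    counts_per = design.cell_counts(n_types)
    rng = np.random.default_rng(design.seed if seed is None else seed)

    profiles = _type_programs(design, n_types, rng)
    # gene-wise multiplicative batch factor, constant within a batch
    batch_factors = np.exp(
        rng.normal(0.0, design.batch_effect_sd, size=(design.n_genes, design.n_batches))
    )

    blocks: list[np.ndarray] = []
    batch_labels: list[str] = []
    type_labels: list[str] = []
    lo, hi = design.library_size_range
    for b in range(design.n_batches):
        for t, tname in enumerate(vocab):
            n = counts_per[b, t]
            rate = profiles[:, t] * batch_factors[:, b]
            rate = rate / rate.sum()
            lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
            lam = rate[:, None] * lib[None, :]
            if design.count_model == "poisson":
                x = rng.poisson(lam)
            else:  # negative binomial via gamma-Poisson
                shape = design.nb_dispersion
                x = rng.poisson(rng.gamma(shape, lam / shape))
            if design.dropout_rate > 0:
                keep = rng.random(x.shape) >= design.dropout_rate
                x = x * keep
            blocks.append(x)
            batch_labels.extend([f"batch{b}"] * n)
            type_labels.extend([tname] * n)

    counts = np.concatenate(blocks, axis=1).astype(np.int64)
    n_cells = counts.shape[1]
    return CellMatrix(
        counts=counts,
        gene_ids=[f"gene{g:04d}" for g in range(design.n_genes)],
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        batch_labels=np.array(batch_labels),
        type_labels=np.array(type_labels),
    )


def split_holdout(
    cells: CellMatrix, fraction: float, seed: int = 0
) -> tuple[CellMatrix, CellMatrix]:
    """Stratified (batch, type) split into (1-fraction, fraction) partitions.

    ``fraction`` is the share assigned to the second (holdout) matrix.
    A stratum with a single cell goes wholly to the larger split, with a
    warning. The partition is disjoint and exhaustive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    main_idx: list[np.ndarray] = []
    hold_idx: list[np.ndarray] = []
    strata = sorted(set(zip(map(str, cells.batch_labels), map(str, cells.type_labels))))
    holdout_larger = fraction > 0.5
    for b, t in strata:
        idx = np.flatnonzero((cells.batch_labels == b) & (cells.type_labels == t))
        if len(idx) == 1:
            warnings.warn(
                f"stratum ({b}, {t}) has a single cell; assigned to the larger split",
                stacklevel=2,
            )
            (hold_idx if holdout_larger else main_idx).append(idx)
            continue
        idx = rng.permutation(idx)
        n_hold = int(round(fraction * len(idx)))
        n_hold = min(max(n_hold, 0), len(idx))
        hold_idx.append(idx[:n_hold])
        main_idx.append(idx[n_hold:])
    main = np.sort(np.concatenate(main_idx)) if main_idx else np.array([], dtype=int)
    hold = np.sort(np.concatenate(hold_idx)) if hold_idx else np.array([], dtype=int)
    return cells.subset_cells(main), cells.subset_cells(hold)
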