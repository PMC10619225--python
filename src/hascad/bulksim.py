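"""Pseudo-bulk simulation with known cell fractions.

A pseudo-bulk sample is the per-gene mean of cells drawn (with
replacement) from a labelled expression pool at prescribed type
fractions; the fraction vector, normalized to sum to one, is the ground
truth the deconvolution model is trained against. Mixing operates on
whatever representation the pool provides -- by default the
batch-corrected log-expression of a reference, or raw log-CP10K for the
uncorrected baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vocabulary import CellTypeVocabulary, DEFAULT_VOCABULARY

__all__ = ["PseudoBulkSet", "sample_fractions", "mix", "build_set"]


@dataclass
class PseudoBulkSet:
    """Simulated bulk expression paired with its ground-truth compositions."""

    expression: np.ndarray  # genes x samples
    truth: np.ndarray  # samples x 15
    gene_ids: list[str]
    cells_per_sample: int
    source_tag: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.truth = np.asarray(self.truth, dtype=float)
        if self.expression.shape[1] != self.truth.shape[0]:
            raise ValueError("expression columns must match truth rows")
        if (self.truth < 0).any():
            raise ValueError("truth fractions must be non-negative")
        if not np.allclose(self.truth.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every truth row must sum to one")

    @property
    def n_samples(self) -> int:
        return self.truth.shape[0]

    def subset(self, idx) -> "PseudoBulkSet":
        idx = np.asarray(idx)
        return PseudoBulkSet(
            expression=self.expression[:, idx],
            truth=self.truth[idx],
            gene_ids=list(self.gene_ids),
            cells_per_sample=self.cells_per_sample,
            source_tag=self.source_tag,
            seed=self.seed,
        )


def sample_fractions(
    n_samples: int,
    mode: str = "dense",
    seed: int = 0,
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
    stratified: bool = False,
) -> np.ndarray:
    """Random composition matrix (n_samples x 15), rows on the simplex.

    dense: independent uniforms per type, normalized. sparse: a random
    subset of types is zeroed before normalization. pure: one type per
    sample at fraction 1 (with ``stratified=True`` types are cycled in
    vocabulary order instead of drawn at random).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    T = len(vocab)
    rng = np.random.default_rng(seed)
    if mode == "dense":
        F = rng.uniform(size=(n_samples, T))
    elif mode == "sparse":
        F = rng.uniform(size=(n_samples, T))
        for i in range(n_samples):
            n_zero = rng.integers(1, T)  # keep at least one type
            F[i, rng.choice(T, size=n_zero, replace=False)] = 0.0
    elif mode == "pure":
        F = np.zeros((n_samples, T))
        if stratified:
            types = np.arange(n_samples) % T
        else:
            types = rng.integers(0, T, size=n_samples)
        F[np.arange(n_samples), types] = 1.0
        return F
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return F / F.sum(axis=1, keepdims=True)


def _allocate_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` cells to types.

    Ties in the remainder are broken by vocabulary order, making the
    allocation deterministic.
    """
    raw = fractions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        remainder = raw - base
        order = np.lexsort((np.arange(fractions.size), -remainder))
        base[order[:short]] += 1
    return base


def _type_pools(
    type_labels: np.ndarray,
    vocab: CellTypeVocabulary,
    cell_ids: list[str] | None,
) -> list[np.ndarray]:
    """Per-type cell indices, ordered by cell id when ids are given."""
    pools = []
    for tname in vocab:
        pool = np.flatnonzero(np.asarray(type_labels) == tname)
        if cell_ids is not None and pool.size:
            pool = pool[np.argsort([cell_ids[i] for i in pool], kind="stable")]
        pools.append(pool)
    return pools


def mix(
    expression: np.ndarray,
    type_labels: np.ndarray,
    fractions: np.ndarray,
    cells_per_sample: int = 500,
    seed: int = 0,
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
    cell_ids: list[str] | None = None,
    _pools: list[np.ndarray] | None = None,
) -> np.ndarray:
    """One pseudo-bulk profile: per-gene mean of cells drawn at the fractions.

    Cell counts per type follow largest-remainder rounding of
    ``fraction * cells_per_sample``; cells are drawn with replacement.
    Within each type the pool is ordered by cell id (falling back to the
    labels' positional order), so the draw is invariant to pool
    reordering at a fixed seed.
    """
    fractions = np.asarray(fractions, dtype=float)
    type_labels = np.asarray(type_labels)
    if fractions.size != len(vocab):
        raise ValueError("fractions must have one entry per vocabulary type")
    rng = np.random.default_rng(seed)
    alloc = _allocate_counts(fractions, cells_per_sample)
    pools = _pools if _pools is not None else _type_pools(type_labels, vocab, cell_ids)
    total = np.zeros(expression.shape[0])
    for t, tname in enumerate(vocab):
        n = alloc[t]
        if n == 0:
            continue
        pool = pools[t]
        if pool.size == 0:
            raise ValueError(f"no cells available for type {tname!r} with positive fraction")
        chosen = pool[rng.integers(0, pool.size, size=n)]
        total += expression[:, chosen].sum(axis=1)
    return total / cells_per_sample


def build_set(
    expression: np.ndarray,
    type_labels: np.ndarray,
    gene_ids: list[str],
    n_samples: int = 8000,
    cells_per_sample: int = 500,
    mode: str = "dense",
    seed: int = 0,
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
    source_tag: str = "",
    cell_ids: list[str] | None = None,
    stratified: bool = False,
) -> PseudoBulkSet:
    """Simulate a full pseudo-bulk set; reproducible from ``seed``."""
    truth = sample_fractions(n_samples, mode=mode, seed=seed, vocab=vocab, stratified=stratified)
    rng = np.random.default_rng(seed + 1)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n_samples)
    pools = _type_pools(type_labels, vocab, cell_ids)
    X = np.empty((expression.shape[0], n_samples))
    for i in range(n_samples):
        X[:, i] = mix(
            expression,
            type_labels,
            truth[i],
            cells_per_sample=cells_per_sample,
            seed=int(sample_seeds[i]),
            vocab=vocab,
            _pools=pools,
        )
    return PseudoBulkSet(
        expression=X,
        truth=truth,
        gene_ids=list(gene_ids),
        cells_per_sample=cells_per_sample,
        source_tag=source_tag,
        seed=seed,
    )
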