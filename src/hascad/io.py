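"""Readers and writers for the on-disk formats.

Expression travels as Matrix Market directories (matrix.mtx plus
genes.tsv / barcodes.tsv / labels.tsv sidecars) or as dense TSV/CSV with
genes as rows; gzip-compressed text is accepted transparently. Fraction
matrices are TSV with the vocabulary as header and one row per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .bulksim import PseudoBulkSet
from .synthetic import CellMatrix
from .vocabulary import CellTypeVocabulary, DEFAULT_VOCABULARY

__all__ = [
    "read_expression",
    "write_mtx_dir",
    "read_mtx_dir",
    "write_dense_tsv",
    "write_fractions",
    "read_fractions",
    "write_bulk_set",
    "read_bulk_set",
]


def _check_unique(gene_ids: list[str]) -> None:
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise ValueError(f"duplicated gene id {g!r}")
        seen.add(g)


def write_mtx_dir(cells: CellMatrix, outdir) -> Path:
    """Matrix Market triple (matrix.mtx, genes.tsv, barcodes.tsv) + labels.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(cells.counts))
    (outdir / "genes.tsv").write_text("".join(f"{g}\n" for g in cells.gene_ids))
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cells.cell_ids))
    labels = pd.DataFrame(
        {
            "cell_id": cells.cell_ids,
            "batch": cells.batch_labels,
            "cell_type": cells.type_labels,
        }
    )
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    return outdir


def read_mtx_dir(indir) -> CellMatrix:
    indir = Path(indir)
    counts = np.asarray(spio.mmread(indir / "matrix.mtx").todense())
    gene_ids = (indir / "genes.tsv").read_text().splitlines()
    cell_ids = (indir / "barcodes.tsv").read_text().splitlines()
    _check_unique(gene_ids)
    labels_path = indir / "labels.tsv"
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t", dtype=str)
        labels = labels.set_index("cell_id").loc[cell_ids]
        batch = labels["batch"].to_numpy()
        ctype = labels["cell_type"].to_numpy()
    else:
        batch = np.array(["batch0"] * len(cell_ids))
        ctype = np.array(["unknown"] * len(cell_ids))
    return CellMatrix(counts, gene_ids, cell_ids, batch, ctype)


def write_dense_tsv(matrix: np.ndarray, gene_ids, sample_ids, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.asarray(matrix), index=list(gene_ids), columns=list(sample_ids))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    return path


def read_expression(path, fmt: str | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a genes x samples matrix; returns (matrix, gene_ids, sample_ids).

    ``fmt`` is one of mtx_dir / tsv / csv, inferred from the path when
    omitted. Gene ids must be unique. Gzipped text files are accepted.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx_dir"
        elif ".csv" in path.name:
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "mtx_dir":
        cells = read_mtx_dir(path)
        return cells.counts.astype(float), list(cells.gene_ids), list(cells.cell_ids)
    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    gene_ids = [str(g) for g in df.index]
    _check_unique(gene_ids)
    return df.to_numpy(dtype=float), gene_ids, [str(c) for c in df.columns]


def write_fractions(
    matrix: np.ndarray,
    path,
    sample_ids: list[str] | None = None,
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
    force: bool = False,
) -> Path:
    """TSV of composition rows: sample id first, then the 15 vocabulary columns."""
    M = np.atleast_2d(np.asarray(matrix, dtype=float))
    if M.size and M.shape[1] != len(vocab):
        raise ValueError("fraction columns must match the vocabulary")
    if M.size and not force:
        if (M < -1e-9).any() or not np.allclose(M.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows are not on the simplex (use force=True to override)")
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(M.shape[0])]
    df = pd.DataFrame(M, index=sample_ids, columns=list(vocab))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    return Path(path)


def read_fractions(path, vocab: CellTypeVocabulary = DEFAULT_VOCABULARY):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(vocab):
        raise ValueError("fraction file header does not match the vocabulary")
    return df.to_numpy(dtype=float), [str(s) for s in df.index]


def write_bulk_set(bulk: PseudoBulkSet, outdir, vocab: CellTypeVocabulary = DEFAULT_VOCABULARY) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = [f"sample{i}" for i in range(bulk.n_samples)]
    write_dense_tsv(bulk.expression, bulk.gene_ids, samples, outdir / "expression.tsv")
    write_fractions(bulk.truth, outdir / "truth.tsv", samples, vocab=vocab)
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "cells_per_sample": bulk.cells_per_sample,
                "source_tag": bulk.source_tag,
                "seed": bulk.seed,
                "n_samples": bulk.n_samples,
            },
            indent=2,
        )
    )
    return outdir


def read_bulk_set(indir, vocab: CellTypeVocabulary = DEFAULT_VOCABULARY) -> PseudoBulkSet:
    indir = Path(indir)
    expr, gene_ids, _ = read_expression(indir / "expression.tsv", fmt="tsv")
    truth, _ = read_fractions(indir / "truth.tsv", vocab=vocab)
    man = json.loads((indir / "manifest.json").read_text())
    return PseudoBulkSet(
        expression=expr,
        truth=truth,
        gene_ids=gene_ids,
        cells_per_sample=man["cells_per_sample"],
        source_tag=man["source_tag"],
        seed=man["seed"],
    )
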