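"""Evaluation battery for deconvolution predictions.

Per-sample Pearson correlation and mean squared error across the 15
types, aggregation of subtype fractions into parent classes, major-type
calls for pure-type samples, Bland-Altman agreement statistics, and the
two cross-validation harnesses (sample-level k-fold and
leave-one-dataset-out over batches).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bulksim, harmonize
from .deconvnet import DeconvolutionEnsemble, EnsembleSpec, loss_components
from .synthetic import CellMatrix
from .vocabulary import CellTypeVocabulary, DEFAULT_VOCABULARY

__all__ = [
    "TypeMapping",
    "PURE_TYPE_MAPPING",
    "PBMC_MAPPING",
    "EvaluationReport",
    "per_sample_pcc",
    "per_sample_mse",
    "aggregate",
    "major_type",
    "bland_altman",
    "make_report",
    "kfold_cv",
    "leave_one_dataset_out",
]


# ---------------------------------------------------------------------------
# type aggregation


@dataclass(frozen=True)
class TypeMapping:
    """Parent class -> child cell types, children disjoint across parents."""

    parents: dict[str, tuple[str, ...]]
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for parent, children in self.parents.items():
            for c in children:
                if c not in self.vocab:
                    raise ValueError(f"unknown child type {c!r} under {parent!r}")
                if c in seen:
                    raise ValueError(f"child type {c!r} mapped to more than one parent")
                seen.add(c)

    @property
    def parent_names(self) -> list[str]:
        return list(self.parents)

    @property
    def mapped_children(self) -> set[str]:
        return {c for ch in self.parents.values() for c in ch}


#: the four pure-type benchmark classes and their child subtypes
PURE_TYPE_MAPPING = TypeMapping(
    {
        "B cells": ("bnaive", "bmem"),
        "CD4 T cells": ("cd4mem", "cd4naive", "treg"),
        "Dendritic cells": ("pDC", "aDC"),
        "Monocytes": ("mono14", "mono16"),
    }
)

#: mapping to the experimentally measured PBMC classes (NK/B/DC/monocyte/CD8/CD4/Treg)
PBMC_MAPPING = TypeMapping(
    {
        "NK": ("nk",),
        "B cell": ("bnaive", "bmem"),
        "DC": ("pDC", "aDC"),
        "monocyte": ("mono14", "mono16"),
        "CD8": ("cd8naive", "cd8eff", "cd8mem"),
        "CD4": ("cd4naive", "cd4mem"),
        "Treg": ("treg",),
    }
)


def aggregate(pred: np.ndarray, mapping: TypeMapping) -> pd.DataFrame:
    """Sum child fractions into parent classes; unmapped mass goes to "other"."""
    P = np.atleast_2d(np.asarray(pred, dtype=float))
    vocab = mapping.vocab
    if P.shape[1] != len(vocab):
        raise ValueError("prediction columns must match the vocabulary")
    cols = {}
    for parent, children in mapping.parents.items():
        idx = [vocab.index(c) for c in children]
        cols[parent] = P[:, idx].sum(axis=1)
    unmapped = [i for i, name in enumerate(vocab) if name not in mapping.mapped_children]
    cols["other"] = P[:, unmapped].sum(axis=1) if unmapped else np.zeros(P.shape[0])
    return pd.DataFrame(cols)


def major_type(
    pred_row: np.ndarray,
    mapping: TypeMapping | None = None,
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
    include_other: bool = True,
) -> str:
    """Highest-fraction (optionally aggregated) class; ties break by order."""
    row = np.asarray(pred_row, dtype=float)
    if mapping is None:
        return vocab[int(np.argmax(row))]  # argmax takes the first tie
    agg = aggregate(row, mapping)
    if not include_other:
        agg = agg.drop(columns="other")
    return str(agg.columns[int(np.argmax(agg.iloc[0].to_numpy()))])


# ---------------------------------------------------------------------------
# per-sample metrics


def per_sample_pcc(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Pearson r across the types of each sample; zero variance -> 0."""
    mse, pcc_loss = loss_components(truth, pred)
    if np.any(pcc_loss == 1.0):
        constant = np.flatnonzero(pcc_loss == 1.0)
        warnings.warn(
            f"{constant.size} sample(s) with zero variance; their PCC is set to 0",
            stacklevel=2,
        )
    return 1.0 - pcc_loss


def per_sample_mse(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Mean squared difference across the types of each sample."""
    mse, _ = loss_components(truth, pred)
    return mse


def bland_altman(
    truth: np.ndarray, pred: np.ndarray, vocab: CellTypeVocabulary = DEFAULT_VOCABULARY
) -> dict:
    """Per-type mean and SD of (prediction - truth), plus the pooled SD."""
    Y = np.atleast_2d(np.asarray(truth, dtype=float))
    P = np.atleast_2d(np.asarray(pred, dtype=float))
    if Y.shape != P.shape:
        raise ValueError("truth and prediction shapes differ")
    diff = P - Y
    return {
        "types": list(vocab) if Y.shape[1] == len(vocab) else list(range(Y.shape[1])),
        "mean": diff.mean(axis=0),
        "sd": diff.std(axis=0),
        "overall_sd": float(diff.std()),
    }


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvaluationReport:
    """Predictions with their per-sample metrics and summaries."""

    truth: np.ndarray
    predictions: np.ndarray
    pcc: np.ndarray
    mse: np.ndarray
    bland_altman: dict
    confusion: pd.DataFrame | None = None
    folds: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def median_pcc(self) -> float:
        return float(np.median(self.pcc))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.mse))

    def summary(self) -> dict:
        out = {
            "n_samples": int(self.truth.shape[0]),
            "median_pcc": self.median_pcc,
            "mean_pcc": float(np.mean(self.pcc)),
            "mean_mse": self.mean_mse,
            "overall_sd": self.bland_altman["overall_sd"],
        }
        out.update(self.extra)
        return out

    def to_json(self, path) -> None:
        payload = {
            "summary": self.summary(),
            "per_sample_pcc": self.pcc.tolist(),
            "per_sample_mse": self.mse.tolist(),
            "bland_altman": {
                "types": list(self.bland_altman["types"]),
                "mean": np.asarray(self.bland_altman["mean"]).tolist(),
                "sd": np.asarray(self.bland_altman["sd"]).tolist(),
                "overall_sd": self.bland_altman["overall_sd"],
            },
        }
        if self.confusion is not None:
            payload["confusion"] = self.confusion.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def confusion_table(true_classes, called_classes) -> pd.DataFrame:
    """Rows = true class, columns = called class, values = sample counts."""
    return pd.crosstab(
        pd.Series(list(true_classes), name="true"),
        pd.Series(list(called_classes), name="called"),
    )


def make_report(truth: np.ndarray, pred: np.ndarray, **extra) -> EvaluationReport:
    mse, pcc_loss = loss_components(truth, pred)
    return EvaluationReport(
        truth=np.asarray(truth),
        predictions=np.asarray(pred),
        pcc=1.0 - pcc_loss,
        mse=mse,
        bland_altman=bland_altman(truth, pred),
        extra=extra,
    )


# ---------------------------------------------------------------------------
# cross-validation harnesses


def kfold_cv(
    bulk: bulksim.PseudoBulkSet,
    k: int = 10,
    spec: EnsembleSpec | None = None,
    max_epochs: int | None = None,
    val_fraction: float = 0.1,
    seed: int = 0,
    keep_models: bool = False,
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
) -> EvaluationReport:
    """Sample-level k-fold cross-validation of the ensemble.

    Folds are a seeded disjoint partition of the pseudo-bulk samples.
    For each fold an ensemble is trained on the remaining samples (with
    ``val_fraction`` of them carved out for early stopping) and predicts
    the held-out fold; metrics are pooled over all held-out predictions.
    """
    n = bulk.n_samples
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % k
    spec = spec if spec is not None else EnsembleSpec(seed=seed)

    preds = np.zeros_like(bulk.truth)
    models = []
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        fit_idx = np.flatnonzero(folds != fold)
        fit_rng = np.random.default_rng(seed * 1000 + fold)
        fit_idx = fit_rng.permutation(fit_idx)
        n_val = max(1, int(round(val_fraction * fit_idx.size)))
        val_set = bulk.subset(fit_idx[:n_val])
        train_set = bulk.subset(fit_idx[n_val:])
        ens = DeconvolutionEnsemble.build(spec, bulk.gene_ids, vocab)
        ens.train(train_set, val_set, max_epochs=max_epochs)
        preds[test_idx] = ens.predict(bulk.expression[:, test_idx])
        if keep_models:
            models.append(ens)

    report = make_report(bulk.truth, preds, k=k)
    report.folds = folds
    if keep_models:
        report.extra["models"] = models
    return report


def leave_one_dataset_out(
    cells: CellMatrix,
    n_top: int = 512,
    d: int = 20,
    n_train: int = 2000,
    n_val: int = 500,
    n_test: int = 500,
    cells_per_sample: int = 500,
    spec: EnsembleSpec | None = None,
    max_epochs: int | None = None,
    correct: bool = True,
    seed: int = 0,
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
) -> dict[str, EvaluationReport]:
    """Hold out each batch in turn; train on the others, test on the held-out.

    For every batch, a reference is built from the remaining batches
    (Harmony-corrected when ``correct``), training/validation pseudo-bulk
    is simulated from it, and test pseudo-bulk is simulated from the
    held-out batch after Symphony-style projection into the reference
    space (or from its raw log-CP10K profile when ``correct`` is False).
    """
    batches = cells.batch_names
    if len(batches) < 2:
        raise ValueError("leave-one-dataset-out requires at least two batches")
    spec = spec if spec is not None else EnsembleSpec(seed=seed)
    reports: dict[str, EvaluationReport] = {}
    for held in batches:
        train_cells = cells.subset_batches([b for b in batches if b != held])
        test_cells = cells.subset_batches([held])
        assert not set(test_cells.cell_ids) & set(train_cells.cell_ids)
        ref = harmonize.build_reference(
            train_cells, n_top=n_top, d=d, seed=seed, correct=correct
        )
        pool = ref.corrected_expression if correct else ref.normalized_expression
        train_set = bulksim.build_set(
            pool, ref.type_labels, ref.scaling.selected_genes,
            n_samples=n_train, cells_per_sample=cells_per_sample,
            seed=seed, vocab=vocab, source_tag="train",
        )
        val_set = bulksim.build_set(
            pool, ref.type_labels, ref.scaling.selected_genes,
            n_samples=n_val, cells_per_sample=cells_per_sample,
            seed=seed + 1, vocab=vocab, source_tag="val",
        )
        test_norm = harmonize.log_cp10k(test_cells.counts)
        if correct:
            proj = harmonize.project_query(test_norm, test_cells.gene_ids, ref)
            test_pool = proj.corrected_query_expression
        else:
            sel = [test_cells.gene_ids.index(g) for g in ref.scaling.selected_genes]
            test_pool = test_norm[sel]
        test_set = bulksim.build_set(
            test_pool, test_cells.type_labels, ref.scaling.selected_genes,
            n_samples=n_test, cells_per_sample=cells_per_sample,
            seed=seed + 2, vocab=vocab, source_tag=f"test:{held}",
        )
        ens = DeconvolutionEnsemble.build(spec, ref.scaling.selected_genes, vocab)
        ens.train(train_set, val_set, max_epochs=max_epochs)
        pred = ens.predict(test_set.expression)
        reports[held] = make_report(test_set.truth, pred, held_out=held)
    return reports
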