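"""Batch-corrected single-cell references and query projection.

The reference build follows the Harmony recipe: log-CP10K normalization,
VST-style variable-gene selection, per-gene standardization, a PCA
embedding ``Z = SigmaV^T`` with gene loadings ``U``, then an iterative
correction that alternates a diversity-penalized soft k-means with a
per-cluster ridge regression removing batch-specific linear offsets from
the embedding. ``U @ Z'`` mapped back through the inverse standardization
is the corrected expression used for pseudo-bulk simulation.

Queries (bulk samples or new cells) are projected Symphony-style: align
genes to the reference, standardize with the *reference* scaling, embed
with the reference loadings, softly assign to the reference clusters and
remove the query-wide offset against the reference cluster means.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .synthetic import CellMatrix

__all__ = [
    "ScalingParams",
    "EmbeddingSet",
    "ClusterState",
    "ReferenceModel",
    "QueryProjection",
    "log_cp10k",
    "tpm",
    "vst_select",
    "standardize",
    "embed",
    "correct_embedding",
    "reconstruct",
    "project_query",
    "build_reference",
    "batch_mixing_entropy",
]

logger = logging.getLogger(__name__)

_CLIP = 10.0  # standardized expression is clipped at +/-10, Harmony-style


# ---------------------------------------------------------------------------
# normalizations


def log_cp10k(counts: np.ndarray) -> np.ndarray:
    """log2(count / cell_total * 1e4 + 1), per cell (column)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(f"cells with zero total counts at columns {bad[:10].tolist()}")
    return np.log2(counts / totals[None, :] * 1e4 + 1.0)


def tpm(counts: np.ndarray) -> np.ndarray:
    """Scale each sample (column) to sum to one million."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(f"samples with zero total at columns {bad[:10].tolist()}")
    return counts / totals[None, :] * 1e6


# ---------------------------------------------------------------------------
# variable genes and scaling


@dataclass
class ScalingParams:
    """Selected genes with their standardization statistics."""

    selected_genes: list[str]
    mean: np.ndarray
    scale: np.ndarray
    transform_tag: str = "log_cp10k"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if len(set(self.selected_genes)) != len(self.selected_genes):
            raise ValueError("selected_genes must be unique")
        if not (len(self.selected_genes) == self.mean.size == self.scale.size):
            raise ValueError("scaling vectors must match the gene list")
        if (self.scale <= 0).any():
            raise ValueError("scale must be strictly positive for every retained gene")


def vst_select(
    matrix: np.ndarray,
    gene_ids: list[str],
    n_top: int,
    transform_tag: str = "log_cp10k",
) -> ScalingParams:
    """Rank genes by standardized variance about a mean-variance trend.

    Fits a degree-2 polynomial of log10(variance) on log10(mean) over the
    expressed genes, computes each gene's variance of trend-standardized
    values clipped at sqrt(n_cells), and keeps the ``n_top`` genes with the
    highest clipped standardized variance. Per-gene mean and (observed)
    standard deviation of the retained genes are recorded for later
    standardization. Deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_cells = matrix.shape
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length does not match matrix rows")
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds the {n_genes} available genes")
    mu = matrix.mean(axis=1)
    var = matrix.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    usable = (var > 0) & (mu > 0)
    if not usable.any():
        raise ValueError("no variable genes: the matrix is constant per gene")

    lm, lv = np.log10(mu[usable]), np.log10(var[usable])
    if usable.sum() >= 3:
        coef = np.polyfit(lm, lv, deg=2)
    else:  # too few points for a trend; flat fit
        coef = np.array([0.0, 0.0, lv.mean()])
    expected_sd = np.sqrt(10.0 ** np.polyval(coef, np.log10(np.maximum(mu, 1e-12))))
    expected_sd[~usable] = np.inf  # zero-variance genes can never rank

    clip = np.sqrt(n_cells)
    z = (matrix - mu[:, None]) / expected_sd[:, None]
    np.clip(z, -clip, clip, out=z)
    std_var = z.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    std_var[~usable] = -np.inf

    order = np.argsort(-std_var, kind="stable")[:n_top]
    order = np.sort(order)  # keep input gene order within the selection
    sd = np.sqrt(var[order])
    sd = np.maximum(sd, 1e-8)
    return ScalingParams(
        selected_genes=[gene_ids[i] for i in order],
        mean=mu[order],
        scale=sd,
        transform_tag=transform_tag,
    )


def standardize(matrix: np.ndarray, scaling: ScalingParams) -> np.ndarray:
    """Per-gene z-score of the selected-gene matrix, clipped at +/-10."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(scaling.selected_genes):
        raise ValueError("matrix rows must match selected_genes")
    z = (matrix - scaling.mean[:, None]) / scaling.scale[:, None]
    return np.clip(z, -_CLIP, _CLIP)


# ---------------------------------------------------------------------------
# embedding


@dataclass
class EmbeddingSet:
    """PCA factorization M = U Sigma V^T with Z = Sigma V^T (d x cells)."""

    U: np.ndarray
    Z: np.ndarray
    Z_corrected: np.ndarray
    d: int

    def __post_init__(self) -> None:
        if self.Z.shape != self.Z_corrected.shape:
            raise ValueError("Z and Z_corrected must share shape")
        if self.U.shape[1] != self.d or self.Z.shape[0] != self.d:
            raise ValueError("inconsistent embedding dimension")


def embed(scaled_matrix: np.ndarray, d: int) -> EmbeddingSet:
    """Top-d SVD of the standardized genes x cells matrix.

    Signs are fixed so the largest-magnitude loading of each component is
    positive, making repeated runs bit-identical. If ``d`` exceeds the
    numerical rank it is reduced with a warning.
    """
    X = np.asarray(scaled_matrix, dtype=float)
    if d > min(X.shape):
        raise ValueError(f"d={d} exceeds min(genes, cells)={min(X.shape)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if d > rank:
        warnings.warn(f"requested d={d} exceeds rank {rank}; reduced", stacklevel=2)
        d = rank
    U = U[:, :d]
    Z = s[:d, None] * Vt[:d]
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    U = U * flip[None, :]
    Z = Z * flip[:, None]
    return EmbeddingSet(U=U, Z=Z, Z_corrected=Z.copy(), d=d)


# ---------------------------------------------------------------------------
# diversity-penalized correction


@dataclass
class ClusterState:
    """Soft clustering of the corrected embedding.

    centroids live on the unit sphere used for assignment; cluster_means
    are membership-weighted means in the (unnormalized) corrected
    embedding, used when projecting queries.
    """

    centroids: np.ndarray  # d x K, unit columns
    assignments: np.ndarray  # K x cells, columns sum to 1
    theta: float
    sigma: float
    K: int
    cluster_means: np.ndarray = field(default=None)  # d x K
    cluster_weights: np.ndarray = field(default=None)  # K
    objective: list[float] = field(default_factory=list)


def _soft_assign(Zn: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """Soft k-means responsibilities on the unit sphere (no penalty)."""
    d2 = 2.0 * (1.0 - Y.T @ Zn)  # K x N
    logr = -d2 / sigma
    logr -= logr.max(axis=0, keepdims=True)
    R = np.exp(logr)
    return R / R.sum(axis=0, keepdims=True)


def _normalize_cols(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=0)
    norms[norms == 0] = 1.0
    return Z / norms[None, :]


def _objective(R, d2, O, E, sigma, theta) -> float:
    ent = float(np.sum(R * np.log(np.maximum(R, 1e-300))))
    div = float(np.sum(O * np.log((O + 1.0) / (E + 1.0))))
    return float(np.sum(R * d2)) + sigma * ent + sigma * theta * div


def correct_embedding(
    embedding: EmbeddingSet,
    batch_labels: np.ndarray,
    K: int | None = None,
    theta: float = 2.0,
    sigma: float = 0.1,
    max_iter: int = 10,
    tol: float = 1e-4,
    ridge: float = 1e-3,
    seed: int = 0,
    block_frac: float = 0.05,
    global_center: bool = True,
) -> tuple[EmbeddingSet, ClusterState]:
    """Iterative batch correction of the embedding.

    With ``global_center`` (default) the per-batch grand-mean offsets are
    removed first -- the K=1 limit of the mixture correction, which
    eliminates any pure translation exactly. Then the routine alternates
    (i) a soft k-means on the cosine sphere whose assignments are
    penalized (strength ``theta``, temperature ``sigma``) when a
    cluster's batch composition deviates from the global batch
    proportions, and (ii) a per-cluster, membership-weighted ridge
    regression that removes batch-specific offsets from the centered
    embedding. Stops when the relative change of the clustering objective
    drops below ``tol`` or after ``max_iter`` rounds.
    """
    batch_labels = np.asarray(batch_labels)
    names = sorted(set(map(str, batch_labels)))
    N = embedding.Z.shape[1]
    if batch_labels.size != N:
        raise ValueError("batch_labels must have one entry per cell")
    if len(names) < 2:
        logger.info("single batch: nothing to correct")
        out = EmbeddingSet(embedding.U, embedding.Z, embedding.Z.copy(), embedding.d)
        state = ClusterState(
            centroids=np.zeros((embedding.d, 0)),
            assignments=np.zeros((0, N)),
            theta=theta,
            sigma=sigma,
            K=0,
        )
        return out, state

    if K is None:
        K = max(2, min(100, N // 30))
    if K < 2:
        raise ValueError("K must be at least 2")

    B = len(names)
    bidx = np.array([names.index(str(b)) for b in batch_labels])
    Phi = np.zeros((B, N))
    Phi[bidx, np.arange(N)] = 1.0
    pr_b = Phi.mean(axis=1)  # global batch proportions

    Z0 = embedding.Z.copy()
    if global_center:
        grand = Z0.mean(axis=1, keepdims=True)
        for b in range(B):
            sel = bidx == b
            Z0[:, sel] -= Z0[:, sel].mean(axis=1, keepdims=True) - grand
    Zc = Z0.copy()
    rng = np.random.default_rng(seed)

    Zn = _normalize_cols(Zc)
    km = KMeans(n_clusters=K, random_state=seed, n_init=4).fit(Zn.T)
    Y = _normalize_cols(km.cluster_centers_.T)
    R = _soft_assign(Zn, Y, sigma)

    objective: list[float] = []
    block = max(1, int(np.ceil(block_frac * N)))
    for _ in range(max_iter):
        # -- clustering with diversity penalty, Harmony-style block updates
        O = R @ Phi.T  # K x B observed co-occurrence
        for _pass in range(2):
            order = rng.permutation(N)
            for start in range(0, N, block):
                cells = order[start : start + block]
                O -= R[:, cells] @ Phi[:, cells].T
                E = R.sum(axis=1, keepdims=True) - R[:, cells].sum(axis=1, keepdims=True)
                E = E * pr_b[None, :]
                d2 = 2.0 * (1.0 - Y.T @ Zn[:, cells])
                pen = theta * np.log((E[:, bidx[cells]] + 1.0) / (O[:, bidx[cells]] + 1.0))
                logr = (-d2 + pen) / sigma
                logr -= logr.max(axis=0, keepdims=True)
                Rb = np.exp(logr)
                R[:, cells] = Rb / Rb.sum(axis=0, keepdims=True)
                O += R[:, cells] @ Phi[:, cells].T
        Y = _normalize_cols((R @ Zn.T).T)

        d2_all = 2.0 * (1.0 - Y.T @ Zn)
        E_all = R.sum(axis=1, keepdims=True) * pr_b[None, :]
        objective.append(_objective(R, d2_all, R @ Phi.T, E_all, sigma, theta))

        # -- mixture-of-experts ridge correction against the original Z
        Zc = Z0.copy()
        Phi_star = np.vstack([np.ones(N), Phi])  # intercept + batch design
        lam = np.full(B + 1, ridge)
        lam[0] = 0.0  # intercept not penalized
        for k in range(K):
            Rk = R[k]
            A = Phi_star * Rk[None, :]
            M = A @ Phi_star.T + np.diag(lam)
            W = np.linalg.solve(M, A @ Z0.T)  # (1+B) x d
            Zc -= (Rk[:, None] * W[1 + bidx]).T
        if global_center:
            # keep per-batch grand means aligned: the summed soft-weighted
            # cluster corrections may otherwise reintroduce a net offset
            grand = Zc.mean(axis=1, keepdims=True)
            for b in range(B):
                sel = bidx == b
                Zc[:, sel] -= Zc[:, sel].mean(axis=1, keepdims=True) - grand
        Zn = _normalize_cols(Zc)

        if len(objective) > 1:
            prev, cur = objective[-2], objective[-1]
            if abs(prev - cur) / max(abs(prev), 1e-12) < tol:
                break

    weights = R.sum(axis=1)
    means = (Zc @ R.T) / np.maximum(weights, 1e-12)[None, :]
    state = ClusterState(
        centroids=Y,
        assignments=R,
        theta=theta,
        sigma=sigma,
        K=K,
        cluster_means=means,
        cluster_weights=weights,
        objective=objective,
    )
    corrected = EmbeddingSet(U=embedding.U, Z=embedding.Z, Z_corrected=Zc, d=embedding.d)
    return corrected, state


def reconstruct(embedding: EmbeddingSet, scaling: ScalingParams) -> np.ndarray:
    """U @ Z' mapped back to the expression scale (x scale + mean, clipped at 0)."""
    X = embedding.U @ embedding.Z_corrected
    X = X * scaling.scale[:, None] + scaling.mean[:, None]
    return np.maximum(X, 0.0)


# ---------------------------------------------------------------------------
# the reference model and query projection


@dataclass
class ReferenceModel:
    """Everything needed to simulate training data and project queries."""

    scaling: ScalingParams
    embedding: EmbeddingSet
    clusters: ClusterState
    batch_names: list[str]
    corrected_expression: np.ndarray  # selected genes x cells
    normalized_expression: np.ndarray  # selected genes x cells, pre-correction
    cell_ids: list[str]
    batch_labels: np.ndarray
    type_labels: np.ndarray

    def __post_init__(self) -> None:
        if self.corrected_expression.shape[0] != len(self.scaling.selected_genes):
            raise ValueError("corrected_expression rows must equal |selected_genes|")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("U", data=self.embedding.U)
            f.create_dataset("Z", data=self.embedding.Z)
            f.create_dataset("Z_corrected", data=self.embedding.Z_corrected)
            f.create_dataset("centroids", data=self.clusters.centroids)
            f.create_dataset("assignments", data=self.clusters.assignments)
            if self.clusters.cluster_means is not None:
                f.create_dataset("cluster_means", data=self.clusters.cluster_means)
                f.create_dataset("cluster_weights", data=self.clusters.cluster_weights)
            f.create_dataset("corrected_expression", data=self.corrected_expression)
            f.create_dataset("normalized_expression", data=self.normalized_expression)
            f.create_dataset("mean", data=self.scaling.mean)
            f.create_dataset("scale", data=self.scaling.scale)
            str_dt = h5py.string_dtype()
            f.create_dataset("genes", data=self.scaling.selected_genes, dtype=str_dt)
            f.create_dataset("cell_ids", data=self.cell_ids, dtype=str_dt)
            f.create_dataset("batch_labels", data=list(map(str, self.batch_labels)), dtype=str_dt)
            f.create_dataset("type_labels", data=list(map(str, self.type_labels)), dtype=str_dt)
            f.attrs["manifest"] = json.dumps(
                {
                    "transform_tag": self.scaling.transform_tag,
                    "d": self.embedding.d,
                    "K": self.clusters.K,
                    "theta": self.clusters.theta,
                    "sigma": self.clusters.sigma,
                    "batch_names": self.batch_names,
                    "objective": self.clusters.objective,
                }
            )

    @classmethod
    def load(cls, path) -> "ReferenceModel":
        with h5py.File(path, "r") as f:
            man = json.loads(f.attrs["manifest"])
            genes = [g.decode() if isinstance(g, bytes) else g for g in f["genes"][...]]
            scaling = ScalingParams(genes, f["mean"][...], f["scale"][...], man["transform_tag"])
            emb = EmbeddingSet(f["U"][...], f["Z"][...], f["Z_corrected"][...], man["d"])
            clusters = ClusterState(
                centroids=f["centroids"][...],
                assignments=f["assignments"][...],
                theta=man["theta"],
                sigma=man["sigma"],
                K=man["K"],
                cluster_means=f["cluster_means"][...] if "cluster_means" in f else None,
                cluster_weights=f["cluster_weights"][...] if "cluster_weights" in f else None,
                objective=list(man.get("objective", [])),
            )
            decode = lambda ds: [x.decode() if isinstance(x, bytes) else x for x in ds[...]]
            return cls(
                scaling=scaling,
                embedding=emb,
                clusters=clusters,
                batch_names=man["batch_names"],
                corrected_expression=f["corrected_expression"][...],
                normalized_expression=f["normalized_expression"][...],
                cell_ids=decode(f["cell_ids"]),
                batch_labels=np.array(decode(f["batch_labels"])),
                type_labels=np.array(decode(f["type_labels"])),
            )


@dataclass
class QueryProjection:
    """Query samples mapped into the corrected reference space."""

    Zq: np.ndarray
    Zq_corrected: np.ndarray
    corrected_query_expression: np.ndarray


def project_query(
    query_expression: np.ndarray,
    query_gene_ids: list[str],
    reference: ReferenceModel,
    min_overlap: float = 0.5,
    query_ridge: float = 1.0,
) -> QueryProjection:
    """Project normalized query expression into the corrected reference space.

    The query must be on the same normalized scale as the reference
    (``reference.scaling.transform_tag``). Genes are aligned by id; genes
    absent from the query are imputed at the reference per-gene mean
    (zero after standardization). Query samples are softly assigned to
    the reference clusters and the membership-weighted query offset from
    the reference cluster means is removed (ridge-shrunk by
    ``query_ridge``), giving ``Z_q'`` and the corrected expression
    ``U @ Z_q'``.
    """
    X = np.asarray(query_expression, dtype=float)
    if X.shape[0] != len(query_gene_ids):
        raise ValueError("query gene ids must match expression rows")
    ref_genes = reference.scaling.selected_genes
    pos = {g: i for i, g in enumerate(query_gene_ids)}
    hits = [pos.get(g) for g in ref_genes]
    overlap = sum(h is not None for h in hits) / len(ref_genes)
    if overlap < min_overlap:
        raise ValueError(
            f"query shares only {overlap:.1%} of reference genes "
            f"(minimum {min_overlap:.0%})"
        )
    S = X.shape[1]
    aligned = np.tile(reference.scaling.mean[:, None], (1, S))
    for row, h in enumerate(hits):
        if h is not None:
            aligned[row] = X[h]

    Xs = standardize(aligned, reference.scaling)
    U = reference.embedding.U
    Zq = U.T @ Xs

    clusters = reference.clusters
    if clusters.K == 0 or clusters.cluster_means is None:
        Zq_c = Zq.copy()
    else:
        Rq = _soft_assign(_normalize_cols(Zq), clusters.centroids, clusters.sigma)
        mass = Rq.sum(axis=1)  # per-cluster query weight
        resid = Zq @ Rq.T - clusters.cluster_means * mass[None, :]
        delta = resid / (mass + query_ridge)[None, :]  # d x K offsets
        Zq_c = Zq - delta @ Rq
    expr = U @ Zq_c * reference.scaling.scale[:, None] + reference.scaling.mean[:, None]
    return QueryProjection(Zq=Zq, Zq_corrected=Zq_c, corrected_query_expression=np.maximum(expr, 0.0))


def build_reference(
    cells: CellMatrix,
    n_top: int = 512,
    d: int = 20,
    K: int | None = None,
    theta: float = 2.0,
    sigma: float = 0.1,
    max_iter: int = 10,
    tol: float = 1e-4,
    ridge: float = 1e-3,
    seed: int = 0,
    correct: bool = True,
) -> ReferenceModel:
    """Full reference build: normalize, select genes, embed, correct, reconstruct.

    With ``correct=False`` (or a single batch) the corrected expression is
    the rank-d reconstruction of the uncorrected embedding, which keeps the
    corrected/uncorrected comparison on the same representation.
    """
    norm = log_cp10k(cells.counts)
    scaling = vst_select(norm, cells.gene_ids, n_top)
    sel = [cells.gene_ids.index(g) for g in scaling.selected_genes]
    norm_sel = norm[sel]
    Xs = standardize(norm_sel, scaling)
    emb = embed(Xs, d)
    if correct and len(set(map(str, cells.batch_labels))) >= 2:
        emb, state = correct_embedding(
            emb, cells.batch_labels, K=K, theta=theta, sigma=sigma,
            max_iter=max_iter, tol=tol, ridge=ridge, seed=seed,
        )
    else:
        state = ClusterState(
            centroids=np.zeros((emb.d, 0)),
            assignments=np.zeros((0, emb.Z.shape[1])),
            theta=theta,
            sigma=sigma,
            K=0,
        )
    corrected = reconstruct(emb, scaling)
    return ReferenceModel(
        scaling=scaling,
        embedding=emb,
        clusters=state,
        batch_names=cells.batch_names,
        corrected_expression=corrected,
        normalized_expression=norm_sel,
        cell_ids=list(cells.cell_ids),
        batch_labels=np.asarray(cells.batch_labels),
        type_labels=np.asarray(cells.type_labels),
    )


def batch_mixing_entropy(
    embedding: np.ndarray, batch_labels: np.ndarray, k: int = 30
) -> float:
    """Mean per-cell entropy of batch labels among k nearest neighbors.

    Higher means better batch mixing; the score of a perfectly mixed
    dataset approaches the entropy of the global batch proportions.
    """
    Z = np.asarray(embedding, dtype=float)
    batch_labels = np.asarray(batch_labels)
    N = Z.shape[1]
    k = min(k, N - 1)
    names = sorted(set(map(str, batch_labels)))
    bidx = np.array([names.index(str(b)) for b in batch_labels])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z.T)
    _, idx = nn.kneighbors(Z.T)
    idx = idx[:, 1:]  # drop self
    ent = np.zeros(N)
    for b in range(len(names)):
        p = (bidx[idx] == b).mean(axis=1)
        mask = p > 0
        ent[mask] -= p[mask] * np.log(p[mask])
    return float(ent.mean())
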