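"""Ensemble feed-forward deconvolution model.

Three parallel multilayer perceptrons with softmax heads map a bulk
expression profile (over the reference gene list) to a 15-type
composition vector; the ensemble prediction is the arithmetic mean of
the three module outputs, which stays on the simplex by convexity.

Training minimizes a composite loss per sample,

    loss = MSE(truth, pred) + (1 - r(truth, pred)),

where the Pearson correlation r is taken across the 15 types of one
sample and defined as 0 when either vector has zero variance across
types. Optimization is Adam (lr 1e-4, batch 64) with early stopping on
validation loss (patience 20 epochs) and best-weight restoration.

The networks, backpropagation and Adam are implemented directly on
numpy arrays; gradients are verified against finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .bulksim import PseudoBulkSet
from .vocabulary import CellTypeVocabulary, DEFAULT_VOCABULARY

__all__ = [
    "ModuleSpec",
    "EnsembleSpec",
    "DeconvolutionEnsemble",
    "composite_loss",
    "loss_components",
]

_DTYPE = np.float32


# ---------------------------------------------------------------------------
# loss


def loss_components(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (MSE, PCC-loss) arrays.

    MSE is the mean squared difference over the types of one sample;
    the PCC loss is 1 - r across the types, with r := 0 when truth or
    prediction is constant across types.
    """
    Y = np.asarray(truth, dtype=float)
    P = np.asarray(pred, dtype=float)
    if Y.shape != P.shape:
        raise ValueError(f"shape mismatch: truth {Y.shape} vs pred {P.shape}")
    if Y.ndim == 1:
        Y, P = Y[None, :], P[None, :]
    T = Y.shape[1]
    mse = ((P - Y) ** 2).sum(axis=1) / T
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=1, keepdims=True)
    sy = np.linalg.norm(Yc, axis=1)
    sp = np.linalg.norm(Pc, axis=1)
    valid = (sy > 0) & (sp > 0)
    r = np.zeros(Y.shape[0])
    r[valid] = (Yc[valid] * Pc[valid]).sum(axis=1) / (sy[valid] * sp[valid])
    return mse, 1.0 - r


def composite_loss(truth: np.ndarray, pred: np.ndarray) -> float:
    """Mean over samples of per-sample MSE + (1 - Pearson r across types)."""
    mse, pcc_loss = loss_components(truth, pred)
    return float((mse + pcc_loss).mean())


def _loss_grad(Y: np.ndarray, P: np.ndarray) -> tuple[float, np.ndarray]:
    """Batch loss and its gradient with respect to the predictions."""
    B, T = Y.shape
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=1, keepdims=True)
    sy = np.linalg.norm(Yc, axis=1)
    sp = np.linalg.norm(Pc, axis=1)
    valid = (sy > 0) & (sp > 0)
    r = np.zeros(B, dtype=P.dtype)
    denom = np.where(valid, sy * sp, 1.0)
    r[valid] = ((Yc * Pc).sum(axis=1) / denom)[valid]
    loss = float((((P - Y) ** 2).sum(axis=1) / T + 1.0 - r).mean())
    # d/dP of -r; both terms are already mean-free across types
    grad_r = np.zeros_like(P)
    grad_r[valid] = (
        Yc[valid] / denom[valid][:, None]
        - r[valid][:, None] * Pc[valid] / (sp[valid] ** 2)[:, None]
    )
    grad = (2.0 * (P - Y) / T - grad_r) / B
    return loss, grad


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ModuleSpec:
    """One feed-forward module: three hidden layers, softmax over 15 types."""

    hidden_sizes: tuple[int, int, int]
    input_dim: int
    output_dim: int = 15
    activation: str = "relu"
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 3:
            raise ValueError("exactly three hidden layers are required")
        for h in self.hidden_sizes:
            if not 32 <= h <= 1024:
                raise ValueError(f"hidden size {h} outside the allowed [32, 1024]")
        if self.output_dim != 15:
            raise ValueError("output_dim must be 15")
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_sizes, self.output_dim)

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


_DEFAULT_HIDDEN = ((1024, 512, 256), (512, 256, 128), (256, 128, 64))


@dataclass(frozen=True)
class EnsembleSpec:
    """Hyperparameters of the three-module ensemble."""

    hidden_sizes: tuple[tuple[int, int, int], ...] = _DEFAULT_HIDDEN
    learning_rate: float = 1e-4
    batch_size: int = 64
    patience: int = 20
    max_epochs: int = 500
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 3:
            raise ValueError("the ensemble has exactly three modules")
        first = tuple(h[0] for h in self.hidden_sizes)
        if first != (1024, 512, 256):
            raise ValueError(f"first-layer sizes must be (1024, 512, 256), got {first}")

    def module_specs(self, input_dim: int) -> list[ModuleSpec]:
        return [
            ModuleSpec(hidden_sizes=tuple(h), input_dim=input_dim, dropout_rate=self.dropout_rate)
            for h in self.hidden_sizes
        ]


# ---------------------------------------------------------------------------
# one MLP module


class _Module:
    def __init__(self, spec: ModuleSpec, rng: np.random.Generator):
        self.spec = spec
        sizes = spec.layer_sizes
        self.W = [
            (rng.standard_normal((a, b)) * np.sqrt(2.0 / a)).astype(_DTYPE)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(b, dtype=_DTYPE) for b in sizes[1:]]
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    # -- forward / backward

    def forward(self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Returns (softmax probabilities, cache for backward)."""
        a = X
        pre, acts, masks = [], [X], []
        n_hidden = len(self.W) - 1
        for l in range(n_hidden):
            h = a @ self.W[l] + self.b[l]
            pre.append(h)
            a = np.maximum(h, 0.0)
            if train and self.spec.dropout_rate > 0:
                mask = (rng.random(a.shape) >= self.spec.dropout_rate).astype(_DTYPE)
                a = a * mask / (1.0 - self.spec.dropout_rate)
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        z = a @ self.W[-1] + self.b[-1]
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        P = e / e.sum(axis=1, keepdims=True)
        return P, (pre, acts, masks, P)

    def backward(self, cache, dP: np.ndarray):
        """Gradients of the scalar loss given dLoss/dP."""
        pre, acts, masks, P = cache
        # softmax Jacobian-vector product
        delta = P * (dP - (dP * P).sum(axis=1, keepdims=True))
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for l in range(len(self.W) - 1, -1, -1):
            gW[l] = acts[l].T @ delta
            gb[l] = delta.sum(axis=0)
            if l > 0:
                delta = delta @ self.W[l].T
                if masks[l - 1] is not None:
                    delta = delta * masks[l - 1] / (1.0 - self.spec.dropout_rate)
                delta = delta * (pre[l - 1] > 0)
        return gW, gb

    # -- Adam

    def adam_step(self, gW, gb, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in self.W + self.b]
            self._adam_v = [np.zeros_like(p) for p in self.W + self.b]
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        grads = gW + gb
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


# ---------------------------------------------------------------------------
# the ensemble


@dataclass
class DeconvolutionEnsemble:
    """Three parallel MLPs whose averaged softmax outputs are the prediction."""

    spec: EnsembleSpec
    gene_ids: list[str]
    vocab: CellTypeVocabulary = DEFAULT_VOCABULARY
    modules: list = field(default_factory=list)
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None
    history: dict = field(default_factory=dict)
    trained: bool = False

    @classmethod
    def build(
        cls,
        spec: EnsembleSpec,
        gene_ids: list[str],
        vocab: CellTypeVocabulary = DEFAULT_VOCABULARY,
    ) -> "DeconvolutionEnsemble":
        """Seeded initialization of the three untrained modules."""
        input_dim = len(gene_ids)
        modules = [
            _Module(ms, np.random.default_rng([spec.seed, m]))
            for m, ms in enumerate(spec.module_specs(input_dim))
        ]
        return cls(spec=spec, gene_ids=list(gene_ids), vocab=vocab, modules=modules)

    # -- input handling

    def _align(self, expression: np.ndarray, gene_ids, impute_missing: bool) -> np.ndarray:
        """Reorder a genes x samples matrix to the model gene list."""
        expression = np.asarray(expression, dtype=float)
        if gene_ids is None:
            if expression.shape[0] != len(self.gene_ids):
                raise ValueError("expression rows do not match the model gene list")
            return expression
        pos = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in self.gene_ids if g not in pos]
        if missing and not impute_missing:
            raise ValueError(f"query is missing {len(missing)} model genes, e.g. {missing[:5]}")
        fill = self.input_mean if self.input_mean is not None else np.zeros(len(self.gene_ids))
        X = np.empty((len(self.gene_ids), expression.shape[1]))
        for row, g in enumerate(self.gene_ids):
            X[row] = expression[pos[g]] if g in pos else fill[row]
        return X

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.input_mean is None:
            return X.astype(_DTYPE)
        return ((X - self.input_mean[:, None]) / self.input_scale[:, None]).astype(_DTYPE)

    # -- training

    def train(
        self,
        train_set: PseudoBulkSet,
        val_set: PseudoBulkSet,
        max_epochs: int | None = None,
        verbose: bool = False,
    ) -> "DeconvolutionEnsemble":
        """Fit all three modules with Adam and early stopping.

        Validation loss is evaluated every epoch; training stops once it
        has not improved for ``spec.patience`` consecutive epochs, and the
        best-validation weights are restored.
        """
        if list(train_set.gene_ids) != list(self.gene_ids):
            missing = set(self.gene_ids) - set(train_set.gene_ids)
            raise ValueError(f"training set gene list mismatch; missing {sorted(missing)[:5]}")
        if list(val_set.gene_ids) != list(self.gene_ids):
            raise ValueError("validation set gene list mismatch")
        max_epochs = self.spec.max_epochs if max_epochs is None else max_epochs

        mu = train_set.expression.mean(axis=1)
        sd = train_set.expression.std(axis=1)
        self.input_mean = mu
        self.input_scale = np.maximum(sd, 1e-8)

        Xtr = self._standardize(train_set.expression).T  # samples x genes
        Ytr = train_set.truth.astype(_DTYPE)
        Xva = self._standardize(val_set.expression).T
        Yva = val_set.truth

        rng = np.random.default_rng([self.spec.seed, 9999])
        n = Xtr.shape[0]
        bs = self.spec.batch_size
        hist = {"train_loss": [], "val_loss": [], "val_pcc": []}
        best_loss = np.inf
        best_weights = None
        stall = 0
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                xb, yb = Xtr[idx], Ytr[idx]
                for mod in self.modules:
                    P, cache = mod.forward(xb, train=True, rng=rng)
                    loss, dP = _loss_grad(yb.astype(P.dtype), P)
                    gW, gb = mod.backward(cache, dP.astype(_DTYPE))
                    mod.adam_step(gW, gb, self.spec.learning_rate)
                    epoch_loss += loss
                n_batches += 1
            hist["train_loss"].append(epoch_loss / (n_batches * len(self.modules)))

            val_pred = self._predict_standardized(Xva)
            val_loss = composite_loss(Yva, val_pred)
            mse, pl = loss_components(Yva, val_pred)
            hist["val_loss"].append(val_loss)
            hist["val_pcc"].append(float(np.median(1.0 - pl)))
            if verbose:
                print(
                    f"epoch {epoch + 1}: train {hist['train_loss'][-1]:.4f} "
                    f"val {val_loss:.4f} val_pcc {hist['val_pcc'][-1]:.4f}"
                )
            if val_loss < best_loss:
                best_loss = val_loss
                best_weights = [m.get_weights() for m in self.modules]
                stall = 0
            else:
                stall += 1
                if stall >= self.spec.patience:
                    break
        if best_weights is not None:
            for m, w in zip(self.modules, best_weights):
                m.set_weights(w)
        self.history = hist
        self.trained = True
        return self

    # -- prediction

    def _predict_standardized(self, X: np.ndarray, chunk: int = 2048) -> np.ndarray:
        out = np.zeros((X.shape[0], len(self.vocab)))
        for start in range(0, X.shape[0], chunk):
            xb = X[start : start + chunk]
            acc = np.zeros((xb.shape[0], len(self.vocab)))
            for mod in self.modules:
                P, _ = mod.forward(xb)
                acc += P
            out[start : start + chunk] = acc / len(self.modules)
        return out

    def predict(
        self,
        expression: np.ndarray,
        gene_ids: list[str] | None = None,
        impute_missing: bool = False,
    ) -> np.ndarray:
        """Composition matrix (samples x 15): mean of the module softmax outputs."""
        X = self._align(expression, gene_ids, impute_missing)
        return self._predict_standardized(self._standardize(X).T)

    # -- persistence

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for m, mod in enumerate(self.modules):
                for l, (W, b) in enumerate(zip(mod.W, mod.b)):
                    f.create_dataset(f"module{m}/W{l}", data=W)
                    f.create_dataset(f"module{m}/b{l}", data=b)
            if self.input_mean is not None:
                f.create_dataset("input_mean", data=self.input_mean)
                f.create_dataset("input_scale", data=self.input_scale)
            f.create_dataset("genes", data=self.gene_ids, dtype=h5py.string_dtype())
            f.attrs["manifest"] = json.dumps(
                {
                    "hidden_sizes": [list(h) for h in self.spec.hidden_sizes],
                    "learning_rate": self.spec.learning_rate,
                    "batch_size": self.spec.batch_size,
                    "patience": self.spec.patience,
                    "max_epochs": self.spec.max_epochs,
                    "dropout_rate": self.spec.dropout_rate,
                    "seed": self.spec.seed,
                    "vocabulary": list(self.vocab),
                    "trained": self.trained,
                    "history": self.history,
                }
            )

    @classmethod
    def load(cls, path) -> "DeconvolutionEnsemble":
        with h5py.File(path, "r") as f:
            man = json.loads(f.attrs["manifest"])
            spec = EnsembleSpec(
                hidden_sizes=tuple(tuple(h) for h in man["hidden_sizes"]),
                learning_rate=man["learning_rate"],
                batch_size=man["batch_size"],
                patience=man["patience"],
                max_epochs=man["max_epochs"],
                dropout_rate=man["dropout_rate"],
                seed=man["seed"],
            )
            genes = [g.decode() if isinstance(g, bytes) else g for g in f["genes"][...]]
            vocab = CellTypeVocabulary(tuple(man["vocabulary"]))
            ens = cls.build(spec, genes, vocab)
            for m, mod in enumerate(ens.modules):
                mod.W = [f[f"module{m}/W{l}"][...] for l in range(len(mod.W))]
                mod.b = [f[f"module{m}/b{l}"][...] for l in range(len(mod.b))]
            if "input_mean" in f:
                ens.input_mean = f["input_mean"][...]
                ens.input_scale = f["input_scale"][...]
            ens.trained = man["trained"]
            ens.history = man["history"]
            return ens
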