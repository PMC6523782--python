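"""GloVe k-mer embeddings: co-occurrence counting and weighted least-squares
factorization of the log-count matrix.

The corpus is the set of tokenized transcripts.  For every token pair at
distance ≤ radius within one sequence (windows never cross sequence
boundaries) the count X[i][j] is incremented; with a symmetric window X is
symmetric.  Embeddings minimise

    J = Σ_{X_ij ≠ 0} f(X_ij) (w_iᵀ w̃_j + b_i + b̃_j − log X_ij)²

where f(x) = (x / x_max)^α for x < x_max, else 1 — a non-decreasing weight
that damps rare pairs and caps the influence of very frequent ones.

Optimisation is full-batch over the nonzero entries with per-parameter
AdaGrad scaling by default (plain gradient descent by option); both are
deterministic given the seed used for the small-uniform initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .kmer import KmerSequence, KmerVocabulary

__all__ = [
    "CooccurrenceMatrix",
    "GloveConfig",
    "GloveModel",
    "EmbeddingTable",
    "build_cooccurrence",
    "glove_weight",
    "glove_loss",
    "loss_and_grads",
    "train_glove",
]


@dataclass
class CooccurrenceMatrix:
    """Sparse V×V counts; entry [i-1, j-1] counts token j in the context of token i."""

    X: sp.csr_matrix
    window_diameter: int

    @property
    def vocab_size(self) -> int:
        return self.X.shape[0]

    def count(self, token_i: int, token_j: int) -> float:
        return float(self.X[token_i - 1, token_j - 1])

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def nonzero_entries(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(row, col, count) arrays over nonzero entries, 0-based rows/cols."""
        coo = self.X.tocoo()
        return coo.row.astype(np.int64), coo.col.astype(np.int64), coo.data.astype(float)


@dataclass
class GloveConfig:
    embedding_dim: int = 100
    x_max: float = 15000.0
    alpha: float = 0.75
    max_iters: int = 3000
    learning_rate: float = 0.05
    seed: int = 0
    optimizer: str = "adagrad"  # or "sgd"
    combine: str = "sum"  # final embedding w + w̃; "main" keeps w only
    init_scale: float = 0.05

    def __post_init__(self):
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be ≥ 1")
        if self.x_max <= 0:
            raise ValueError("x_max must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.optimizer not in ("adagrad", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.combine not in ("sum", "main"):
            raise ValueError(f"unknown combine {self.combine!r}")


@dataclass
class GloveModel:
    """Main vectors W, context vectors Wt and the two bias vectors."""

    W: np.ndarray  # (V, D)
    Wt: np.ndarray  # (V, D)
    b: np.ndarray  # (V,)
    bt: np.ndarray  # (V,)
    config: GloveConfig


@dataclass
class EmbeddingTable:
    """(V+1)×D lookup table; row 0 is the all-zero padding vector."""

    E: np.ndarray
    k: int | None = None

    def __post_init__(self):
        if not np.all(self.E[0] == 0):
            raise ValueError("padding row 0 must be exactly zero")
        if not np.isfinite(self.E).all():
            raise ValueError("embedding table contains non-finite values")

    @property
    def dim(self) -> int:
        return self.E.shape[1]

    @property
    def vocab_size(self) -> int:
        return self.E.shape[0] - 1

    def save_text(self, path, vocab: KmerVocabulary) -> None:
        """Plain word-vector format: k-mer string then D floats per line."""
        if vocab.size != self.vocab_size:
            raise ValueError("vocabulary size does not match table")
        with open(path, "w") as fh:
            for idx in range(1, self.vocab_size + 1):
                vec = " ".join(f"{v:.6g}" for v in self.E[idx])
                fh.write(f"{vocab.kmer_of(idx)} {vec}\n")

    @classmethod
    def load_text(cls, path, vocab: KmerVocabulary) -> "EmbeddingTable":
        rows: dict[int, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                rows[vocab.index_of(parts[0])] = np.array(parts[1:], dtype=float)
        dim = len(next(iter(rows.values())))
        E = np.zeros((vocab.size + 1, dim))
        for idx, vec in rows.items():
            E[idx] = vec
        return cls(E=E, k=vocab.k)


def build_cooccurrence(
    corpus: list[KmerSequence],
    vocab: KmerVocabulary,
    window_diameter: int = 15,
    distance_weighting: bool = False,
    symmetric: bool = True,
) -> CooccurrenceMatrix:
    """Count token co-occurrences within a window of the given diameter.

    radius = floor(diameter / 2); every ordered pair of distinct positions
    at distance ≤ radius contributes one count (or 1/d with
    ``distance_weighting``).  With ``symmetric=False`` only left context is
    counted (X[right][left] increments), giving an asymmetric matrix.
    """
    if window_diameter < 1:
        raise ValueError("window_diameter must be ≥ 1")
    if not corpus:
        raise ValueError("empty corpus")
    radius = max(1, window_diameter // 2)
    V = vocab.size
    rows, cols, vals = [], [], []
    for seq in corpus:
        t = seq.tokens - 1  # 0-based
        if (t < 0).any() or (t >= V).any():
            raise ValueError(f"corpus tokens outside vocabulary for {seq.record_id!r}")
        for d in range(1, radius + 1):
            if d >= len(t):
                break
            left, right = t[:-d], t[d:]
            w = np.full(len(left), 1.0 / d if distance_weighting else 1.0)
            rows.append(right)
            cols.append(left)
            vals.append(w)
            if symmetric:
                rows.append(left)
                cols.append(right)
                vals.append(w)
    if not rows:
        raise ValueError("no co-occurring pairs: all sequences have a single token")
    X = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(V, V)
    ).tocsr()
    return CooccurrenceMatrix(X=X, window_diameter=window_diameter)


def glove_weight(x, x_max: float = 15000.0, alpha: float = 0.75):
    """Loss weight f(x) = (x/x_max)^α for x < x_max, else 1.  Requires x > 0."""
    arr = np.asarray(x, dtype=float)
    if (arr <= 0).any():
        raise ValueError("glove_weight is defined for positive counts only")
    return np.where(arr < x_max, (arr / x_max) ** alpha, 1.0)[()]


def _check_dims(model: GloveModel, cooc: CooccurrenceMatrix) -> None:
    V = cooc.vocab_size
    if model.W.shape[0] != V or model.Wt.shape[0] != V:
        raise ValueError(f"model vocabulary {model.W.shape[0]} != matrix {V}")


def glove_loss(model: GloveModel, cooc: CooccurrenceMatrix) -> float:
    """Weighted squared error J over nonzero co-occurrence entries."""
    _check_dims(model, cooc)
    i, j, x = cooc.nonzero_entries()
    f = glove_weight(x, model.config.x_max, model.config.alpha)
    resid = (
        np.einsum("nd,nd->n", model.W[i], model.Wt[j])
        + model.b[i] + model.bt[j] - np.log(x)
    )
    return float(np.sum(f * resid**2))


def loss_and_grads(
    model: GloveModel, cooc: CooccurrenceMatrix
) -> tuple[float, dict[str, np.ndarray]]:
    """J and its analytic gradient with respect to W, Wt, b, bt."""
    _check_dims(model, cooc)
    i, j, x = cooc.nonzero_entries()
    f = glove_weight(x, model.config.x_max, model.config.alpha)
    resid = (
        np.einsum("nd,nd->n", model.W[i], model.Wt[j])
        + model.b[i] + model.bt[j] - np.log(x)
    )
    loss = float(np.sum(f * resid**2))
    g = 2.0 * f * resid  # dJ/d(resid_n) per entry
    grads = {
        "W": np.zeros_like(model.W),
        "Wt": np.zeros_like(model.Wt),
        "b": np.zeros_like(model.b),
        "bt": np.zeros_like(model.bt),
    }
    np.add.at(grads["W"], i, g[:, None] * model.Wt[j])
    np.add.at(grads["Wt"], j, g[:, None] * model.W[i])
    np.add.at(grads["b"], i, g)
    np.add.at(grads["bt"], j, g)
    return loss, grads


def init_model(V: int, config: GloveConfig) -> GloveModel:
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    return GloveModel(
        W=rng.uniform(-s, s, size=(V, config.embedding_dim)),
        Wt=rng.uniform(-s, s, size=(V, config.embedding_dim)),
        b=rng.uniform(-s, s, size=V),
        bt=rng.uniform(-s, s, size=V),
        config=config,
    )


def train_glove(
    cooc: CooccurrenceMatrix, config: GloveConfig | None = None, k: int | None = None
) -> tuple[GloveModel, EmbeddingTable, list[float]]:
    """Fit the embedding model; returns (model, table, per-iteration losses).

    One iteration is a full gradient pass over the nonzero entries.  AdaGrad
    divides each update by the root of the accumulated squared gradients,
    which copes with the heavy-tailed count distribution; plain descent is
    available via ``optimizer='sgd'``.
    """
    config = config or GloveConfig()
    model = init_model(cooc.vocab_size, config)
    lr = config.learning_rate
    accum = {name: np.full_like(getattr(model, name), 1e-8) for name in ("W", "Wt", "b", "bt")}
    losses: list[float] = []
    for it in range(config.max_iters):
        loss, grads = loss_and_grads(model, cooc)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite GloVe loss at iteration {it}")
        losses.append(loss)
        for name, grad in grads.items():
            param = getattr(model, name)
            if config.optimizer == "adagrad":
                accum[name] += grad**2
                param -= lr * grad / np.sqrt(accum[name])
            else:
                param -= lr * grad
    losses.append(glove_loss(model, cooc))
    if losses[-1] > losses[0]:
        raise FloatingPointError(
            f"GloVe training diverged: final loss {losses[-1]:.4g} > initial {losses[0]:.4g}"
        )
    vecs = model.W + model.Wt if config.combine == "sum" else model.W
    E = np.zeros((cooc.vocab_size + 1, config.embedding_dim))
    E[1:] = vecs
    return model, EmbeddingTable(E=E, k=k), losses
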