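"""The supervised classifier: embedding lookup → bidirectional LSTM →
three-stage 1-D convolution/max-pooling → logistic head.

Every sequence arrives as a fixed-length token vector (padding token 0 maps
to the all-zero embedding row).  The BLSTM runs one LSTM forward and one
over the reversed sequence, concatenating the hidden states per time step
into a 2H×L feature matrix.  The convolution stack applies valid (no-pad)
1-D cross-correlation, ReLU, and non-overlapping max-pooling three times;
the final feature map is flattened (optionally through an intermediate
dense layer) into the logistic regression that yields
p(y=1|x) = σ(βᵀc + b).  Training minimises the cross-entropy
−Σ log p(y_i|x_i) by mini-batch gradient descent with early stopping on a
validation split.

Ablation variants: ``use_blstm=False`` feeds the embedded matrix straight
into the convolution stack; ``use_conv=False`` feeds the final BLSTM state
(forward and backward last hidden states) into the head.

The LSTM transition per time step:

    i_t = σ(W_i x_t + U_i h_{t−1} + b_i)      input gate
    g_t = tanh(W_g x_t + U_g h_{t−1} + b_g)   candidate
    f_t = σ(W_f x_t + U_f h_{t−1} + b_f)      forget gate
    c_t = i_t ⊙ g_t + f_t ⊙ c_{t−1}
    o_t = σ(W_o x_t + U_o h_{t−1} + b_o)      output gate
    h_t = o_t ⊙ tanh(c_t)

All computation is double-precision NumPy with explicit backpropagation;
results are bit-reproducible given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .glove import EmbeddingTable
from .kmer import build_vocabulary, encode_records
from .sequence_io import DatasetSplit

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "LstmCellParams",
    "ClassifierModel",
    "lstm_step",
    "blstm_forward",
    "conv_stage_forward",
    "predict_proba",
    "train_classifier",
    "conv_output_lengths",
]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NetworkConfig:
    """Architecture and optimisation hyperparameters.

    Defaults follow the full model: 1000-token inputs, 100-dimensional
    embeddings, 80 hidden units per LSTM direction, conv stages of
    100/80/80 kernels with lengths 10/8/8 and pools 4/2/2, learning rate
    1e-4, batch 128, at most 12 epochs.
    """

    max_len: int = 1000
    embedding_dim: int = 100
    lstm_hidden: int = 80
    conv_filters: tuple[int, ...] = (100, 80, 80)
    conv_kernels: tuple[int, ...] = (10, 8, 8)
    pool_sizes: tuple[int, ...] = (4, 2, 2)
    use_blstm: bool = True
    use_conv: bool = True
    dense_dim: int | None = None  # None: direct flatten into the logistic layer
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 12
    optimizer: str = "sgd"  # or "adam"
    freeze_embeddings: bool = False
    val_fraction: float = 0.1
    patience: int = 2
    stride: int | None = None  # tokenization step; None → equals k
    seed: int = 0

    def __post_init__(self):
        if not len(self.conv_filters) == len(self.conv_kernels) == len(self.pool_sizes):
            raise ValueError("conv_filters, conv_kernels and pool_sizes must have equal length")
        if not (self.use_blstm or self.use_conv):
            raise ValueError("at most one of the BLSTM/conv stages may be ablated")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class LstmCellParams:
    """Per-gate weights of one LSTM cell (input, candidate, forget, output)."""

    W_i: np.ndarray
    W_g: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    U_i: np.ndarray
    U_g: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    b_i: np.ndarray
    b_g: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray

    @classmethod
    def from_packed(cls, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray) -> "LstmCellParams":
        """Unpack (D,4H)/(H,4H)/(4H,) matrices with gate order i, g, f, o."""
        H = Wh.shape[0]
        Wi, Wg, Wf, Wo = (Wx[:, i * H : (i + 1) * H].T for i in range(4))
        Ui, Ug, Uf, Uo = (Wh[:, i * H : (i + 1) * H].T for i in range(4))
        bi, bg, bf, bo = (b[i * H : (i + 1) * H] for i in range(4))
        return cls(Wi, Wg, Wf, Wo, Ui, Ug, Uf, Uo, bi, bg, bf, bo)


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LstmCellParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM transition for a single input vector; returns (h_t, c_t)."""
    p = params
    H = p.b_i.shape[0]
    if h_prev.shape[-1] != H or c_prev.shape[-1] != H:
        raise ValueError("h_prev/c_prev size does not match the cell's hidden size")
    if x_t.shape[-1] != p.W_i.shape[1]:
        raise ValueError("x_t size does not match the cell's input size")
    i_t = _sigmoid(p.W_i @ x_t + p.U_i @ h_prev + p.b_i)
    g_t = np.tanh(p.W_g @ x_t + p.U_g @ h_prev + p.b_g)
    f_t = _sigmoid(p.W_f @ x_t + p.U_f @ h_prev + p.b_f)
    c_t = i_t * g_t + f_t * c_prev
    o_t = _sigmoid(p.W_o @ x_t + p.U_o @ h_prev + p.b_o)
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# Parameter container and initialisation
# ---------------------------------------------------------------------------


@dataclass
class ClassifierModel:
    """All trainable parameters plus the architecture config.

    Parameters live in a flat name→array dict so optimisers and gradient
    checks can treat them uniformly.  Packed LSTM weights use gate order
    i, g, f, o along the last axis.
    """

    params: dict[str, np.ndarray]
    config: NetworkConfig
    vocab_hash: str | None = None

    @property
    def embedding(self) -> np.ndarray:
        return self.params["emb"]

    def lstm_cell(self, direction: str) -> LstmCellParams:
        pre = {"forward": "f", "backward": "b"}[direction]
        return LstmCellParams.from_packed(
            self.params[f"{pre}_Wx"], self.params[f"{pre}_Wh"], self.params[f"{pre}_b"]
        )

    def save(self, path) -> None:
        arrays = dict(self.params)
        arrays["_config_json"] = np.frombuffer(
            json.dumps({"config": asdict(self.config), "vocab_hash": self.vocab_hash}).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_config_json"]).decode())
            cfg = meta["config"]
            for key in ("conv_filters", "conv_kernels", "pool_sizes"):
                cfg[key] = tuple(cfg[key])
            params = {k: data[k] for k in data.files if k != "_config_json"}
        return cls(params=params, config=NetworkConfig(**cfg), vocab_hash=meta["vocab_hash"])


def conv_output_lengths(config: NetworkConfig) -> list[int]:
    """Per-stage output lengths: L_out = floor((L_in − kernel + 1) / pool)."""
    L = config.max_len  # both the BLSTM and the raw embedding preserve sequence length
    lengths = []
    for K, P in zip(config.conv_kernels, config.pool_sizes):
        if L < K:
            raise ValueError(f"feature length {L} shorter than kernel {K}")
        L = (L - K + 1) // P
        if L < 1:
            raise ValueError("pooling reduced the feature map to zero length")
        lengths.append(L)
    return lengths


def _feature_dim(config: NetworkConfig) -> int:
    """Dimension of the vector entering the dense/logistic head."""
    if not config.use_conv:
        return 2 * config.lstm_hidden
    return config.conv_filters[-1] * conv_output_lengths(config)[-1]


def init_model(
    config: NetworkConfig, embeddings: EmbeddingTable, vocab_hash: str | None = None
) -> ClassifierModel:
    """Glorot-uniform initialisation; embedding rows copied from GloVe."""
    if embeddings.dim != config.embedding_dim:
        raise ValueError(
            f"embedding table dim {embeddings.dim} != config.embedding_dim {config.embedding_dim}"
        )
    rng = np.random.default_rng(config.seed)

    def glorot(shape, fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=shape)

    D, H = config.embedding_dim, config.lstm_hidden
    params: dict[str, np.ndarray] = {"emb": embeddings.E.copy()}
    if config.use_blstm:
        for pre in ("f", "b"):
            params[f"{pre}_Wx"] = glorot((D, 4 * H), D, H)
            params[f"{pre}_Wh"] = glorot((H, 4 * H), H, H)
            params[f"{pre}_b"] = np.zeros(4 * H)
    if config.use_conv:
        C_in = 2 * H if config.use_blstm else D
        for s, (C_out, K) in enumerate(zip(config.conv_filters, config.conv_kernels)):
            params[f"conv{s}_K"] = glorot((C_out, C_in, K), C_in * K, C_out)
            params[f"conv{s}_b"] = np.zeros(C_out)
            C_in = C_out
    d = _feature_dim(config)
    if config.dense_dim is not None:
        params["dense_W"] = glorot((d, config.dense_dim), d, config.dense_dim)
        params["dense_b"] = np.zeros(config.dense_dim)
        d = config.dense_dim
    params["out_w"] = glorot((d,), d, 1)
    params["out_b"] = np.zeros(1)
    return ClassifierModel(params=params, config=config, vocab_hash=vocab_hash)


# ---------------------------------------------------------------------------
# Forward/backward building blocks (batched)
# ---------------------------------------------------------------------------


def _lstm_forward_batch(X: np.ndarray, Wx, Wh, b) -> tuple[np.ndarray, dict]:
    """Run one direction over X (B,T,D); returns H_all (B,T,H) and caches."""
    B, T, D = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((T, B, H))
    cache = {"i": np.empty((T, B, H)), "g": np.empty((T, B, H)),
             "f": np.empty((T, B, H)), "o": np.empty((T, B, H)),
             "c": np.empty((T, B, H)), "c_prev": np.empty((T, B, H)),
             "h_prev": np.empty((T, B, H))}
    XW = X @ Wx  # (B,T,4H) — input contribution precomputed
    for t in range(T):
        z = XW[:, t] + h @ Wh + b
        i = _sigmoid(z[:, :H])
        g = np.tanh(z[:, H : 2 * H])
        f = _sigmoid(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        cache["h_prev"][t] = h
        cache["c_prev"][t] = c
        c = i * g + f * c
        h = o * np.tanh(c)
        cache["i"][t], cache["g"][t], cache["f"][t], cache["o"][t] = i, g, f, o
        cache["c"][t] = c
        Hs[t] = h
    return Hs.transpose(1, 0, 2), cache


def _lstm_backward_batch(dH: np.ndarray, X: np.ndarray, Wx, Wh, cache):
    """BPTT for one direction.  dH: (B,T,H) gradient w.r.t. every h_t."""
    B, T, D = X.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, g, f, o = cache["i"][t], cache["g"][t], cache["f"][t], cache["o"][t]
        c, c_prev, h_prev = cache["c"][t], cache["c_prev"][t], cache["h_prev"][t]
        tanh_c = np.tanh(c)
        dh = dH[:, t] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1 - tanh_c**2) + dc_next
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), dg * (1 - g**2), df * f * (1 - f), do * o * (1 - o)], axis=1
        )  # (B, 4H)
        dWx += X[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
    return dX, dWx, dWh, db


def _conv_forward_batch(X: np.ndarray, K: np.ndarray, b: np.ndarray, pool: int):
    """X (B,C_in,L) → pooled (B,C_out,L_p) with caches for backprop."""
    B, C_in, L = X.shape
    C_out, _, Kw = K.shape
    if L < Kw:
        raise ValueError(f"input length {L} shorter than kernel {Kw}")
    L_c = L - Kw + 1
    idx = np.arange(L_c)[:, None] + np.arange(Kw)[None, :]
    Xw = X[:, :, idx]  # (B, C_in, L_c, Kw)
    Xcol = Xw.transpose(0, 2, 1, 3).reshape(B, L_c, C_in * Kw)
    Wmat = K.reshape(C_out, C_in * Kw).T  # (C_in*Kw, C_out)
    pre = Xcol @ Wmat + b  # (B, L_c, C_out)
    act = np.maximum(pre, 0.0)
    L_p = L_c // pool
    if L_p < 1:
        raise ValueError("pooling window longer than the convolved feature map")
    blocks = act[:, : L_p * pool].reshape(B, L_p, pool, C_out)
    argmax = blocks.argmax(axis=2)  # (B, L_p, C_out)
    pooled = np.take_along_axis(blocks, argmax[:, :, None, :], axis=2)[:, :, 0, :]
    out = pooled.transpose(0, 2, 1)  # (B, C_out, L_p)
    cache = {"Xcol": Xcol, "pre": pre, "argmax": argmax, "shape": (B, C_in, L, L_c, Kw, pool)}
    return out, cache


def _conv_backward_batch(dout: np.ndarray, K: np.ndarray, cache):
    B, C_in, L, L_c, Kw, pool = cache["shape"]
    C_out = K.shape[0]
    L_p = dout.shape[2]
    dpooled = dout.transpose(0, 2, 1)  # (B, L_p, C_out)
    dblocks = np.zeros((B, L_p, pool, C_out))
    np.put_along_axis(dblocks, cache["argmax"][:, :, None, :], dpooled[:, :, None, :], axis=2)
    dact = np.zeros_like(cache["pre"])  # (B, L_c, C_out)
    dact[:, : L_p * pool] = dblocks.reshape(B, L_p * pool, C_out)
    dpre = dact * (cache["pre"] > 0)
    db = dpre.sum(axis=(0, 1))
    Wmat = K.reshape(C_out, C_in * Kw).T
    dWmat = np.einsum("blk,blc->kc", cache["Xcol"], dpre)  # (C_in*Kw, C_out)
    dK = dWmat.T.reshape(C_out, C_in, Kw)
    dXcol = dpre @ Wmat.T  # (B, L_c, C_in*Kw)
    dXw = dXcol.reshape(B, L_c, C_in, Kw).transpose(0, 2, 1, 3)  # (B, C_in, L_c, Kw)
    dX = np.zeros((B, C_in, L))
    for kk in range(Kw):  # kernels are short; a python loop over taps is cheap
        dX[:, :, kk : kk + L_c] += dXw[:, :, :, kk]
    return dX, dK, db


def conv_stage_forward(
    features: np.ndarray, kernel: np.ndarray, bias: np.ndarray, pool: int
) -> np.ndarray:
    """One conv→ReLU→max-pool stage on a single C_in×L_in feature matrix.

    Valid cross-correlation over the time axis summing input channels, plus
    bias, ReLU, then non-overlapping max-pooling (trailing remainder
    dropped); output is C_out × floor((L_in − kernel + 1)/pool).
    """
    out, _ = _conv_forward_batch(features[None], kernel, bias, pool)
    return out[0]


# ---------------------------------------------------------------------------
# Full forward / backward
# ---------------------------------------------------------------------------


def _forward(model: ClassifierModel, tokens: np.ndarray, want_cache: bool = False):
    cfg = model.config
    P = model.params
    tokens = np.atleast_2d(tokens)
    X = P["emb"][tokens]  # (B,T,D)
    cache: dict = {"tokens": tokens, "X": X}
    if cfg.use_blstm:
        Hf, cf = _lstm_forward_batch(X, P["f_Wx"], P["f_Wh"], P["f_b"])
        Hb_rev, cb = _lstm_forward_batch(X[:, ::-1], P["b_Wx"], P["b_Wh"], P["b_b"])
        Hb = Hb_rev[:, ::-1]  # realign backward states to forward time
        feats = np.concatenate([Hf, Hb], axis=2)  # (B,T,2H)
        cache.update(lstm_f=cf, lstm_b=cb, Hf=Hf, Hb_rev=Hb_rev)
        if cfg.use_conv:
            cur = feats.transpose(0, 2, 1)  # (B, 2H, T)
        else:
            flat = np.concatenate([Hf[:, -1], Hb_rev[:, -1]], axis=1)  # final states
    else:
        cur = X.transpose(0, 2, 1)  # (B, D, T)
    if cfg.use_conv:
        conv_caches = []
        for s in range(len(cfg.conv_filters)):
            cur, cc = _conv_forward_batch(cur, P[f"conv{s}_K"], P[f"conv{s}_b"], cfg.pool_sizes[s])
            conv_caches.append(cc)
        cache["conv"] = conv_caches
        flat = cur.reshape(cur.shape[0], -1)
        cache["last_map_shape"] = cur.shape
    cache["flat"] = flat
    if cfg.dense_dim is not None:
        dpre = flat @ P["dense_W"] + P["dense_b"]
        dact = np.maximum(dpre, 0.0)
        cache.update(dense_pre=dpre, dense_act=dact)
        head_in = dact
    else:
        head_in = flat
    cache["head_in"] = head_in
    z = head_in @ P["out_w"] + P["out_b"][0]
    p = _sigmoid(z)
    if not np.isfinite(p).all():
        raise FloatingPointError("non-finite activation in the forward pass")
    return (p, cache) if want_cache else p


def predict_proba(tokens: np.ndarray, model: ClassifierModel) -> np.ndarray:
    """p(y=1|x) for one token vector or a batch; classification is p ≥ 0.5."""
    single = np.asarray(tokens).ndim == 1
    p = _forward(model, tokens)
    return p[0] if single else p


def blstm_forward(tokens: np.ndarray, model: ClassifierModel) -> np.ndarray:
    """Per-time-step BLSTM features for one sequence, as a (2H)×L matrix.

    Rows 1..H are the forward hidden states; rows H+1..2H the backward
    states re-aligned to forward time.
    """
    if not model.config.use_blstm:
        raise ValueError("model was built without a BLSTM stage")
    P = model.params
    X = P["emb"][np.atleast_2d(tokens)]
    Hf, _ = _lstm_forward_batch(X, P["f_Wx"], P["f_Wh"], P["f_b"])
    Hb_rev, _ = _lstm_forward_batch(X[:, ::-1], P["b_Wx"], P["b_Wh"], P["b_b"])
    return np.concatenate([Hf[0], Hb_rev[0, ::-1]], axis=1).T


def loss_and_grads(
    model: ClassifierModel, tokens: np.ndarray, labels: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy over the batch and its gradient for every parameter."""
    cfg = model.config
    P = model.params
    y = np.asarray(labels, dtype=float)
    p, cache = _forward(model, tokens, want_cache=True)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    B = len(y)
    grads = {k: np.zeros_like(v) for k, v in P.items()}
    dz = (p - y) / B  # (B,)
    head_in = cache["head_in"]
    grads["out_w"] = head_in.T @ dz
    grads["out_b"] = np.array([dz.sum()])
    dhead = np.outer(dz, P["out_w"])
    if cfg.dense_dim is not None:
        dpre = dhead * (cache["dense_pre"] > 0)
        grads["dense_W"] = cache["flat"].T @ dpre
        grads["dense_b"] = dpre.sum(axis=0)
        dflat = dpre @ P["dense_W"].T
    else:
        dflat = dhead
    if cfg.use_conv:
        dcur = dflat.reshape(cache["last_map_shape"])
        for s in range(len(cfg.conv_filters) - 1, -1, -1):
            dcur, dK, db = _conv_backward_batch(dcur, P[f"conv{s}_K"], cache["conv"][s])
            grads[f"conv{s}_K"] = dK
            grads[f"conv{s}_b"] = db
        if cfg.use_blstm:
            dfeats = dcur.transpose(0, 2, 1)  # (B,T,2H)
            H = cfg.lstm_hidden
            dHf, dHb = dfeats[:, :, :H], dfeats[:, :, H:]
        else:
            dX_direct = dcur.transpose(0, 2, 1)  # (B,T,D)
    else:
        # head consumed the final states only
        H = cfg.lstm_hidden
        T = cache["X"].shape[1]
        dHf = np.zeros((B, T, H))
        dHb = np.zeros((B, T, H))
        dHf[:, -1] = dflat[:, :H]
        dHb[:, 0] = dflat[:, H:]  # backward's last step is forward time 0
    if cfg.use_blstm:
        X = cache["X"]
        dHb_rev = dHb[:, ::-1]  # back to the backward LSTM's own time order
        dX_f, dWx_f, dWh_f, db_f = _lstm_backward_batch(
            dHf, X, P["f_Wx"], P["f_Wh"], cache["lstm_f"]
        )
        dX_b_rev, dWx_b, dWh_b, db_b = _lstm_backward_batch(
            dHb_rev, X[:, ::-1], P["b_Wx"], P["b_Wh"], cache["lstm_b"]
        )
        grads["f_Wx"], grads["f_Wh"], grads["f_b"] = dWx_f, dWh_f, db_f
        grads["b_Wx"], grads["b_Wh"], grads["b_b"] = dWx_b, dWh_b, db_b
        dX = dX_f + dX_b_rev[:, ::-1]
    else:
        dX = dX_direct
    if not cfg.freeze_embeddings:
        np.add.at(grads["emb"], cache["tokens"], dX)
        grads["emb"][0] = 0.0  # padding row stays zero
    return loss, grads


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def _stratified_val_split(y: np.ndarray, val_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    val_idx = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, round(len(idx) * val_fraction)) if val_fraction > 0 else 0
        val_idx.extend(idx[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def fit(
    model: ClassifierModel,
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig | None = None,
) -> list[dict]:
    """Mini-batch training with early stopping; mutates ``model`` in place.

    Returns the per-epoch log (train/validation loss and accuracy).  The
    best-validation-loss parameters are restored at the end.
    """
    cfg = config or model.config
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed + 1)
    train_idx, val_idx = _stratified_val_split(y, cfg.val_fraction, rng)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xva, yva = X[val_idx], y[val_idx]

    state = {k: {"m": np.zeros_like(v), "v": np.zeros_like(v)} for k, v in model.params.items()}
    best_val = np.inf
    best_params = None
    bad_epochs = 0
    tstep = 0
    log: list[dict] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        epoch_loss = 0.0
        n_correct = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = loss_and_grads(model, Xtr[idx], ytr[idx])
            epoch_loss += loss * len(idx)
            tstep += 1
            for name, g in grads.items():
                if cfg.freeze_embeddings and name == "emb":
                    continue
                param = model.params[name]
                if cfg.optimizer == "adam":
                    st = state[name]
                    st["m"] = 0.9 * st["m"] + 0.1 * g
                    st["v"] = 0.999 * st["v"] + 0.001 * g**2
                    mhat = st["m"] / (1 - 0.9**tstep)
                    vhat = st["v"] / (1 - 0.999**tstep)
                    param -= cfg.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
                else:
                    param -= cfg.learning_rate * g
                if name == "emb":
                    param[0] = 0.0
        p_tr = _forward(model, Xtr)
        n_correct = int(((p_tr >= 0.5).astype(int) == ytr).sum())
        entry = {
            "epoch": epoch,
            "train_loss": epoch_loss / len(ytr),
            "train_acc": n_correct / len(ytr),
        }
        if len(yva):
            p_va = _forward(model, Xva)
            eps = 1e-12
            val_loss = float(
                -np.mean(yva * np.log(p_va + eps) + (1 - yva) * np.log(1 - p_va + eps))
            )
            entry["val_loss"] = val_loss
            entry["val_acc"] = float(((p_va >= 0.5).astype(int) == yva).mean())
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
        log.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
        if len(yva) and bad_epochs > cfg.patience:
            logger.info("early stop at epoch %d (patience %d)", epoch, cfg.patience)
            break
    if best_params is not None:
        model.params = best_params
    return log


def train_classifier(
    split: DatasetSplit,
    embeddings: EmbeddingTable,
    config: NetworkConfig,
) -> tuple[ClassifierModel, list[dict]]:
    """Encode the split's training records and fit the classifier.

    The k-mer size is taken from the embedding table; stride defaults to k
    (non-overlapping windows).  Returns the fitted model and training log.
    """
    if not split.train:
        raise ValueError("empty training split")
    k = embeddings.k
    if k is None:
        k = round(np.log(embeddings.vocab_size) / np.log(4))
    vocab = build_vocabulary(k)
    if vocab.size != embeddings.vocab_size:
        raise ValueError("embedding table size is not 4^k for any supported k")
    stride = config.stride or k
    X, y, _ = encode_records(split.train, vocab, stride=stride, max_len=config.max_len)
    vocab_hash = hashlib.sha256(f"k={k};V={vocab.size}".encode()).hexdigest()[:16]
    model = init_model(config, embeddings, vocab_hash=vocab_hash)
    log = fit(model, X, y, config)
    return model, log
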