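"""End-to-end experiment driver: clean → split → embed → train → evaluate.

This is the programmatic counterpart of the command-line chain and the
single code path used by the CLI, the sensitivity sweep and the example
scripts, so that every entry point measures the same pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import glove, kmer, metrics, network, sequence_io

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Hyperparameters for one full train/evaluate cycle.

    Defaults are the full-scale settings: k = s = 6, co-occurrence window
    diameter 15, 100-dimensional embeddings with x_max 15000 and α = 0.75,
    3000 GloVe iterations, 1000-token inputs, 80 hidden LSTM units per
    direction, conv stages 100/80/80 × (10,8,8) pooled by (4,2,2),
    learning rate 1e-4, batch 128, ≤ 12 epochs.  Desk-scale runs override
    the size-bearing fields.
    """

    k: int = 6
    stride: int = 6
    window_diameter: int = 15
    train_frac: float = 0.7
    balance: bool = True
    glove: glove.GloveConfig = field(default_factory=glove.GloveConfig)
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    seed: int = 0

    def __post_init__(self):
        # one master seed drives every stochastic stage
        self.glove = dataclasses.replace(self.glove, seed=self.seed)
        self.network = dataclasses.replace(self.network, seed=self.seed, stride=self.stride)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentResult:
    metrics: dict[str, float]
    model: network.ClassifierModel
    embeddings: glove.EmbeddingTable
    split: sequence_io.DatasetSplit
    training_log: list[dict]
    glove_losses: list[float]
    test_scores: np.ndarray
    test_labels: np.ndarray


def build_embeddings(
    records: list[sequence_io.SequenceRecord], cfg: ExperimentConfig
) -> tuple[glove.EmbeddingTable, list[float]]:
    """Unsupervised stage: tokenize the whole corpus, count co-occurrences
    within the window, and fit GloVe vectors."""
    vocab = kmer.build_vocabulary(cfg.k)
    corpus = kmer.tokenize_records(records, vocab, stride=cfg.stride)
    cooc = glove.build_cooccurrence(corpus, vocab, window_diameter=cfg.window_diameter)
    _, table, losses = glove.train_glove(cooc, cfg.glove, k=cfg.k)
    return table, losses


def run_experiment(
    records: list[sequence_io.SequenceRecord],
    cfg: ExperimentConfig | None = None,
    clean: bool = True,
) -> ExperimentResult:
    """Full cycle on labelled records; returns held-out metrics and artefacts.

    The embedding stage is unsupervised and uses the whole corpus (labels
    never enter it); the classifier is fitted on the training partition and
    scored on the held-out test partition.
    """
    cfg = cfg or ExperimentConfig()
    if clean:
        records = sequence_io.clean_records(records)
    split = sequence_io.balanced_split(
        records, train_frac=cfg.train_frac, balance=cfg.balance, seed=cfg.seed
    )
    table, glove_losses = build_embeddings(split.train + split.test, cfg)
    model, log = network.train_classifier(split, table, cfg.network)
    vocab = kmer.build_vocabulary(cfg.k)
    X_test, y_test, _ = kmer.encode_records(
        split.test, vocab, stride=cfg.stride, max_len=cfg.network.max_len
    )
    scores = network.predict_proba(X_test, model)
    report = metrics.evaluate(y_test, scores)
    return ExperimentResult(
        metrics=report,
        model=model,
        embeddings=table,
        split=split,
        training_log=log,
        glove_losses=glove_losses,
        test_scores=scores,
        test_labels=y_test,
    )


def desk_scale_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """A reduced configuration sized for laptop-class corpora.

    Keeps the architecture shape (BLSTM → three conv/pool stages →
    logistic) but scales every size-bearing knob with the corpus: k = s = 4
    (a 256-token vocabulary whose co-occurrence counts are well populated
    by a few-hundred-sequence corpus, where V = 4096 would leave almost
    every count at 1), x_max matched to the resulting count scale, smaller
    embedding/hidden/filter sizes, shorter inputs, and Adam so the short
    schedule converges.  See docs/methods.md for the rationale.
    """
    net = dict(
        max_len=128,
        embedding_dim=32,
        lstm_hidden=24,
        conv_filters=(24, 16, 16),
        conv_kernels=(10, 8, 8),
        pool_sizes=(4, 2, 2),
        learning_rate=5e-4,
        batch_size=64,
        max_epochs=30,
        optimizer="adam",
        patience=6,
    )
    glove_cfg = dict(embedding_dim=32, max_iters=200, x_max=50.0)
    net.update({k: v for k, v in overrides.items() if k in network.NetworkConfig.__dataclass_fields__})
    glove_cfg["embedding_dim"] = net["embedding_dim"]  # the two stages must agree
    glove_cfg.update(
        {k[6:]: v for k, v in overrides.items() if k.startswith("glove_")}
    )
    top = {
        "k": 4,
        "stride": 4,
    }
    top.update(
        {
            k: v
            for k, v in overrides.items()
            if k in ("k", "stride", "window_diameter", "train_frac", "balance")
        }
    )
    cfg = ExperimentConfig(
        glove=glove.GloveConfig(**glove_cfg),
        network=network.NetworkConfig(**net),
        seed=seed,
        **top,
    )
    return cfg
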