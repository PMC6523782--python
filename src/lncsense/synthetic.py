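"""Synthetic transcript generator with a controllable class signal.

The generator emulates the compositional contrast between mRNAs and
lncRNAs that a sequence-only classifier can learn.  Class 0 ("lncRNA")
sequences are i.i.d. nucleotides from a background composition.  Class 1
("mRNA") sequences share the background but carry one planted open reading
frame: an ATG start codon, in-frame codons drawn from a biased codon table
with no internal stops, and a stop codon.  Codon bias strength is scaled by
``separation`` ∈ [0, 1]; at 0 the planting is disabled entirely, so the two
class-conditional distributions coincide exactly and any classifier is at
chance.  The bias itself is a third-position G/C preference, the classical
signature of codon usage in highly expressed coding sequence.

Lengths are log-normal (median/spread configurable), truncated to
[200, max_nt], identical for both classes by default so sequence length
carries no class information.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import LNCRNA, MRNA, SequenceRecord, write_fasta

BASES = "ACTG"
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

__all__ = ["SyntheticConfig", "simulate_dataset", "kmer_frequency_divergence"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a well-separated desk-scale dataset."""

    n_per_class: int = 500
    length_median: float = 600.0  # nt; log-normal median, shared by both classes
    length_sigma: float = 0.45  # log-scale spread
    min_nt: int = 200
    max_nt: int = 10000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A,C,T,G
    orf_fraction: float = 0.5  # fraction of a class-1 sequence covered by the ORF
    separation: float = 1.0  # 0 = identical classes, 1 = full codon bias
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be ≥ 1")
        if not 0 <= self.separation <= 1:
            raise ValueError("separation must lie in [0, 1]")
        if not 0 < self.orf_fraction <= 1:
            raise ValueError("orf_fraction must lie in (0, 1]")
        if self.min_nt < 6 or self.max_nt < self.min_nt:
            raise ValueError(f"infeasible length bounds [{self.min_nt}, {self.max_nt}]")
        if self.length_median < self.min_nt or self.length_median > self.max_nt:
            raise ValueError("length_median outside the truncation bounds")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be a probability vector over A,C,T,G")


def _codon_tables(background: np.ndarray, separation: float):
    """(codons, probabilities) for internal ORF codons, stop codons excluded.

    The biased table prefers G/C at the third codon position; the actual
    table is the ``separation``-weighted mixture of background and bias.
    """
    third_pos_bias = {"A": 0.08, "C": 0.42, "T": 0.08, "G": 0.42}
    codons = ["".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOP_CODONS]
    base_p = {b: background[i] for i, b in enumerate(BASES)}
    bg = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
    biased = np.array([base_p[c[0]] * base_p[c[1]] * third_pos_bias[c[2]] for c in codons])
    mix = (1.0 - separation) * bg / bg.sum() + separation * biased / biased.sum()
    return codons, mix / mix.sum()


def _sample_length(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    mu = np.log(cfg.length_median)
    for _ in range(1000):  # rejection keeps the shape of the truncated law
        n = int(round(np.exp(rng.normal(mu, cfg.length_sigma))))
        if cfg.min_nt <= n <= cfg.max_nt:
            return n
    raise ValueError("length bounds reject virtually all draws; widen them")


def _background_seq(n: int, background: np.ndarray, rng) -> str:
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=background)])


def _plant_orf(seq: str, cfg: SyntheticConfig, codons, codon_p, rng) -> str:
    n = len(seq)
    orf_len = int(cfg.orf_fraction * n) // 3 * 3
    orf_len = max(9, min(orf_len, n // 3 * 3))  # at least start + 1 codon + stop
    n_internal = orf_len // 3 - 2
    internal = "".join(rng.choice(codons, size=n_internal, p=codon_p)) if n_internal else ""
    orf = START_CODON + internal + STOP_CODONS[rng.integers(len(STOP_CODONS))]
    start = int(rng.integers(0, n - len(orf) + 1))
    return seq[:start] + orf + seq[start + len(orf):]


def simulate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> list[SequenceRecord]:
    """Generate ``2 * n_per_class`` labelled records, optionally writing
    FASTA + label TSV + a JSON sidecar of all generator parameters.

    Deterministic given ``config.seed``; lncRNA-like records first.
    """
    rng = np.random.default_rng(config.seed)
    background = np.asarray(config.background, dtype=float)
    codons, codon_p = _codon_tables(background, config.separation)
    records: list[SequenceRecord] = []
    for label, tag in ((LNCRNA, "lnc"), (MRNA, "mrna")):
        for i in range(config.n_per_class):
            n = _sample_length(config, rng)
            seq = _background_seq(n, background, rng)
            if label == MRNA and config.separation > 0:
                seq = _plant_orf(seq, config, codons, codon_p, rng)
            records.append(SequenceRecord(id=f"{tag}_{i:05d}", bases=seq, label=label))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta([r for r in records if r.label == MRNA], out_dir / "mrna.fa")
        write_fasta([r for r in records if r.label == LNCRNA], out_dir / "lncrna.fa")
        with open(out_dir / "labels.tsv", "w") as fh:
            for r in records:
                fh.write(f"{r.id}\t{r.label}\n")
        with open(out_dir / "generator.json", "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2)
            fh.write("\n")
    return records


def kmer_frequency_divergence(records: list[SequenceRecord], k: int = 6) -> float:
    """Total-variation distance between the class-averaged k-mer frequency
    vectors — a model-free measure of how separable the two classes are."""
    from .kmer import build_vocabulary, tokenize

    vocab = build_vocabulary(k)
    freqs = {}
    for label in (LNCRNA, MRNA):
        counts = np.zeros(vocab.size)
        for rec in records:
            if rec.label != label:
                continue
            tokens = tokenize(rec, vocab, stride=1).tokens
            counts += np.bincount(tokens - 1, minlength=vocab.size)
        if counts.sum() == 0:
            raise ValueError(f"no records with label {label}")
        freqs[label] = counts / counts.sum()
    return 0.5 * float(np.abs(freqs[MRNA] - freqs[LNCRNA]).sum())
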