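"""k-mer vocabulary, sliding-window tokenization and fixed-length encoding.

Transcript sequences are decomposed into overlapping or non-overlapping
k-mers with a sliding window of width ``k`` and step ``s``.  Each of the
4**k possible k-mers receives an integer index in ``[1, 4**k]``; index 0 is
reserved for the padding token, whose embedding row is identically zero.

The alphabet digit order is A, C, T, G (A=0, C=1, T=2, G=3), so for k=2 the
first indices are AA→1, AC→2, AT→3, AG→4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import SequenceRecord

ALPHABET = "ACTG"
_BASE_DIGIT = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "KmerVocabulary",
    "KmerSequence",
    "build_vocabulary",
    "tokenize",
    "tokenize_records",
    "pad_truncate",
    "encode_records",
    "write_corpus",
    "read_corpus",
]


@dataclass(frozen=True)
class KmerVocabulary:
    """Bijection between the 4**k k-mer strings and indices 1..4**k."""

    k: int

    @property
    def size(self) -> int:
        return 4**self.k

    def index_of(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        idx = 0
        for base in kmer:
            try:
                idx = idx * 4 + _BASE_DIGIT[base]
            except KeyError:
                raise ValueError(f"non-ACTG base in k-mer {kmer!r}") from None
        return idx + 1

    def kmer_of(self, index: int) -> str:
        if not 1 <= index <= self.size:
            raise ValueError(f"index {index} outside [1, {self.size}]")
        value = index - 1
        bases = []
        for _ in range(self.k):
            bases.append(ALPHABET[value % 4])
            value //= 4
        return "".join(reversed(bases))

    def all_kmers(self) -> list[str]:
        """All 4**k k-mers in index order (index i ↔ position i-1)."""
        return [self.kmer_of(i) for i in range(1, self.size + 1)]


@dataclass
class KmerSequence:
    """Integer token sequence produced from one transcript."""

    record_id: str
    tokens: np.ndarray  # 1-D int64, values in [1, 4**k]
    k: int
    stride: int
    label: int | None = None

    def __len__(self) -> int:
        return len(self.tokens)


def build_vocabulary(k: int) -> KmerVocabulary:
    """Create the k-mer dictionary for word size ``k`` (1 ≤ k ≤ 10)."""
    if not 1 <= k <= 10:
        raise ValueError(f"k must be in [1, 10], got {k}")
    return KmerVocabulary(k=k)


def _digits(bases: str) -> np.ndarray:
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    digits = np.full(arr.shape, -1, dtype=np.int64)
    for base, d in _BASE_DIGIT.items():
        digits[arr == ord(base)] = d
    if (digits < 0).any():
        bad = bases[int(np.argmax(digits < 0))]
        raise ValueError(f"non-ACTG character {bad!r} in sequence")
    return digits


def tokenize(record: SequenceRecord, vocab: KmerVocabulary, stride: int = None) -> KmerSequence:
    """Slide a window of width k and step s over the sequence.

    Token i is the index of ``bases[i*s : i*s + k]``; a trailing fragment
    shorter than k is discarded, so L = floor((n - k)/s) + 1.
    """
    k = vocab.k
    s = k if stride is None else stride
    if s < 1:
        raise ValueError(f"stride must be ≥ 1, got {s}")
    n = len(record.bases)
    if n < k:
        raise ValueError(f"sequence {record.id!r} shorter than k={k} ({n} nt): no token can be formed")
    digits = _digits(record.bases)
    length = (n - k) // s + 1
    # base-4 positional weights, most significant first
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    starts = np.arange(length, dtype=np.int64) * s
    windows = digits[starts[:, None] + np.arange(k)]
    tokens = windows @ weights + 1
    return KmerSequence(record_id=record.id, tokens=tokens, k=k, stride=s, label=record.label)


def tokenize_records(
    records: list[SequenceRecord], vocab: KmerVocabulary, stride: int = None
) -> list[KmerSequence]:
    return [tokenize(r, vocab, stride=stride) for r in records]


def pad_truncate(seq: KmerSequence | np.ndarray, max_len: int = 1000) -> np.ndarray:
    """Right-pad with token 0 or keep the first ``max_len`` tokens.

    Short token sequences are zero-filled on the right; long ones keep
    their 5' prefix.  Output length is exactly ``max_len``.
    """
    if max_len < 1:
        raise ValueError(f"max_len must be ≥ 1, got {max_len}")
    tokens = seq.tokens if isinstance(seq, KmerSequence) else np.asarray(seq, dtype=np.int64)
    out = np.zeros(max_len, dtype=np.int64)
    n = min(len(tokens), max_len)
    out[:n] = tokens[:n]
    return out


def encode_records(
    records: list[SequenceRecord],
    vocab: KmerVocabulary,
    stride: int = None,
    max_len: int = 1000,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Tokenize + pad a labelled record list into (tokens, labels, ids) arrays."""
    seqs = tokenize_records(records, vocab, stride=stride)
    X = np.stack([pad_truncate(s, max_len) for s in seqs])
    y = np.array([-1 if s.label is None else s.label for s in seqs], dtype=np.int64)
    return X, y, [s.record_id for s in seqs]


def write_corpus(seqs: list[KmerSequence], path) -> None:
    """Serialize a tokenized corpus: one line per sequence, id then tokens."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(s.record_id + "\t" + " ".join(map(str, s.tokens.tolist())) + "\n")


def read_corpus(path, k: int, stride: int) -> list[KmerSequence]:
    seqs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rid, _, rest = line.partition("\t")
            tokens = np.array([int(t) for t in rest.split()], dtype=np.int64)
            seqs.append(KmerSequence(record_id=rid, tokens=tokens, k=k, stride=stride))
    return seqs
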