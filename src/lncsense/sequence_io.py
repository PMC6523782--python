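"""FASTA input, sequence cleaning, and balanced train/test splitting.

Transcripts enter as FASTA (DNA or RNA alphabet; U is mapped to T and case
is normalised).  Cleaning drops any record shorter than a minimum length
(200 nt by default — the conventional lncRNA length floor) and any record
containing a character outside {A, C, T, G}; ambiguity codes are not
interpreted.  Splitting is stratified by label, with optional random
downsampling of the majority class to exact 1:1 balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

LNCRNA, MRNA = 0, 1  # label convention: 0 = lncRNA, 1 = mRNA (positive class)

__all__ = [
    "SequenceRecord",
    "DatasetSplit",
    "read_fasta",
    "read_labelled_fasta",
    "read_labels_tsv",
    "write_fasta",
    "clean_records",
    "balanced_split",
    "kfold_indices",
]


@dataclass
class SequenceRecord:
    """One transcript: identifier, nucleotide string and optional label."""

    id: str
    bases: str
    label: int | None = None

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class DatasetSplit:
    """Non-overlapping train/test partition of labelled records."""

    train: list[SequenceRecord]
    test: list[SequenceRecord]
    seed: int = 0

    def __post_init__(self):
        train_ids = {r.id for r in self.train}
        overlap = train_ids.intersection(r.id for r in self.test)
        if overlap:
            raise ValueError(f"train/test overlap on ids: {sorted(overlap)[:5]}")


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path, label: int | None = None) -> list[SequenceRecord]:
    """Parse a FASTA file into records (uppercased, U→T).

    ``label`` is attached to every record when given. An empty file is an
    error — silently returning nothing hides truncated downloads.
    """
    records = [
        SequenceRecord(id=rec.id, bases=_normalise(str(rec.seq)), label=label)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_labelled_fasta(pos_path, neg_path) -> list[SequenceRecord]:
    """Two-file label convention: pos = mRNA (1), neg = lncRNA (0)."""
    return read_fasta(pos_path, label=MRNA) + read_fasta(neg_path, label=LNCRNA)


def read_labels_tsv(path) -> dict[str, int]:
    """Two-column ``id<TAB>label`` file mapping record ids to {0,1}."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}:{ln}: expected 'id<TAB>0|1', got {line!r}")
            labels[parts[0]] = int(parts[1])
    return labels


def write_fasta(records: list[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def clean_records(
    records: list[SequenceRecord],
    min_len: int = 200,
    strip_ambiguous: bool = False,
) -> list[SequenceRecord]:
    """Drop records shorter than ``min_len`` or containing non-ACTG characters.

    With ``strip_ambiguous`` the offending characters are removed instead of
    the whole record (the length filter then applies to the stripped
    sequence).  Stripping joins previously non-adjacent bases into spurious
    k-mers, so dropping is the default.  Idempotent; order preserving.
    """
    kept: list[SequenceRecord] = []
    n_short = n_dirty = 0
    valid = set("ACTG")
    for rec in records:
        bases = rec.bases
        if not set(bases) <= valid:
            if strip_ambiguous:
                bases = "".join(b for b in bases if b in valid)
            else:
                n_dirty += 1
                continue
        if len(bases) < min_len:
            n_short += 1
            continue
        kept.append(SequenceRecord(id=rec.id, bases=bases, label=rec.label))
    if n_short or n_dirty:
        logger.info(
            "clean_records: dropped %d short (<%d nt) and %d with non-ACTG characters; %d kept",
            n_short, min_len, n_dirty, len(kept),
        )
    return kept


def _require_labels(records: list[SequenceRecord]) -> np.ndarray:
    labels = np.array([-1 if r.label is None else r.label for r in records])
    if (labels < 0).any():
        raise ValueError("every record must carry a 0/1 label")
    return labels


def balanced_split(
    records: list[SequenceRecord],
    train_frac: float = 0.7,
    balance: bool = True,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified 7:3 (by default) split, optionally after 1:1 downsampling.

    With ``balance`` the majority class is randomly downsampled to the
    minority class size before splitting, so both partitions are 1:1 within
    rounding.  Deterministic given ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0,1), got {train_frac}")
    labels = _require_labels(records)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    train: list[SequenceRecord] = []
    test: list[SequenceRecord] = []
    n_keep = min(int((labels == c).sum()) for c in classes) if balance else None
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        if n_keep is not None:
            idx = idx[:n_keep]
        n_train = round(len(idx) * train_frac)
        train.extend(records[i] for i in idx[:n_train])
        test.extend(records[i] for i in idx[n_train:])
    return DatasetSplit(train=train, test=test, seed=seed)


def kfold_indices(
    records: list[SequenceRecord], k_folds: int = 10, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold partition, returned as (train-ids, test-ids) pairs.

    Test folds are pairwise disjoint and jointly cover every record.
    """
    if k_folds < 2:
        raise ValueError(f"k_folds must be ≥ 2, got {k_folds}")
    labels = _require_labels(records)
    for c in np.unique(labels):
        size = int((labels == c).sum())
        if k_folds > size:
            raise ValueError(f"k_folds={k_folds} exceeds class {c} size {size}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(records), dtype=np.int64)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        # deal class members round-robin across folds for near-equal stratified sizes
        fold_of[idx] = np.arange(len(idx)) % k_folds
    folds = []
    ids = [r.id for r in records]
    for f in range(k_folds):
        test_ids = [ids[i] for i in np.flatnonzero(fold_of == f)]
        train_ids = [ids[i] for i in np.flatnonzero(fold_of != f)]
        folds.append((train_ids, test_ids))
    return folds
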