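"""Reading, validating, deduplicating and splitting labeled protein sequence sets.

Datasets are kept as paired FASTA files (one for bacteriocins, one for
non-bacteriocins); labels are +1 for bacteriocin and -1 for non-bacteriocin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

POSITIVE = 1
NEGATIVE = -1


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the 20-residue alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated amino-acid sequence with identifier and optional label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Ordered collection of protein records with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate sequence id: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == POSITIVE)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == NEGATIVE)

    def subset(self, labels: int) -> list[ProteinRecord]:
        return [r for r in self.records if r.label == labels]

    def merged_with(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(self.records + other.records)


def validate_sequence(record: ProteinRecord, policy: str = "reject") -> ProteinRecord | None:
    """Normalize case and enforce the 20-letter alphabet.

    policy="reject" raises on the first non-standard character (B, Z, X, U,
    '*', gaps, ...), naming its 1-based position; policy="drop-record"
    returns None so callers can exclude and count the record.
    """
    if policy not in ("reject", "drop-record"):
        raise ValueError(f"unknown policy {policy!r}")
    seq = record.sequence.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_SET:
            if policy == "reject":
                raise SequenceValidationError(
                    f"record {record.id!r}: non-standard character {ch!r} at position {pos}"
                )
            return None
    return ProteinRecord(record.id, seq, record.label)


def validate_dataset(dataset: LabeledDataset, policy: str = "reject") -> tuple[LabeledDataset, int]:
    """Validate every record; returns (clean dataset, number dropped)."""
    kept, dropped = [], 0
    for rec in dataset:
        out = validate_sequence(rec, policy=policy)
        if out is None:
            dropped += 1
        else:
            kept.append(out)
    return LabeledDataset(kept), dropped


def read_fasta(path, label: int | None = None, policy: str = "reject") -> LabeledDataset:
    """Read a FASTA file into a validated LabeledDataset.

    The header token up to the first whitespace becomes the record id; any
    trailing header comment is ignored. Wrapped and unwrapped sequence lines
    are both accepted (Biopython handles either).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(entry.id, str(entry.seq), label))
    if not records:
        raise ValueError(f"no sequences in {path}")
    dataset = LabeledDataset(records)
    dataset, _ = validate_dataset(dataset, policy=policy)
    return dataset


def write_fasta(dataset: LabeledDataset, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _identity_aligner() -> PairwiseAligner:
    # Global alignment: match +1, mismatch 0, linear gap -1; identity is
    # exact matches over the alignment length of the best-scoring path.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def percent_identity(seq_a: str, seq_b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment fractional identity: matches / alignment columns."""
    if aligner is None:
        aligner = _identity_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def reduce_redundancy(dataset: LabeledDataset, identity_threshold: float = 0.90) -> LabeledDataset:
    """Greedy longest-first clustering: keep a record iff its identity to every
    already-retained record of the same class is below the threshold.

    Approximates CD-HIT-style redundancy removal at the default 90% cutoff.
    Clustering is per class so a bacteriocin never knocks out a non-bacteriocin.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    aligner = _identity_aligner()
    retained_order = {}
    for lab in sorted({r.label for r in dataset}, key=lambda x: (x is None, x)):
        group = [r for r in dataset if r.label == lab]
        order = sorted(range(len(group)), key=lambda i: (-group[i].length, i))
        kept: list[ProteinRecord] = []
        for i in order:
            rec = group[i]
            if all(
                percent_identity(rec.sequence, k.sequence, aligner) < identity_threshold
                for k in kept
            ):
                kept.append(rec)
                retained_order[rec.id] = None
    return LabeledDataset([r for r in dataset if r.id in retained_order])


def stratified_split(
    dataset: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class random partition; test size per class = floor((1-f)*n_class).

    With the canonical 283+283 training store this yields a 56+56 test set.
    """
    if not (0.0 < train_fraction <= 1.0):
        raise ValueError("train_fraction must be in (0, 1]")
    if train_fraction == 1.0:
        warnings.warn("train_fraction=1.0 leaves an empty test set", stacklevel=2)
    rng = np.random.default_rng(seed)
    train, test = [], []
    labels = sorted({r.label for r in dataset}, key=lambda x: (x is None, x))
    for lab in labels:
        group = [r for r in dataset if r.label == lab]
        if len(group) < 2 and train_fraction < 1.0:
            raise ValueError(f"class {lab} has fewer than 2 members; cannot split")
        n_test = int(np.floor((1.0 - train_fraction) * len(group)))
        test_idx = set(rng.choice(len(group), size=n_test, replace=False).tolist())
        for i, rec in enumerate(group):
            (test if i in test_idx else train).append(rec)
    return LabeledDataset(train), LabeledDataset(test)


def balance_by_subsampling(dataset: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Randomly subsample the majority class (without replacement) to the
    minority class size, e.g. 497 negatives down to 283."""
    n_pos, n_neg = dataset.n_pos, dataset.n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    if n_pos == n_neg:
        return dataset
    rng = np.random.default_rng(seed)
    major_lab = POSITIVE if n_pos > n_neg else NEGATIVE
    target = min(n_pos, n_neg)
    major = [r for r in dataset if r.label == major_lab]
    keep = set(rng.choice(len(major), size=target, replace=False).tolist())
    kept_ids = {major[i].id for i in keep}
    return LabeledDataset(
        [r for r in dataset if r.label != major_lab or r.id in kept_ids]
    )
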