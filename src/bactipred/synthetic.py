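"""Seeded synthetic two-class protein datasets with controllable separation.

Negatives are drawn i.i.d. from a background residue composition close to
the SwissProt average.  Positives are drawn from a mixture that shifts
weight delta onto a bacteriocin-like pool enriched in lysine, arginine,
cysteine and glycine — a caricature of the cationic, disulfide-rich,
glycine-rich character of many bacteriocins, not a biological model.
delta = 0 makes the two classes statistically identical, so the whole
pipeline can be exercised under the null as well as under signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import AMINO_ACIDS, LabeledDataset, NEGATIVE, POSITIVE, ProteinRecord, write_fasta

# Approximate SwissProt background frequencies, order ACDEFGHIKLMNPQRSTVWY.
BACKGROUND_COMPOSITION = np.array([
    0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0593,
    0.0581, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0665,
    0.0535, 0.0687, 0.0110, 0.0292,
])
BACKGROUND_COMPOSITION = BACKGROUND_COMPOSITION / BACKGROUND_COMPOSITION.sum()

# Bacteriocin-like pool: strongly enriched K/R (cationic), C (disulfide
# bridges) and G (flexibility), with the remainder spread thinly.
_ENRICHED = {"K": 0.22, "R": 0.18, "C": 0.15, "G": 0.15}
_rest = (1.0 - sum(_ENRICHED.values())) / (20 - len(_ENRICHED))
ENRICHED_COMPOSITION = np.array(
    [_ENRICHED.get(a, _rest) for a in AMINO_ACIDS]
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    n_per_class sequences per class, lengths uniform on [length_min,
    length_max], class separation delta in [0, 1] (mixture weight of the
    enriched pool in the positive composition).
    """

    n_per_class: int = 100
    length_min: int = 30
    length_max: int = 80
    delta: float = 0.5
    seed: int = 0
    id_prefix: str = ""  # distinguishes records from independently drawn sets

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.length_min <= 10:
            raise ValueError(
                "length_min must exceed 10 (pseudo-AAC needs > lambda residues)"
            )
        if self.length_max < self.length_min:
            raise ValueError("length_max < length_min")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must be in [0, 1]")


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw 2*n_per_class validated records, reproducibly under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    pos_comp = (1.0 - spec.delta) * BACKGROUND_COMPOSITION + spec.delta * ENRICHED_COMPOSITION
    records = []
    for label, comp, tag in (
        (POSITIVE, pos_comp, "pos"),
        (NEGATIVE, BACKGROUND_COMPOSITION, "neg"),
    ):
        for i in range(spec.n_per_class):
            L = int(rng.integers(spec.length_min, spec.length_max + 1))
            seq = "".join(rng.choice(aa, size=L, p=comp))
            records.append(ProteinRecord(f"{spec.id_prefix}{tag}_{i:04d}", seq, label))
    return LabeledDataset(records)


def write_paired_fasta(dataset: LabeledDataset, positives_path, negatives_path) -> None:
    """Persist a labeled dataset as the paired FASTA layout the readers use."""
    write_fasta(LabeledDataset(dataset.subset(POSITIVE)), Path(positives_path))
    write_fasta(LabeledDataset(dataset.subset(NEGATIVE)), Path(negatives_path))
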