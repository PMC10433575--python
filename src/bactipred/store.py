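"""Retrainable training store: paired FASTA files plus pristine originals.

The store directory holds ``positives.fasta`` / ``negatives.fasta`` (the
live training data users may append to) and an ``originals/`` copy frozen at
initialization; ``reset()`` restores the originals byte-for-byte.  A
``manifest.json`` tracks counts and SHA-256 checksums of the live files.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from pathlib import Path

from .sequence_io import (
    LabeledDataset,
    NEGATIVE,
    POSITIVE,
    read_fasta,
    validate_sequence,
    write_fasta,
)

_FILES = {POSITIVE: "positives.fasta", NEGATIVE: "negatives.fasta"}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TrainingStore:
    def __init__(self, directory):
        self.dir = Path(directory)

    @property
    def originals_dir(self) -> Path:
        return self.dir / "originals"

    @property
    def manifest_path(self) -> Path:
        return self.dir / "manifest.json"

    def path_for(self, label: int) -> Path:
        return self.dir / _FILES[label]

    # ------------------------------------------------------------------
    @classmethod
    def initialize(cls, directory, positives_fasta, negatives_fasta) -> "TrainingStore":
        store = cls(directory)
        store.dir.mkdir(parents=True, exist_ok=True)
        store.originals_dir.mkdir(exist_ok=True)
        for label, src in ((POSITIVE, positives_fasta), (NEGATIVE, negatives_fasta)):
            read_fasta(src, label=label)  # validates before accepting
            shutil.copyfile(src, store.path_for(label))
            shutil.copyfile(src, store.originals_dir / _FILES[label])
        store._write_manifest()
        return store

    def _require_populated(self):
        for label in (POSITIVE, NEGATIVE):
            if not self.path_for(label).exists():
                raise FileNotFoundError(
                    f"training store missing {self.path_for(label)}"
                )

    def load(self) -> LabeledDataset:
        self._require_populated()
        pos = read_fasta(self.path_for(POSITIVE), label=POSITIVE)
        neg = read_fasta(self.path_for(NEGATIVE), label=NEGATIVE)
        return pos.merged_with(neg)

    # ------------------------------------------------------------------
    def add_sequences(self, fasta_path, label: int) -> int:
        """Validate and append records; duplicate ids against the whole store
        are rejected and leave the store untouched.  Returns #added."""
        if label not in (POSITIVE, NEGATIVE):
            raise ValueError("label must be +1 or -1")
        self._require_populated()
        current = self.load()
        existing_ids = {r.id for r in current}
        incoming = read_fasta(fasta_path, label=label)
        clashes = [r.id for r in incoming if r.id in existing_ids]
        if clashes:
            raise ValueError(
                f"id(s) already present in store: {', '.join(clashes[:5])}"
            )
        validated = [validate_sequence(r) for r in incoming]
        target = self.path_for(label)
        existing = read_fasta(target, label=label)
        write_fasta(LabeledDataset(existing.records + validated), target)
        self._write_manifest()
        return len(validated)

    def reset(self) -> None:
        """Restore the live files byte-identically from originals/."""
        for label in (POSITIVE, NEGATIVE):
            orig = self.originals_dir / _FILES[label]
            if not orig.exists():
                raise FileNotFoundError(f"missing original: {orig}")
            shutil.copyfile(orig, self.path_for(label))
        self._write_manifest()

    # ------------------------------------------------------------------
    def _write_manifest(self) -> None:
        data = self.load()
        manifest = {
            "n_pos": data.n_pos,
            "n_neg": data.n_neg,
            "checksums": {
                name: _sha256(self.dir / name) for name in _FILES.values()
            },
        }
        self.manifest_path.write_text(json.dumps(manifest, indent=2))

    def manifest(self) -> dict:
        return json.loads(self.manifest_path.read_text())
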