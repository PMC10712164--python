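"""Protein FASTA databases: per-protein lengths and amino-acid count vectors.

A :class:`ProteinDB` is the in-memory form of a proteome search database.
Each record carries the raw sequence, its length in residues, and a
20-dimensional amino-acid count vector in the canonical ``AA_ORDER``.
Ambiguous residues (B, Z, U, X) count toward length but not toward the
composition vector, so length normalization stays faithful without
inventing amino-acid assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AA_ORDER, AMBIGUOUS_RESIDUES

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_VALID_RESIDUES = frozenset(AA_ORDER) | AMBIGUOUS_RESIDUES


class FastaError(ValueError):
    """Raised for malformed or inconsistent FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, sequence, derived length and AA counts."""

    protein_id: str
    sequence: str
    aa_counts: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise FastaError(f"empty sequence for {self.protein_id!r}")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise FastaError(
                f"protein {self.protein_id!r} contains non-amino-acid "
                f"residue(s) {sorted(bad)}"
            )
        counts = np.zeros(len(AA_ORDER), dtype=np.int64)
        for ch in seq:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "aa_counts", counts)

    @property
    def length(self) -> int:
        """Protein length in residues, ambiguous residues included."""
        return len(self.sequence)


@dataclass
class ProteinDB:
    """Mapping of protein_id -> :class:`ProteinRecord` with a source label."""

    records: dict[str, ProteinRecord]
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.records

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self.records[protein_id]

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records.values())

    def length(self, protein_id: str) -> int:
        return self.records[protein_id].length

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord], source: str = "") -> "ProteinDB":
        out: dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.protein_id in out:
                raise FastaError(f"duplicate protein id {rec.protein_id!r}")
            out[rec.protein_id] = rec
        return cls(records=out, source=source)


def read_fasta(path: str | Path) -> ProteinDB:
    """Read a protein FASTA file into a :class:`ProteinDB`.

    The header token before the first whitespace is the protein id;
    sequences are upper-cased.  Duplicate ids, empty sequences, and
    residues outside the 20 canonical + {B, Z, U, X} raise
    :class:`FastaError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(protein_id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return ProteinDB.from_records(records, source=path.name)


def write_fasta(db: ProteinDB, path: str | Path) -> None:
    """Write a :class:`ProteinDB` back to FASTA (id-only headers)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.protein_id, description="")
        for rec in db
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def aa_count_matrix(db: ProteinDB) -> pd.DataFrame:
    """Proteins x 20 amino-acid count matrix.

    Rows are indexed by protein id, columns follow the canonical
    alphabetical ``AA_ORDER``.  Row sums equal protein lengths for
    sequences free of ambiguous residues.
    """
    if len(db) == 0:
        raise FastaError("empty protein database")
    ids = list(db.records)
    mat = np.vstack([db.records[p].aa_counts for p in ids])
    return pd.DataFrame(mat, index=ids, columns=list(AA_ORDER))
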