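"""Spectral-count quantification: razor assignment and length normalization.

Peptide-spectrum matches (PSMs) arrive as rows of (peptide, candidate
proteins, count).  Shared peptides are resolved to a single "razor"
protein by a greedy majority-evidence rule, then per-protein counts are
divided by protein length; the length-normalized PSM count is the
quantification value used by every downstream module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .proteome import ProteinDB

#: Prefix marking contaminant database entries; dropped before quantification.
CONTAMINANT_PREFIX = "contam_"


class QuantError(ValueError):
    """Raised for invalid PSM tables or quantification inputs."""


@dataclass(frozen=True)
class PsmRow:
    peptide: str
    protein_ids: tuple[str, ...]
    psm_count: float

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise QuantError(f"peptide {self.peptide!r} has no candidate proteins")
        if self.psm_count <= 0:
            raise QuantError(
                f"peptide {self.peptide!r} has non-positive count {self.psm_count}"
            )


@dataclass
class PsmTable:
    """Per-sample PSM records mapping peptides to candidate proteins.

    Counts are spectral counts (integers in real search output); the
    synthetic generator may emit exact expected counts, so positive reals
    are accepted.
    """

    sample_id: str
    rows: list[PsmRow] = field(default_factory=list)

    def total_psms(self) -> float:
        return sum(r.psm_count for r in self.rows)


@dataclass
class SampleQuant:
    """Length-normalized quantification values for one sample.

    ``quant[p] = razor_psm[p] / length(p)`` exactly; proteins with zero
    assigned PSMs are absent rather than zero-filled.
    """

    sample_id: str
    quant: dict[str, float]
    razor_psm: dict[str, float]

    def total(self) -> float:
        return sum(self.quant.values())


def _strip_contaminants(table: PsmTable) -> PsmTable:
    rows = []
    for row in table.rows:
        kept = tuple(p for p in row.protein_ids if not p.startswith(CONTAMINANT_PREFIX))
        if kept:
            rows.append(PsmRow(row.peptide, kept, row.psm_count))
    return PsmTable(sample_id=table.sample_id, rows=rows)


def assign_razor(psms: PsmTable, db: ProteinDB) -> dict[str, float]:
    """Assign each PSM row's count to exactly one candidate protein.

    Two passes: unique-peptide counts are tallied first; shared rows are
    then processed in input order, each assigned to the candidate with the
    largest accumulated evidence (unique + previously assigned shared),
    ties broken by lexicographically smallest protein id.  Total counts
    are conserved exactly.
    """
    psms = _strip_contaminants(psms)
    unknown = sorted(
        {p for row in psms.rows for p in row.protein_ids if p not in db}
    )
    if unknown:
        raise QuantError(f"protein ids absent from database: {unknown}")

    evidence: dict[str, float] = {}
    shared: list[PsmRow] = []
    for row in psms.rows:
        if len(row.protein_ids) == 1:
            pid = row.protein_ids[0]
            evidence[pid] = evidence.get(pid, 0.0) + row.psm_count
        else:
            shared.append(row)

    assigned = dict(evidence)
    for row in shared:
        winner = min(
            row.protein_ids,
            key=lambda p: (-assigned.get(p, 0.0), p),
        )
        assigned[winner] = assigned.get(winner, 0.0) + row.psm_count
    return {p: c for p, c in assigned.items() if c > 0}


def length_normalize(razor: Mapping[str, float], db: ProteinDB) -> SampleQuant:
    """Divide razor PSM counts by protein length (PSMs per residue)."""
    quant = {p: c / db.length(p) for p, c in razor.items()}
    return SampleQuant(sample_id="", quant=quant, razor_psm=dict(razor))


def quantify(psms: PsmTable, db: ProteinDB) -> SampleQuant:
    """Razor-assign then length-normalize one PSM table."""
    razor = assign_razor(psms, db)
    sq = length_normalize(razor, db)
    sq.sample_id = psms.sample_id
    return sq


def quant_share(quant: SampleQuant, subset: Iterable[str]) -> float:
    """Fraction of total quantification carried by a protein subset."""
    total = quant.total()
    if total <= 0:
        raise QuantError("zero total quantification")
    subset = set(subset)
    return sum(v for p, v in quant.quant.items() if p in subset) / total


# ---------------------------------------------------------------------------
# I/O: PSM CSV (sample_id, peptide, protein_ids ';'-separated, psm_count)
# and SampleQuant TSV.

def read_psm_csv(path: str | Path) -> list[PsmTable]:
    df = pd.read_csv(path)
    required = {"sample_id", "peptide", "protein_ids", "psm_count"}
    missing = required - set(df.columns)
    if missing:
        raise QuantError(f"PSM CSV missing columns: {sorted(missing)}")
    tables = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        rows = [
            PsmRow(
                peptide=str(r.peptide),
                protein_ids=tuple(str(r.protein_ids).split(";")),
                psm_count=float(r.psm_count),
            )
            for r in grp.itertuples()
        ]
        tables.append(PsmTable(sample_id=str(sample_id), rows=rows))
    return tables


def write_psm_csv(tables: Sequence[PsmTable], path: str | Path) -> None:
    recs = [
        {
            "sample_id": t.sample_id,
            "peptide": r.peptide,
            "protein_ids": ";".join(r.protein_ids),
            "psm_count": r.psm_count,
        }
        for t in tables
        for r in t.rows
    ]
    pd.DataFrame.from_records(recs).to_csv(path, index=False)


def write_quant_tsv(quants: Sequence[SampleQuant], db: ProteinDB, path: str | Path) -> None:
    recs = [
        {
            "sample_id": q.sample_id,
            "protein_id": p,
            "razor_psm": q.razor_psm[p],
            "length": db.length(p),
            "quant": q.quant[p],
        }
        for q in quants
        for p in sorted(q.quant)
    ]
    pd.DataFrame.from_records(recs).to_csv(path, sep="\t", index=False)


def read_quant_tsv(path: str | Path) -> list[SampleQuant]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        out.append(
            SampleQuant(
                sample_id=str(sample_id),
                quant=dict(zip(grp.protein_id.astype(str), grp.quant)),
                razor_psm=dict(zip(grp.protein_id.astype(str), grp.razor_psm)),
            )
        )
    return out
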