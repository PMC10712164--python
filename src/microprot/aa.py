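"""Amino-acid composition of whole cells and cellular components.

The composition of a protein set is the quantification-weighted sum of
per-protein amino-acid count vectors, normalized either by residue count
(mol fraction) or by residue mass (g AA / g protein; the default, using
average residue masses).  The relative-difference statistic compares a
component's profile to that of ribosomal proteins, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import AA_ORDER, ESSENTIAL_AA, RESIDUE_MASS
from .proteome import ProteinDB
from .quant import SampleQuant

Mode = Literal["mass", "count"]

_MASS_VECTOR = np.array([RESIDUE_MASS[a] for a in AA_ORDER])


class ProfileError(ValueError):
    """Raised for invalid profile inputs."""


@dataclass
class AAProfile:
    """20-dim amino-acid fraction vector for a context (whole cell/component)."""

    context: str
    fractions: pd.Series  # indexed by AA 1-letter codes in AA_ORDER
    mode: Mode

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy(dtype=float)
        if (f < 0).any():
            raise ProfileError("negative amino-acid fraction")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ProfileError(f"fractions sum to {f.sum()}, not 1")


@dataclass
class AARelDiff:
    """Per-AA relative difference (%) of a component versus ribosomal proteins."""

    component: str
    delta_pct: pd.Series  # NaN where the ribosomal fraction is zero


def profile(
    quant: SampleQuant,
    db: ProteinDB,
    subset: Iterable[str] | None = None,
    mode: Mode = "mass",
) -> AAProfile:
    """Amino-acid profile of a protein subset, quant-weighted.

    raw_a = sum_p quant_p * count_{p,a}; count mode normalizes raw
    directly, mass mode weights by average residue masses first so the
    result is g AA / g protein.
    """
    ids = set(quant.quant) if subset is None else set(subset) & set(quant.quant)
    if not ids:
        raise ProfileError("subset does not intersect quantified proteins")
    raw = np.zeros(len(AA_ORDER))
    for pid in ids:
        raw += quant.quant[pid] * db[pid].aa_counts
    if mode == "mass":
        raw = raw * _MASS_VECTOR
    elif mode != "count":
        raise ProfileError(f"unknown mode {mode!r}")
    total = raw.sum()
    if total <= 0:
        raise ProfileError("zero total amino-acid signal")
    context = "whole_cell" if subset is None else "subset"
    return AAProfile(
        context=context,
        fractions=pd.Series(raw / total, index=list(AA_ORDER)),
        mode=mode,
    )


def rel_diff(profile_c: AAProfile, profile_ribo: AAProfile) -> AARelDiff:
    """Relative difference (%) of a component profile versus the ribosomal one.

    delta_a = (f_{a,c} - f_{a,ribo}) / f_{a,ribo} * 100.  Amino acids with
    zero ribosomal fraction are reported as NaN, not infinite.
    """
    if profile_c.mode != profile_ribo.mode:
        raise ProfileError(
            f"mode mismatch: {profile_c.mode!r} vs {profile_ribo.mode!r}"
        )
    ribo = profile_ribo.fractions
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (profile_c.fractions - ribo) / ribo * 100.0
    delta = delta.mask(ribo == 0)
    return AARelDiff(component=profile_c.context, delta_pct=delta)


def essential_subset(
    profile_in: AAProfile, renormalize: bool = False
) -> pd.Series:
    """Restrict a profile to the essential + conditionally essential AAs.

    The 15-AA nutritional focus set (Arg, Cys, Gln, Gly, His, Ile, Leu,
    Lys, Met, Phe, Pro, Thr, Trp, Tyr, Val).  Without renormalization the
    values keep their whole-profile scale.
    """
    order = [a for a in AA_ORDER if a in ESSENTIAL_AA]
    sub = profile_in.fractions.loc[order]
    if renormalize:
        total = sub.sum()
        if total <= 0:
            raise ProfileError("essential subset sums to zero; cannot renormalize")
        sub = sub / total
    return sub


def write_profiles_tsv(
    profiles: Sequence[AAProfile], path: str | Path
) -> None:
    recs = [
        {"context": p.context, "mode": p.mode, "aa_code": aa, "value": val}
        for p in profiles
        for aa, val in p.fractions.items()
    ]
    pd.DataFrame.from_records(recs).to_csv(path, sep="\t", index=False)
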