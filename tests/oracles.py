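"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions, deliberately avoiding
the code paths under test: transitive closures by edge-relation fixpoint
iteration, razor assignment by a literal two-pass walk, Spearman by
rank-then-Pearson, and amino-acid profiles by per-residue tallying.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Graph closures by fixpoint iteration


def closure_up(edges: list[tuple[str, str, str]], start: str) -> set[str]:
    """Ancestors-with-self of ``start`` over (child, parent, rel) edges."""
    out = {start}
    changed = True
    while changed:
        changed = False
        for child, parent, _rel in edges:
            if child in out and parent not in out:
                out.add(parent)
                changed = True
    return out


def closure_down(edges: list[tuple[str, str, str]], start: str) -> set[str]:
    """Descendants-with-self of ``start``."""
    out = {start}
    changed = True
    while changed:
        changed = False
        for child, parent, _rel in edges:
            if parent in out and child not in out:
                out.add(child)
                changed = True
    return out


def brute_collapse(
    annotations: set[str],
    edges: list[tuple[str, str, str]],
    names: dict[str, str],
    roots: tuple[str, ...],
    ribosome_root: str,
    complex_root: str,
) -> set[str]:
    """Literal re-implementation of the CC collapse on raw edge lists."""
    expanded: set[str] = set()
    for a in annotations:
        expanded |= closure_up(edges, a)
    reference: set[str] = set()
    ref_sets = {}
    for r in roots:
        ref_sets[r] = closure_down(edges, r)
        reference |= ref_sets[r]
    matched = expanded & reference
    if matched:
        retained = set()
        for t in matched:
            is_proper_ancestor = any(
                u != t and t in closure_up(edges, u) for u in matched
            )
            if not is_proper_ancestor:
                retained.add(t)
    else:
        retained = expanded
    labels = set()
    for t in retained:
        if t in ref_sets.get(ribosome_root, set()):
            labels.add("ribosome")
        elif t in ref_sets.get(complex_root, set()):
            labels.add("protein containing complexes")
        elif "membrane" in names.get(t, t).lower():
            labels.add("membrane")
        else:
            labels.add(names.get(t, t))
    return labels


# ---------------------------------------------------------------------------
# Razor assignment, literal two-pass walk


def brute_razor(rows: list[tuple[str, tuple[str, ...], float]]) -> dict[str, float]:
    """(peptide, candidates, count) rows -> razor totals per protein."""
    assigned: dict[str, float] = {}
    for _pep, prots, count in rows:
        if len(prots) == 1:
            assigned[prots[0]] = assigned.get(prots[0], 0.0) + count
    for _pep, prots, count in rows:
        if len(prots) > 1:
            ranked = sorted(prots, key=lambda p: (-assigned.get(p, 0.0), p))
            assigned[ranked[0]] = assigned.get(ranked[0], 0.0) + count
    return {p: c for p, c in assigned.items() if c > 0}


# ---------------------------------------------------------------------------
# Spearman by rank-then-Pearson


def brute_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# Amino-acid profile by per-residue tally


def brute_profile(
    sequences: dict[str, str],
    quant: dict[str, float],
    aa_order: str,
    masses: dict[str, float] | None = None,
) -> np.ndarray:
    """Walk every residue of every quantified protein and tally."""
    raw = {aa: 0.0 for aa in aa_order}
    for pid, q in quant.items():
        for residue in sequences[pid]:
            if residue in raw:
                raw[residue] += q
    vals = np.array([raw[aa] for aa in aa_order])
    if masses is not None:
        vals = vals * np.array([masses[aa] for aa in aa_order])
    return vals / vals.sum()


# ---------------------------------------------------------------------------
# Random DAG generation for closure tests


def random_dag(
    rng: np.random.Generator, n_terms: int, membrane_fraction: float = 0.2
) -> tuple[dict[str, tuple[str, str]], list[tuple[str, str, str]]]:
    """Random rooted DAG as ({id: (name, namespace)}, edge list).

    Node 0 is a global root; each later node gets 1-2 parents among the
    earlier nodes, with random is_a/part_of relations.  A fraction of
    names contain "membrane" to exercise the name-based grouping.
    """
    terms = {}
    edges = []
    for i in range(n_terms):
        go_id = f"GO:{i:07d}"
        name = f"membrane region {i}" if rng.random() < membrane_fraction else f"term {i}"
        terms[go_id] = (name, "cellular_component")
        if i > 0:
            n_par = 1 + int(rng.random() < 0.4)
            parents = rng.choice(i, size=min(n_par, i), replace=False)
            for p in np.atleast_1d(parents):
                rel = "is_a" if rng.random() < 0.7 else "part_of"
                edges.append((go_id, f"GO:{int(p):07d}", rel))
    return terms, edges
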