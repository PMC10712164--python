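"""GO cellular-component collapsing and proteome allocation.

The allocation procedure mirrors what practitioners do with the Gene
Ontology cellular-component namespace: build a reference of all
descendants of "cellular anatomical entity" (GO:0110165),
"protein-containing complex" (GO:0032991) and "ribosome" (GO:0005840);
expand each protein's annotations with their is_a/part_of ancestors;
intersect with the reference; keep only the most specific term per
lineage; and collapse the survivors into simplified labels (ribosome,
protein containing complexes, membrane, or the term's own name).  The
length-normalized razor quantification of each label is then summed and
the top 3 labels reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .constants import (
    DEFAULT_GO_ROOTS,
    GO_PROTEIN_CONTAINING_COMPLEX,
    GO_RIBOSOME,
)
from .quant import SampleQuant

#: Relations traversed when expanding/collapsing terms.
TRAVERSED_RELATIONS = ("is_a", "part_of")

COMPLEX_LABEL = "protein containing complexes"
MEMBRANE_LABEL = "membrane"
RIBOSOME_LABEL = "ribosome"


class OntologyError(ValueError):
    """Raised for malformed ontologies or unknown terms."""


@dataclass
class GoGraph:
    """GO term DAG restricted to typed is_a / part_of edges.

    Internally a :class:`networkx.DiGraph` with edges pointing child ->
    parent and a ``relation`` attribute on each edge.
    """

    graph: nx.DiGraph

    def __contains__(self, go_id: str) -> bool:
        return go_id in self.graph

    def __len__(self) -> int:
        return len(self.graph)

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, go_id: str) -> str:
        self._require(go_id)
        return self.graph.nodes[go_id].get("name", go_id)

    def namespace(self, go_id: str) -> str:
        self._require(go_id)
        return self.graph.nodes[go_id].get("namespace", "")

    def edges(self) -> list[tuple[str, str, str]]:
        """(child, parent, relation) triples."""
        return [(c, p, d["relation"]) for c, p, d in self.graph.edges(data=True)]

    def _require(self, go_id: str) -> None:
        if go_id not in self.graph:
            raise OntologyError(f"unknown GO term {go_id!r}")

    @classmethod
    def from_edges(
        cls,
        terms: Mapping[str, tuple[str, str]],
        edges: Iterable[tuple[str, str, str]],
    ) -> "GoGraph":
        """Build from {id: (name, namespace)} and (child, parent, relation)."""
        g = nx.DiGraph()
        for go_id, (name, namespace) in terms.items():
            g.add_node(go_id, name=name, namespace=namespace)
        for child, parent, relation in edges:
            if relation not in TRAVERSED_RELATIONS:
                continue
            for endpoint in (child, parent):
                if endpoint not in g:
                    raise OntologyError(f"edge endpoint {endpoint!r} not a term")
            g.add_edge(child, parent, relation=relation)
        _check_acyclic(g)
        return cls(graph=g)


def _check_acyclic(g: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")


def read_obo(path: str | Path) -> GoGraph:
    """Read an OBO 1.2 file, keeping only is_a and part_of edges.

    Obsolete terms are skipped; a cycle over the traversed relations is an
    error naming one cycle member.
    """
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node), namespace=data.get("namespace", ""))
    for child, parent, key in multi.edges(keys=True):
        if key in TRAVERSED_RELATIONS:
            g.add_edge(child, parent, relation=key)
    _check_acyclic(g)
    return GoGraph(graph=g)


def descendants(graph: GoGraph, root_id: str) -> set[str]:
    """All terms below ``root_id`` via is_a/part_of, root included."""
    graph._require(root_id)
    return nx.ancestors(graph.graph, root_id) | {root_id}


def ancestors(graph: GoGraph, term_id: str) -> set[str]:
    """All terms above ``term_id`` via is_a/part_of, the term included."""
    graph._require(term_id)
    return nx.descendants(graph.graph, term_id) | {term_id}


@dataclass
class ReferenceSet:
    """Reference of root -> descendant closure used by the collapse step."""

    roots: tuple[str, ...]
    descendants: dict[str, set[str]]
    all_descendants: set[str] = field(default_factory=set)

    @classmethod
    def build(
        cls,
        graph: GoGraph,
        roots: Iterable[str] = DEFAULT_GO_ROOTS,
        direct_children_only: bool = False,
    ) -> "ReferenceSet":
        roots = tuple(roots)
        desc: dict[str, set[str]] = {}
        for root in roots:
            if direct_children_only:
                graph._require(root)
                desc[root] = set(graph.graph.predecessors(root)) | {root}
            else:
                desc[root] = descendants(graph, root)
        union = set().union(*desc.values()) if desc else set()
        return cls(roots=roots, descendants=desc, all_descendants=union)


def _most_specific(terms: set[str], graph: GoGraph) -> set[str]:
    """Drop any term that is a proper ancestor of another term in the set."""
    kept = set()
    for t in terms:
        proper_anc_of_other = any(
            t != u and t in ancestors(graph, u) for u in terms
        )
        if not proper_anc_of_other:
            kept.add(t)
    return kept


def simplify_label(term: str, graph: GoGraph, ref: ReferenceSet) -> str:
    """Collapse one retained term into its simplified component label."""
    if term in ref.descendants.get(GO_RIBOSOME, set()):
        return RIBOSOME_LABEL
    if term in ref.descendants.get(GO_PROTEIN_CONTAINING_COMPLEX, set()):
        return COMPLEX_LABEL
    if MEMBRANE_LABEL in graph.name(term).lower():
        return MEMBRANE_LABEL
    return graph.name(term)


def retained_terms(
    annotations: Iterable[str], graph: GoGraph, ref: ReferenceSet
) -> set[str]:
    """Expand, intersect with the reference, and keep most specific terms.

    Expand annotations to ancestors-plus-self; intersect with the
    reference closures; if matches exist, retain only the most specific
    term of each lineage; otherwise fall back to the expanded set itself.
    Idempotent: running it on its own output changes nothing.

    Annotation ids missing from the graph are skipped with a warning; it
    is an error only if every id is missing.
    """
    annotations = set(annotations)
    if not annotations:
        raise OntologyError("protein has no CC annotations (filter upstream)")
    known = {a for a in annotations if a in graph}
    missing = annotations - known
    if missing:
        warnings.warn(
            f"skipping GO ids absent from ontology: {sorted(missing)}",
            stacklevel=2,
        )
    if not known:
        raise OntologyError(
            f"none of the annotation ids {sorted(annotations)} are in the ontology"
        )
    expanded: set[str] = set()
    for a in known:
        expanded |= ancestors(graph, a)
    matched = expanded & ref.all_descendants
    return _most_specific(matched, graph) if matched else expanded


def map_protein_terms(
    annotations: Iterable[str], graph: GoGraph, ref: ReferenceSet
) -> set[str]:
    """Collapse a protein's CC annotations into simplified component labels.

    :func:`retained_terms` selects the most specific reference matches
    (or the expanded annotation set when nothing matches); each survivor
    is then collapsed to "ribosome", "protein containing complexes",
    "membrane" (name-based), or its own term name.
    """
    retained = retained_terms(annotations, graph, ref)
    return {simplify_label(t, graph, ref) for t in retained}


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a protein -> GO annotation TSV (protein_id, go_id per line)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise OntologyError(f"bad annotation line: {line!r}")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def label_proteins(
    annotations: Mapping[str, set[str]], graph: GoGraph, ref: ReferenceSet
) -> dict[str, set[str]]:
    """Map every annotated protein to its simplified label set.

    Proteins without any CC annotation are simply absent from the input
    mapping (filtered upstream) and hence from the result.
    """
    return {
        pid: map_protein_terms(terms, graph, ref)
        for pid, terms in annotations.items()
        if terms
    }


@dataclass
class ComponentAllocation:
    """Per-sample summed quantification per simplified component label."""

    sample_id: str
    label_quant: dict[str, float]
    annotated_fraction: float
    top_k: list[str]

    def share(self, label: str) -> float:
        """Label's share of the total (annotated + unannotated) quant."""
        return self.label_quant.get(label, 0.0) / self._total

    _total: float = 0.0


def allocate(
    quant: SampleQuant, labels: Mapping[str, set[str]], k: int = 3
) -> ComponentAllocation:
    """Sum quantification per label and report the top-k components.

    A multi-label protein contributes its full quantification value to
    each of its labels.  ``annotated_fraction`` is the quant-weighted
    fraction of proteins carrying at least one label.
    """
    total = quant.total()
    if not quant.quant or total <= 0:
        raise OntologyError("empty or zero-total quantification")
    label_quant: dict[str, float] = {}
    annotated = 0.0
    for pid, q in quant.quant.items():
        pid_labels = labels.get(pid, set())
        if pid_labels:
            annotated += q
        for lab in pid_labels:
            label_quant[lab] = label_quant.get(lab, 0.0) + q
    top = sorted(label_quant, key=lambda lab: (-label_quant[lab], lab))[:k]
    out = ComponentAllocation(
        sample_id=quant.sample_id,
        label_quant=label_quant,
        annotated_fraction=annotated / total,
        top_k=top,
    )
    out._total = total
    return out


def write_allocation_tsv(allocs: Iterable[ComponentAllocation], path: str | Path) -> None:
    import pandas as pd

    recs = []
    for a in allocs:
        for lab in sorted(a.label_quant, key=lambda l: (-a.label_quant[l], l)):
            recs.append(
                {
                    "sample_id": a.sample_id,
                    "label": lab,
                    "summed_quant": a.label_quant[lab],
                    "share": a.share(lab),
                    "annotated_fraction": a.annotated_fraction,
                }
            )
    pd.DataFrame.from_records(recs).to_csv(path, sep="\t", index=False)
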