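"""Gene Ontology ingestion: the term DAG, ancestor closure and information content.

The ontology is read from an OBO 1.2/1.4 flat file.  Only ``is_a`` and
``part_of`` relationships are retained, because annotation propagation (and
therefore every count downstream) follows exactly those two edge types.
Obsolete terms are recorded but carry no edges; ``alt_id`` aliases resolve to
their primary identifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Set

import networkx as nx
import obonet

RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


class OboParseError(ValueError):
    """Raised when the OBO file is malformed or violates DAG integrity."""


@dataclass
class OntologyDag:
    """The GO term graph restricted to is_a / part_of relations.

    Edges point child -> parent.  ``namespaces`` maps each non-obsolete term to
    one of the three sub-ontologies; ``roots`` maps each namespace to its root
    term (the unique term with no outgoing is_a/part_of edge).
    """

    graph: nx.MultiDiGraph
    namespaces: Dict[str, str]
    obsolete: Set[str]
    alt_ids: Dict[str, str]
    roots: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.roots:
            for term in self.graph.nodes:
                if self.graph.out_degree(term) == 0:
                    ns = self.namespaces.get(term)
                    if ns is not None:
                        self.roots[ns] = term

    @property
    def terms(self) -> Set[str]:
        return set(self.graph.nodes)

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.graph

    def namespace(self, term: str) -> str:
        return self.namespaces[self.resolve(term)]

    def ancestors(
        self, term: str, relations: Iterable[str] = RELATIONS
    ) -> Set[str]:
        """All terms reachable from ``term`` via the selected relations.

        Excludes the term itself.  Raises ``KeyError`` for unknown terms and
        ``ValueError`` for obsolete ones.
        """
        term = self.resolve(term)
        if term in self.obsolete:
            raise ValueError(f"obsolete GO term: {term}")
        if term not in self.graph:
            raise KeyError(f"unknown GO term: {term}")
        relations = frozenset(relations)
        seen: Set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for _, parent, rel in self.graph.out_edges(node, keys=True):
                if rel in relations and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def is_root(self, term: str) -> bool:
        return term in self.roots.values()


def ancestors(dag: OntologyDag, term: str, relations: Iterable[str] = RELATIONS) -> Set[str]:
    return dag.ancestors(term, relations)


def parse_obo(path) -> OntologyDag:
    """Parse an OBO file into an :class:`OntologyDag`.

    Keeps only is_a and part_of edges, records obsolete terms without edges,
    and builds the alt_id -> primary map.  A cyclic is_a/part_of graph raises
    :class:`OboParseError`.
    """
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OboParseError(f"malformed OBO file {path!r}: {exc}") from exc

    graph = nx.MultiDiGraph()
    namespaces: Dict[str, str] = {}
    obsolete: Set[str] = set()
    alt_ids: Dict[str, str] = {}

    for term, data in raw.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            obsolete.add(term)
            continue
        graph.add_node(term)
        ns = data.get("namespace")
        if ns:
            namespaces[term] = ns
        for alias in data.get("alt_id", []):
            alt_ids[alias] = term

    for child, parent, rel in raw.edges(keys=True):
        if rel in RELATIONS and child in graph and parent in graph:
            graph.add_edge(child, parent, key=rel)

    simple = nx.DiGraph(graph)
    if not nx.is_directed_acyclic_graph(simple):
        cycle = nx.find_cycle(simple)
        raise OboParseError(f"is_a/part_of graph contains a cycle: {cycle}")

    return OntologyDag(graph=graph, namespaces=namespaces, obsolete=obsolete, alt_ids=alt_ids)


@dataclass
class InformationContentTable:
    """Per-term information content in bits, plus how it was estimated.

    ``ic[t] = -log2(freq(t))`` where ``freq`` is the fraction of proteins in
    the (propagated) training corpus annotated with ``t`` among those
    annotated with t's namespace root.  Terms never observed in the corpus are
    smoothed to the maximum IC observed in their namespace, so rankings stay
    finite.
    """

    ic: Dict[str, float]
    source_corpus_size: int
    namespaces: Dict[str, str] = field(default_factory=dict)

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def get(self, term: str, default: float | None = None):
        return self.ic.get(term, default)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": list(self.ic),
                "namespace": [self.namespaces.get(t, "") for t in self.ic],
                "ic": list(self.ic.values()),
            }
        )


def compute_information_content(
    dag: OntologyDag, protein_go: Mapping[str, Set[str]]
) -> InformationContentTable:
    """Marginal-frequency information content from a propagated GO corpus.

    Frequencies are computed per namespace: the denominator for term ``t`` is
    the number of proteins annotated with t's namespace root (equivalently,
    with any term of that namespace, since annotations are ancestor-closed).
    """
    if not protein_go:
        raise ValueError("empty annotation corpus")

    term_counts: Dict[str, int] = {}
    ns_counts: Dict[str, int] = {ns: 0 for ns in NAMESPACES}
    for _, terms in protein_go.items():
        seen_ns = set()
        for t in terms:
            t = dag.resolve(t)
            term_counts[t] = term_counts.get(t, 0) + 1
            seen_ns.add(dag.namespaces.get(t))
        for ns in seen_ns:
            if ns in ns_counts:
                ns_counts[ns] += 1

    ic: Dict[str, float] = {}
    namespaces: Dict[str, str] = {}
    max_ic = {ns: 0.0 for ns in NAMESPACES}
    for term, count in term_counts.items():
        ns = dag.namespaces.get(term)
        if ns not in ns_counts or ns_counts[ns] == 0:
            continue
        value = -math.log2(count / ns_counts[ns])
        ic[term] = value
        namespaces[term] = ns
        max_ic[ns] = max(max_ic[ns], value)

    # unseen (zero-frequency) terms: smoothed to the namespace maximum
    for term in dag.graph.nodes:
        if term in ic or term in dag.obsolete:
            continue
        ns = dag.namespaces.get(term)
        if ns in max_ic:
            ic[term] = max_ic[ns]
            namespaces[term] = ns

    return InformationContentTable(
        ic=ic,
        source_corpus_size=len(protein_go),
        namespaces=namespaces,
    )
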