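"""Gene Ontology DAG: parsing, rooted per-namespace structure, depth queries.

Each of the three GO namespaces (molecular_function, biological_process,
cellular_component) is held as a rooted directed acyclic graph with
child→parent edges. Term *depth* is the number of edges on the shortest
root→term path within the term's namespace, so the root itself has depth 0
and its direct children ("catalytic activity"-style terms) have depth 1.
Shallow terms are generic; deep terms are specific. The default edge set
traversed is ``is_a`` plus ``part_of`` — the GO convention for
localization-style reasoning — and never the ``regulates`` family, which can
leak across namespaces. Obsolete terms carry no edges and are rejected by
every query; alternate ids resolve silently to their primary id.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import OboParseError, OboStructureError

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

#: namespace → single-letter GAF aspect
NAMESPACE_TO_ASPECT = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}
ASPECT_TO_NAMESPACE = {v: k for k, v in NAMESPACE_TO_ASPECT.items()}

DEFAULT_RELATIONSHIPS = ("is_a", "part_of")


@dataclass(frozen=True)
class TermInfo:
    """One ontology term as read from its ``[Term]`` stanza."""

    id: str
    name: str
    namespace: str
    alt_ids: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class OntologyGraph:
    """Rooted per-namespace GO DAG answering depth / ancestor / leaf queries.

    Parameters
    ----------
    terms:
        Mapping of primary term id to :class:`TermInfo` (may include obsolete
        terms; they are excluded from the graph structure).
    edges:
        ``(child, parent, relationship)`` triples restricted to the traversed
        relationship kinds.

    Raises
    ------
    OboStructureError
        If the traversed edges contain a cycle, a namespace has more than one
        root, or a non-obsolete term is unreachable from its namespace root.
    """

    def __init__(self, terms: Mapping[str, TermInfo],
                 edges: Iterable[tuple[str, str, str]]):
        self.terms: dict[str, TermInfo] = dict(terms)
        self._alt: dict[str, str] = {}
        for t in self.terms.values():
            for alt in t.alt_ids:
                if alt in self._alt and self._alt[alt] != t.id:
                    raise OboStructureError(
                        f"alternate id {alt} maps to more than one primary term")
                self._alt[alt] = t.id

        self.edges: list[tuple[str, str, str]] = []
        g = nx.DiGraph()  # child -> parent over traversed relationships
        for tid, info in self.terms.items():
            if not info.obsolete:
                g.add_node(tid)
        for child, parent, rel in edges:
            if self.terms[child].obsolete or self.terms[parent].obsolete:
                raise OboStructureError(
                    f"obsolete term on edge {child} -{rel}-> {parent}")
            self.edges.append((child, parent, rel))
            g.add_edge(child, parent, rel=rel)

        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OboStructureError(
                f"cycle among traversed edges involving {cycle[0][0]}")
        self._graph = g

        self.roots: dict[str, str] = {}
        for tid in g.nodes:
            if g.out_degree(tid) == 0:  # no parent
                ns = self.terms[tid].namespace
                if ns in self.roots:
                    raise OboStructureError(
                        f"namespace {ns} has more than one root "
                        f"({self.roots[ns]}, {tid})")
                self.roots[ns] = tid

        self._depth = self._compute_depths()
        unreachable = [t for t in g.nodes if t not in self._depth]
        if unreachable:
            raise OboStructureError(
                f"{len(unreachable)} term(s) unreachable from their namespace "
                f"root, e.g. {unreachable[0]}")

    def _compute_depths(self) -> dict[str, int]:
        # BFS from each root over parent->child (reverse) edges; edges never
        # cross namespaces because every traversed edge ends inside one DAG.
        depth: dict[str, int] = {}
        rev = self._graph.reverse(copy=False)
        for root in self.roots.values():
            depth[root] = 0
            queue = deque([root])
            while queue:
                node = queue.popleft()
                for child in rev.successors(node):
                    if child not in depth:
                        depth[child] = depth[node] + 1
                        queue.append(child)
        return depth

    # -- queries ---------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an alternate id to its primary id (primary ids pass through)."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise LookupError(f"unknown term id {term_id}")

    def __contains__(self, term_id: str) -> bool:
        try:
            return not self.terms[self.resolve(term_id)].obsolete
        except LookupError:
            return False

    def _primary(self, term_id: str) -> str:
        tid = self.resolve(term_id)
        if self.terms[tid].obsolete:
            raise LookupError(f"term {term_id} is obsolete")
        return tid

    def namespace(self, term_id: str) -> str:
        return self.terms[self._primary(term_id)].namespace

    def min_depth(self, term_id: str) -> int:
        """Edges on the shortest root→term path within the term's namespace."""
        return self._depth[self._primary(term_id)]

    def is_leaf(self, term_id: str) -> bool:
        """True iff no non-obsolete term has a traversed edge into this term."""
        return self._graph.in_degree(self._primary(term_id)) == 0

    def ancestors(self, term_id: str) -> set[str]:
        """All terms on any traversed path from the term up to its root."""
        return set(nx.descendants(self._graph, self._primary(term_id)))

    def __len__(self) -> int:
        return sum(1 for t in self.terms.values() if not t.obsolete)


def min_depth(graph: OntologyGraph, term_id: str) -> int:
    return graph.min_depth(term_id)


def is_leaf(graph: OntologyGraph, term_id: str) -> bool:
    return graph.is_leaf(term_id)


def parse_obo(obo_content: str,
              relationships: Iterable[str] = DEFAULT_RELATIONSHIPS,
              ) -> OntologyGraph:
    """Parse OBO 1.2 content into an :class:`OntologyGraph`.

    Only the relationship kinds in *relationships* become edges (default
    ``is_a`` and ``part_of``). Obsolete stanzas are retained so their ids
    raise a clear error when queried, but contribute no structure.
    """
    if "format-version" not in obo_content.split("[Term]")[0]:
        raise OboParseError("content does not declare a format-version header")
    rels = set(relationships)
    graph = obonet.read_obo(io.StringIO(obo_content), ignore_obsolete=False)

    terms: dict[str, TermInfo] = {}
    edges: list[tuple[str, str, str]] = []
    for tid, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        ns = data.get("namespace")
        if ns is None:
            raise OboParseError(
                f"term {tid} (near line {_stanza_line(obo_content, tid)}) "
                "has no namespace")
        if ns not in NAMESPACES:
            raise OboParseError(f"term {tid} has unknown namespace {ns!r}")
        terms[tid] = TermInfo(
            id=tid,
            name=data.get("name", ""),
            namespace=ns,
            alt_ids=frozenset(data.get("alt_id", ())),
            obsolete=obsolete,
        )
        if obsolete:
            continue
        if "is_a" in rels:
            for parent in data.get("is_a", ()):
                edges.append((tid, parent, "is_a"))
        for entry in data.get("relationship", ()):
            rel, _, parent = entry.partition(" ")
            if rel in rels and rel != "is_a":
                edges.append((tid, parent.strip(), rel))

    known = {c for c, p, _ in edges} | {p for c, p, _ in edges}
    missing = known - terms.keys()
    if missing:
        raise OboParseError(f"edge references undefined term {sorted(missing)[0]}")
    return OntologyGraph(terms, edges)


def _stanza_line(content: str, term_id: str) -> int:
    for i, line in enumerate(content.splitlines(), start=1):
        if line.strip() == f"id: {term_id}":
            return i
    return 0
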