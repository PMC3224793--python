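"""Gene Ontology DAG handling and cosine function similarity.

A function (GO term) is represented as a binary vector over all terms of
the ontology: the positions of the term itself and of its ancestors are 1,
all other positions are 0.  The similarity between two functions is the
cosine of their vectors, which for binary vectors reduces to

    fsim(f, f') = |A(f) ∩ A(f')| / sqrt(|A(f)| * |A(f')|)

where A(f) is the (reflexive) ancestor set of f.  This is the quantity the
iterative predictor and the semantic evaluation metrics are built on.

Two closure modes exist.  ``transitive`` (the default) takes the full
reflexive transitive closure of the parent relation, which is the standard
GO reading: a protein annotated with a term is implicitly annotated with
every ancestor of that term.  ``parents_only`` uses the term plus its
direct parents only; it exists to reproduce hand-worked small examples
that enumerate parents rather than the full closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import obonet

NAMESPACES = frozenset(
    {"biological_process", "molecular_function", "cellular_component"}
)

CLOSURE_MODES = ("transitive", "parents_only")


class OntologyError(ValueError):
    """Structural problem with an ontology (cycle, dangling parent...)."""


class UnknownTermError(KeyError):
    """A term identifier that is not present in the ontology."""


@dataclass(frozen=True)
class OntologyTerm:
    """One annotation term: identifier, display name, namespace, parents."""

    id: str
    name: str = ""
    namespace: str = "biological_process"
    parents: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.id in self.parents:
            raise OntologyError(f"term {self.id!r} lists itself as a parent")


@dataclass(frozen=True)
class TermVector:
    """Sparse binary vector of dimension t: the set of positions holding 1."""

    positions: frozenset[int]
    dimension: int

    def __post_init__(self) -> None:
        if not self.positions:
            raise OntologyError("term vector must have at least one position")
        if any(p < 0 or p >= self.dimension for p in self.positions):
            raise OntologyError("vector position out of range")

    def dense(self) -> list[int]:
        """Materialise the full 0/1 list (small ontologies only)."""
        out = [0] * self.dimension
        for p in self.positions:
            out[p] = 1
        return out

    def __len__(self) -> int:
        return len(self.positions)


class Ontology:
    """A DAG of annotation terms with a fixed total ordering of term ids.

    The ordering (lexicographic by id) assigns every term a vector
    position, so term vectors are deterministic across runs.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.id in self.terms:
                raise OntologyError(f"duplicate term id {term.id!r}")
            self.terms[term.id] = term
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.id!r} references unknown parent {parent!r}"
                    )
        self._check_acyclic()
        self.term_index: dict[str, int] = {
            tid: i for i, tid in enumerate(sorted(self.terms))
        }
        self._alt_ids: dict[str, str] = dict(alt_ids or {})
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._fsim_cache: dict[tuple[str, str, str], float] = {}

    def _check_acyclic(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                graph.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            child, parent = nx.find_cycle(graph)[0][:2]
            raise OntologyError(
                f"parent relation contains a cycle through edge "
                f"{child!r} -> {parent!r}"
            )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt_ids

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.terms))

    def canonical_id(self, term_id: str) -> str:
        """Resolve a possibly-secondary (alt) id to its canonical term id."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt_ids:
            return self._alt_ids[term_id]
        raise UnknownTermError(term_id)

    def parents(self, term_id: str) -> frozenset[str]:
        return self.terms[self.canonical_id(term_id)].parents

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive closure: the term plus all terms reachable
        via parent links."""
        tid = self.canonical_id(term_id)
        cached = self._ancestor_cache.get(tid)
        if cached is not None:
            return cached
        closure = {tid}
        stack = list(self.terms[tid].parents)
        while stack:
            cur = stack.pop()
            if cur not in closure:
                closure.add(cur)
                stack.extend(self.terms[cur].parents)
        result = frozenset(closure)
        self._ancestor_cache[tid] = result
        return result

    def term_vector(
        self, term_id: str, closure_mode: str = "transitive"
    ) -> TermVector:
        """Binary ancestor vector of a term under the ontology's term order."""
        tid = self.canonical_id(term_id)
        if closure_mode == "transitive":
            members = self.ancestors(tid)
        elif closure_mode == "parents_only":
            members = {tid} | set(self.terms[tid].parents)
        else:
            raise ValueError(f"unknown closure_mode {closure_mode!r}")
        positions = frozenset(self.term_index[t] for t in members)
        return TermVector(positions=positions, dimension=len(self))

    def fsim(
        self, f1: str, f2: str, closure_mode: str = "transitive"
    ) -> float:
        """Memoised cosine similarity between two terms' ancestor vectors."""
        a, b = self.canonical_id(f1), self.canonical_id(f2)
        if a > b:
            a, b = b, a
        key = (a, b, closure_mode)
        cached = self._fsim_cache.get(key)
        if cached is None:
            cached = function_similarity(
                self.term_vector(a, closure_mode),
                self.term_vector(b, closure_mode),
            )
            self._fsim_cache[key] = cached
        return cached


def ancestors(ontology: Ontology, term: str) -> frozenset[str]:
    """Reflexive ancestor set of ``term`` (the term itself included)."""
    return ontology.ancestors(term)


def term_vector(
    ontology: Ontology, term: str, closure_mode: str = "transitive"
) -> TermVector:
    return ontology.term_vector(term, closure_mode=closure_mode)


def function_similarity(v1: TermVector, v2: TermVector) -> float:
    """Cosine of two binary term vectors; always in [0, 1].

    For binary vectors the dot product is the size of the position
    intersection and each norm is the square root of the number of ones.
    """
    inter = len(v1.positions & v2.positions)
    if inter == 0:
        return 0.0
    return inter / math.sqrt(len(v1.positions) * len(v2.positions))


def load_obo(
    path,
    namespace: str = "biological_process",
    include_part_of: bool = True,
) -> Ontology:
    """Read an OBO 1.2/1.4 file into an :class:`Ontology`.

    Only non-obsolete terms of the requested ``namespace`` are kept.
    ``is_a`` edges are always used as parent links; ``part_of``
    relationships are included unless ``include_part_of`` is False.  All
    other relationship types are ignored.  Secondary (alt) ids are mapped
    to their canonical term id.  A cyclic parent relation raises
    :class:`OntologyError` naming one offending edge.
    """
    if namespace is not None and namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    graph = obonet.read_obo(path, ignore_obsolete=True)

    keep: dict[str, dict] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace", "biological_process")
        if namespace is None or ns == namespace:
            keep[node] = data

    terms = []
    alt_ids: dict[str, str] = {}
    for node, data in keep.items():
        parents: set[str] = set(data.get("is_a", ()))
        if include_part_of:
            for rel in data.get("relationship", ()):
                parts = rel.split()
                if len(parts) == 2 and parts[0] == "part_of":
                    parents.add(parts[1])
        # drop parents outside the kept namespace
        parents &= set(keep)
        parents.discard(node)
        terms.append(
            OntologyTerm(
                id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace", "biological_process"),
                parents=frozenset(parents),
            )
        )
        for alt in data.get("alt_id", ()):
            alt_ids[alt] = node
    return Ontology(terms, alt_ids=alt_ids)
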