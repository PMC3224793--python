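"""PPI network and annotation I/O plus the standard preprocessing filters.

The predictor operates on an undirected simple graph of proteins and a map
from each protein to its set of directly annotated GO terms.  Before
prediction the data are cleaned: duplicated interactions and
self-interactions are dropped, and proteins without any GO annotation are
removed from the network together with their incident edges.  Annotated
proteins that end up without edges are kept — they still count towards the
dataset size N and the per-term counts n_f used by the IDF-style weights.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd
from Bio.UniProt import GOA

from .ontology import Ontology, UnknownTermError

logger = logging.getLogger(__name__)

# tokens that mark the first line of an edge list as a header
_HEADER_TOKENS = {
    "protein", "protein1", "protein2", "protein_a", "protein_b",
    "proteina", "proteinb", "source", "target", "node1", "node2",
    "interactor_a", "interactor_b", "from", "to", "gene1", "gene2",
}


class NetworkFormatError(ValueError):
    """Malformed network or annotation file."""


class UnknownProteinError(KeyError):
    """A protein identifier not present in the network."""


class InteractionNetwork:
    """Undirected simple graph over protein identifiers.

    Self-loops may be present after reading raw files; :func:`preprocess`
    removes them.  Duplicate edges never exist (the underlying graph is
    simple and undirected).
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self._graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        proteins: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(proteins)
        g.add_edges_from(edges)
        return cls(g)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((a, b)) for a, b in self._graph.edges)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, protein: str) -> bool:
        return protein in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def neighbors(self, protein: str) -> frozenset[str]:
        if protein not in self._graph:
            raise UnknownProteinError(protein)
        return frozenset(q for q in self._graph.neighbors(protein) if q != protein)

    def degree(self, protein: str) -> int:
        return len(self.neighbors(protein))

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self._graph.copy())

    def to_graph(self) -> nx.Graph:
        """The underlying networkx graph (shared, not copied)."""
        return self._graph


class AnnotationMap(Mapping[str, frozenset[str]]):
    """Mapping protein id -> set of directly annotated term ids (F(p))."""

    def __init__(self, annotations: Mapping[str, Iterable[str]]) -> None:
        self._data: dict[str, frozenset[str]] = {
            p: frozenset(ts) for p, ts in annotations.items()
        }

    def __getitem__(self, protein: str) -> frozenset[str]:
        return self._data[protein]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def get_terms(self, protein: str) -> frozenset[str]:
        """F(p), or the empty set for an unannotated protein."""
        return self._data.get(protein, frozenset())

    def without(self, proteins: Iterable[str]) -> "AnnotationMap":
        """Copy with the given proteins' annotations hidden (removed)."""
        hide = set(proteins)
        return AnnotationMap(
            {p: ts for p, ts in self._data.items() if p not in hide}
        )

    def restricted_to(self, ontology: Ontology) -> "AnnotationMap":
        """Drop terms unknown to the ontology; canonicalise alt ids;
        drop proteins left with an empty set."""
        out: dict[str, set[str]] = {}
        for p, ts in self._data.items():
            kept = {ontology.canonical_id(t) for t in ts if t in ontology}
            if kept:
                out[p] = kept
        return AnnotationMap(out)


def read_edge_list(path) -> InteractionNetwork:
    """Read a two-column TSV/whitespace edge list.

    An optional header line is auto-detected by its column names.
    Orientation and duplicates collapse (the graph is simple and
    undirected); self-loops are retained here and removed by
    :func:`preprocess`.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (
                a.lower() in _HEADER_TOKENS or b.lower() in _HEADER_TOKENS
            ):
                continue
            if not a or not b:
                raise NetworkFormatError(f"{path}:{lineno}: empty identifier")
            g.add_edge(a, b)
    return InteractionNetwork(g)


def read_annotations_tsv(
    path, ontology: Ontology | None = None
) -> AnnotationMap:
    """Read a simple two-column protein<TAB>term annotation file.

    Multiple rows per protein accumulate.  If an ontology is given, terms
    are canonicalised and restricted to it.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(fields)}"
                )
            protein, term = fields[0].strip(), fields[1].strip()
            if lineno == 1 and protein.lower() in {"protein", "gene", "id"}:
                continue
            out.setdefault(protein, set()).add(term)
    amap = AnnotationMap(out)
    if ontology is not None:
        amap = amap.restricted_to(ontology)
    return amap


_BIOGRID_COLUMNS = {
    "systematic": (
        "Systematic Name Interactor A",
        "Systematic Name Interactor B",
    ),
    "official": (
        "Official Symbol Interactor A",
        "Official Symbol Interactor B",
    ),
}


def read_biogrid_tab(
    path,
    id_column_policy: str = "systematic",
    experimental_system: str | None = None,
) -> InteractionNetwork:
    """Read a BioGRID tab-delimited (TAB2-style) export.

    ``id_column_policy`` selects systematic-name or official-symbol
    columns.  If ``experimental_system`` is given, only rows whose
    "Experimental System" matches it (case-insensitively) contribute
    edges.  Rows with an empty or placeholder ("-") identifier are
    skipped with a warning.
    """
    try:
        col_a, col_b = _BIOGRID_COLUMNS[id_column_policy]
    except KeyError:
        raise ValueError(f"unknown id_column_policy {id_column_policy!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in (col_a, col_b) if c not in df.columns]
    if experimental_system is not None and "Experimental System" not in df.columns:
        missing.append("Experimental System")
    if missing:
        raise NetworkFormatError(
            f"{path}: missing required column(s) {missing}"
        )
    if experimental_system is not None:
        mask = (
            df["Experimental System"].str.strip().str.lower()
            == experimental_system.strip().lower()
        )
        df = df[mask]
    g = nx.Graph()
    skipped = 0
    for a, b in zip(df[col_a], df[col_b]):
        a = (a or "").strip() if isinstance(a, str) else ""
        b = (b or "").strip() if isinstance(b, str) else ""
        if not a or not b or a == "-" or b == "-":
            skipped += 1
            continue
        g.add_edge(a, b)
    if skipped:
        logger.warning(
            "%s: skipped %d row(s) with empty interactor identifiers",
            path, skipped,
        )
    return InteractionNetwork(g)


def read_gaf(path, ontology: Ontology) -> AnnotationMap:
    """Read a GAF 2.x association file into an :class:`AnnotationMap`.

    Proteins are keyed by DB object symbol.  Rows with a NOT qualifier
    are excluded, term ids are canonicalised through the ontology's alt-id
    table, and terms outside the ontology's namespace are dropped.
    """
    _validate_gaf_lines(path)
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            if any(q.upper() == "NOT" for q in rec.get("Qualifier", ())):
                continue
            term = rec["GO_ID"]
            if term not in ontology:
                continue
            symbol = rec["DB_Object_Symbol"]
            out.setdefault(symbol, set()).add(ontology.canonical_id(term))
    return AnnotationMap(out)


def _validate_gaf_lines(path) -> None:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            n_fields = len(line.split("\t"))
            if n_fields < 15:
                raise NetworkFormatError(
                    f"{path}:{lineno}: GAF line has {n_fields} fields, "
                    f"expected at least 15"
                )


def preprocess(
    network: InteractionNetwork, annotations: AnnotationMap
) -> tuple[InteractionNetwork, AnnotationMap]:
    """Apply the standard cleaning filters; inputs are left unmodified.

    Removes self-interactions and proteins without any annotation (with
    their incident edges).  Duplicate edges cannot exist in the simple
    undirected representation.  Annotated proteins left without edges are
    retained.  Annotations for proteins absent from the network are kept
    untouched in the returned map.
    """
    g = nx.Graph()
    annotated = set(annotations)
    g.add_nodes_from(p for p in network.proteins if p in annotated)
    for edge in network.edges:
        pair = tuple(edge)
        if len(pair) == 1:  # self-loop
            continue
        a, b = pair
        if a in annotated and b in annotated:
            g.add_edge(a, b)
    clean_net = InteractionNetwork(g)
    clean_ann = AnnotationMap({p: ts for p, ts in annotations.items() if ts})
    return clean_net, clean_ann


def neighbors(network: InteractionNetwork, p: str) -> frozenset[str]:
    """Direct interaction partners of ``p`` (never contains ``p``)."""
    return network.neighbors(p)


def candidate_functions(
    network: InteractionNetwork, annotations: AnnotationMap, p: str
) -> frozenset[str]:
    """FN(p): the union of the annotation sets of p's direct neighbours."""
    out: set[str] = set()
    for q in network.neighbors(p):
        out |= annotations.get_terms(q)
    return frozenset(out)
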