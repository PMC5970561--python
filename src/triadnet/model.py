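"""Core domain types: gene nodes, evidence-typed edges and the integrated multigraph.

A gene–gene association network here is an undirected multigraph whose
parallel edges are distinguished by *evidence type*: co-expression
(``CoEx``), yeast two-hybrid protein interaction (``Y2H``) or literature
text-mining (``EVEX``).  At most one edge of each type may connect a given
gene pair, so an edge is keyed by ``(unordered pair, data type)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "DataType",
    "AnnotationStatus",
    "GeneNode",
    "EvexAttrs",
    "EvidenceEdge",
    "FamilyRecord",
    "TriadMotif",
    "IntegratedNetwork",
    "classify_annotation_status",
]


class DataType(str, Enum):
    """Evidence type of an association edge."""

    COEX = "CoEx"
    Y2H = "Y2H"
    EVEX = "EVEX"

    @classmethod
    def parse(cls, text: str) -> "DataType":
        t = text.strip().lower()
        for member in cls:
            if member.value.lower() == t:
                return member
        raise ValueError(f"unknown data type {text!r}")


class AnnotationStatus(str, Enum):
    ANNOTATED = "annotated"
    HYPOTHETICAL = "hypothetical"
    UNKNOWN = "unknown"
    UNANNOTATED = "unannotated"


_HYPOTHETICAL_RE = re.compile(r"\bhypothetical\b", re.IGNORECASE)
_UNKNOWN_RE = re.compile(r"\bunknown\b", re.IGNORECASE)


def classify_annotation_status(description: Optional[str]) -> AnnotationStatus:
    """Classify a free-text gene annotation.

    Empty or missing descriptions are *unannotated*.  Descriptions
    containing the word ``hypothetical`` (e.g. "hypothetical protein
    (FeS assembly protein)") are *hypothetical*; ones containing
    ``unknown`` are *unknown*; anything else counts as a meaningful
    annotation.  Matching is token-based and case-insensitive because
    source annotations embed the keywords in longer phrases.
    """
    if description is None or not description.strip():
        return AnnotationStatus.UNANNOTATED
    if _HYPOTHETICAL_RE.search(description):
        return AnnotationStatus.HYPOTHETICAL
    if _UNKNOWN_RE.search(description):
        return AnnotationStatus.UNKNOWN
    return AnnotationStatus.ANNOTATED


@dataclass
class GeneNode:
    """A gene/locus with identifiers, annotation and family membership.

    ``gene_id`` (the locus tag, e.g. ``slr1843``) is the primary key used
    to join all evidence sources.
    """

    gene_id: str
    entrez_id: Optional[int] = None
    symbol: Optional[str] = None
    synonyms: tuple[str, ...] = ()
    description: Optional[str] = None
    family_id: Optional[str] = None
    family_description: Optional[str] = None
    annotation_status: Optional[AnnotationStatus] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        self.synonyms = tuple(self.synonyms)
        if self.annotation_status is None:
            self.annotation_status = classify_annotation_status(self.description)

    def merged_with(self, other: "GeneNode") -> tuple["GeneNode", list[str]]:
        """First-non-empty field merge; returns merged node and conflict notes."""
        if other.gene_id != self.gene_id:
            raise ValueError("cannot merge nodes with different gene_ids")
        conflicts: list[str] = []
        kwargs = {}
        for name in ("entrez_id", "symbol", "description", "family_id", "family_description"):
            mine, theirs = getattr(self, name), getattr(other, name)
            if mine in (None, "") and theirs not in (None, ""):
                kwargs[name] = theirs
            elif mine not in (None, "") and theirs not in (None, "") and mine != theirs:
                conflicts.append(f"{self.gene_id}.{name}: kept {mine!r}, dropped {theirs!r}")
        merged = replace(self, **kwargs) if kwargs else replace(self)
        merged.synonyms = tuple(dict.fromkeys((*self.synonyms, *other.synonyms)))
        if "description" in kwargs:
            merged.annotation_status = classify_annotation_status(merged.description)
        return merged, conflicts


#: ordered set of recognised text-mining event categories
EVENT_TYPES = ("binding", "regulation", "indirect_regulation")
POLARITIES = ("positive", "negative", "unspecified")


@dataclass
class EvexAttrs:
    """Attributes of a text-mining (EVEX-style) association edge."""

    event_types: frozenset[str] = frozenset({"regulation"})
    polarity: str = "unspecified"
    speculation: bool = False
    negation: bool = False
    confidence: float = 0.0
    source_organisms: tuple[int, ...] = ()
    taxonomic_distance: Optional[int] = None
    article_ids: tuple[str, ...] = ()
    is_self_species: bool = False

    def __post_init__(self) -> None:
        self.event_types = frozenset(self.event_types)
        bad = self.event_types - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event type(s) {sorted(bad)}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        self.source_organisms = tuple(self.source_organisms)
        self.article_ids = tuple(self.article_ids)
        if self.taxonomic_distance is not None and self.taxonomic_distance < 0:
            raise ValueError("taxonomic_distance must be non-negative")


@dataclass
class EvidenceEdge:
    """One undirected association between two genes, tagged with one evidence type.

    The pair is order-invariant: ``EvidenceEdge("a", "b", ...)`` and
    ``EvidenceEdge("b", "a", ...)`` denote the same edge.
    """

    gene_a: str
    gene_b: str
    data_type: DataType
    pearson_r: Optional[float] = None
    evex: Optional[EvexAttrs] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a!r} not allowed")
        self.data_type = DataType(self.data_type)
        if self.data_type is DataType.COEX:
            if self.pearson_r is None:
                raise ValueError("CoEx edge requires pearson_r")
            # NaN marks an unknown correlation (e.g. bare SIF input)
            if self.pearson_r == self.pearson_r and not -1.0000001 <= self.pearson_r <= 1.0000001:
                raise ValueError(f"pearson_r {self.pearson_r} outside [-1, 1]")
        if self.data_type is DataType.EVEX and self.evex is None:
            raise ValueError("EVEX edge requires evex attributes")

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (sorted) endpoint pair."""
        a, b = self.gene_a, self.gene_b
        return (a, b) if a <= b else (b, a)

    @property
    def key(self) -> tuple[tuple[str, str], DataType]:
        return (self.pair, self.data_type)

    def other(self, gene_id: str) -> str:
        if gene_id == self.gene_a:
            return self.gene_b
        if gene_id == self.gene_b:
            return self.gene_a
        raise KeyError(gene_id)

    def touches(self, a: str, b: str) -> bool:
        return self.pair == ((a, b) if a <= b else (b, a))


@dataclass
class FamilyRecord:
    """A gene family with member descriptions and a derived canonical description.

    ``canonical_description`` is the representative surface form of the
    majority canonical form of the member descriptions; it is computed
    deterministically by :func:`triadnet.textmining.canonicalize`.
    """

    family_id: str
    member_descriptions: tuple[str, ...] = ()
    canonical_description: Optional[str] = None

    def __post_init__(self) -> None:
        self.member_descriptions = tuple(self.member_descriptions)
        if self.canonical_description is None and self.member_descriptions:
            from .textmining import canonicalize

            _, rep = canonicalize(list(self.member_descriptions))
            self.canonical_description = rep


@dataclass
class TriadMotif:
    """Three genes pairwise connected by three edges of >=2 evidence types.

    ``roles`` maps each gene id to ``key``/``candidate``/``context`` (the
    candidate-gene filter) or ``functional``/``hypothetical``/``context``
    (the hypothetical-protein filter).  ``rank`` is attached by the filters.
    """

    nodes: tuple[str, str, str]
    edges: tuple[EvidenceEdge, EvidenceEdge, EvidenceEdge]
    roles: dict = field(default_factory=dict)
    rank: Optional["RankTuple"] = None  # noqa: F821 - defined in motifs

    def __post_init__(self) -> None:
        self.nodes = tuple(sorted(self.nodes))
        if len(set(self.nodes)) != 3:
            raise ValueError("motif needs 3 distinct nodes")
        pairs = {e.pair for e in self.edges}
        expected = {
            tuple(sorted((self.nodes[i], self.nodes[j])))
            for i, j in ((0, 1), (0, 2), (1, 2))
        }
        if pairs != expected:
            raise ValueError("motif edges do not form a triangle over its nodes")
        # store edges in canonical pair order for deterministic identity
        self.edges = tuple(sorted(self.edges, key=lambda e: (e.pair, e.data_type.value)))

    @property
    def identity(self) -> tuple:
        """Hashable identity: node triple + (pair, type) of each edge."""
        return (self.nodes, tuple((e.pair, e.data_type) for e in self.edges))

    @property
    def data_types(self) -> frozenset[DataType]:
        return frozenset(e.data_type for e in self.edges)


class IntegratedNetwork:
    """Undirected multigraph of genes with evidence-typed parallel edges.

    Backed by a :class:`networkx.MultiGraph` whose edge keys are the
    evidence-type labels, which enforces the one-edge-per-(pair, type)
    invariant structurally.
    """

    def __init__(self, provenance: Optional[Iterable[str]] = None) -> None:
        self._g = nx.MultiGraph()
        self.provenance: list[str] = list(provenance or [])

    # -- nodes ---------------------------------------------------------
    def add_gene(self, node: GeneNode, merge: bool = True) -> None:
        if node.gene_id in self._g:
            if not merge:
                raise ValueError(f"duplicate gene {node.gene_id!r}")
            existing: GeneNode = self._g.nodes[node.gene_id]["data"]
            merged, _ = existing.merged_with(node)
            self._g.nodes[node.gene_id]["data"] = merged
        else:
            self._g.add_node(node.gene_id, data=node)

    def ensure_gene(self, gene_id: str) -> GeneNode:
        if gene_id not in self._g:
            self._g.add_node(gene_id, data=GeneNode(gene_id))
        return self._g.nodes[gene_id]["data"]

    def gene(self, gene_id: str) -> GeneNode:
        return self._g.nodes[gene_id]["data"]

    def set_gene(self, node: GeneNode) -> None:
        """Replace the stored record for an existing gene."""
        if node.gene_id not in self._g:
            raise KeyError(node.gene_id)
        self._g.nodes[node.gene_id]["data"] = node

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._g

    def genes(self) -> Iterator[GeneNode]:
        for gid in sorted(self._g.nodes):
            yield self._g.nodes[gid]["data"]

    def gene_ids(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    # -- edges ---------------------------------------------------------
    def add_edge(self, edge: EvidenceEdge, on_duplicate: str = "error") -> None:
        """Insert an edge; endpoints are created as bare genes if absent.

        ``on_duplicate`` is one of ``error``/``replace``/``skip``.
        """
        self.ensure_gene(edge.gene_a)
        self.ensure_gene(edge.gene_b)
        a, b = edge.pair
        key = edge.data_type.value
        if self._g.has_edge(a, b, key=key):
            if on_duplicate == "error":
                raise ValueError(f"duplicate edge ({a}, {b}, {key})")
            if on_duplicate == "skip":
                return
        self._g.add_edge(a, b, key=key, data=edge)

    def get_edge(self, a: str, b: str, data_type: DataType) -> Optional[EvidenceEdge]:
        d = self._g.get_edge_data(a, b, key=DataType(data_type).value)
        return None if d is None else d["data"]

    def edges_between(self, a: str, b: str) -> list[EvidenceEdge]:
        d = self._g.get_edge_data(a, b)
        if not d:
            return []
        return sorted((v["data"] for v in d.values()), key=lambda e: e.data_type.value)

    def has_any_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def remove_edge(self, a: str, b: str, data_type: DataType) -> None:
        self._g.remove_edge(a, b, key=DataType(data_type).value)

    def edges(self) -> Iterator[EvidenceEdge]:
        seen = []
        for a, b, d in self._g.edges(data="data"):
            seen.append(d)
        yield from sorted(seen, key=lambda e: (e.pair, e.data_type.value))

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, gene_id: str) -> list[str]:
        return sorted(self._g.neighbors(gene_id))

    def degree_by_type(self, gene_id: str) -> dict[DataType, int]:
        counts: dict[DataType, int] = {t: 0 for t in DataType}
        for _, _, k in self._g.edges(gene_id, keys=True):
            counts[DataType(k)] += 1
        return counts

    # -- whole-network helpers ----------------------------------------
    def copy(self) -> "IntegratedNetwork":
        out = IntegratedNetwork(provenance=self.provenance)
        out._g = self._g.copy()
        return out

    def induced_subnetwork(self, gene_ids: Iterable[str]) -> "IntegratedNetwork":
        keep = set(gene_ids)
        out = IntegratedNetwork(provenance=self.provenance)
        for gid in sorted(keep):
            out.add_gene(self.gene(gid))
        for e in self.edges():
            if e.gene_a in keep and e.gene_b in keep:
                out.add_edge(e)
        return out

    def node_attr_dict(self) -> dict[str, GeneNode]:
        return {gid: self._g.nodes[gid]["data"] for gid in self._g.nodes}

    def edge_key_set(self) -> set[tuple[tuple[str, str], DataType]]:
        return {e.key for e in self.edges()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntegratedNetwork):
            return NotImplemented
        return (
            self.node_attr_dict() == other.node_attr_dict()
            and {e.key: _edge_payload(e) for e in self.edges()}
            == {e.key: _edge_payload(e) for e in other.edges()}
        )

    def __repr__(self) -> str:
        return f"IntegratedNetwork(nodes={self.n_nodes}, edges={self.n_edges})"


def _edge_payload(e: EvidenceEdge) -> tuple:
    ev = e.evex
    ev_t = None
    if ev is not None:
        ev_t = (
            tuple(sorted(ev.event_types)),
            ev.polarity,
            ev.speculation,
            ev.negation,
            round(ev.confidence, 6),
            tuple(sorted(ev.source_organisms)),
            ev.taxonomic_distance,
            tuple(sorted(ev.article_ids)),
            ev.is_self_species,
        )
    r = None if e.pearson_r is None or e.pearson_r != e.pearson_r else round(e.pearson_r, 6)
    return (r, ev_t, tuple(sorted(e.meta.items())))
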