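"""Text-mining event ingestion, family mapping and annotation handling.

Events extracted from the literature connect *gene families* rather than
genes of the target species: an event between families A and B is
projected onto every pair of target-species genes (a, b) with a in A and
b in B.  Events landing on the same gene pair merge into a single EVEX
edge that aggregates article ids, source organisms and the maximum
confidence.  An edge is *self-species* when at least one contributing
article studied the target organism itself — those associations are
"already known" and are treated specially by the motif filters.

Family descriptions are pooled by *canonicalization*: lowercase every
member description, strip all non-alphanumeric characters, and pick the
canonical form shared by the most members; its most frequent original
surface form becomes the family description used to annotate genes that
lack one.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import (
    EVENT_TYPES,
    POLARITIES,
    AnnotationStatus,
    DataType,
    EvexAttrs,
    EvidenceEdge,
    FamilyRecord,
    GeneNode,
    IntegratedNetwork,
    classify_annotation_status,
)

__all__ = [
    "EventRecord",
    "FamilyMap",
    "EvexRejects",
    "build_evex_network",
    "canonicalize",
    "canonical_form",
    "enrich_annotations",
    "EnrichmentReport",
    "compare_annotations",
    "read_event_table",
    "read_family_map",
    "read_family_records",
    "taxonomic_distance",
]

log = logging.getLogger(__name__)

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


@dataclass
class EventRecord:
    """One machine-extracted association between two genes or gene families."""

    subject: str
    object: str
    event_type: str = "regulation"
    polarity: str = "unspecified"
    speculation: bool = False
    negation: bool = False
    confidence: float = 0.0
    organism_taxa: tuple[int, ...] = ()
    article_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        self.organism_taxa = tuple(self.organism_taxa)
        self.article_ids = tuple(self.article_ids)
        if not (self.confidence == self.confidence and abs(self.confidence) != float("inf")):
            raise ValueError("confidence must be finite")


@dataclass
class FamilyMap:
    """Bidirectional family <-> target-species gene membership map."""

    family_to_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.family_to_genes = {f: tuple(gs) for f, gs in self.family_to_genes.items()}
        self.gene_to_family: dict[str, str] = {}
        for fam, genes in self.family_to_genes.items():
            for g in genes:
                if g in self.gene_to_family and self.gene_to_family[g] != fam:
                    raise ValueError(f"gene {g!r} assigned to two families")
                self.gene_to_family[g] = fam

    def members(self, identifier: str) -> tuple[str, ...]:
        """Target-species genes referred to by a family id or a bare gene id."""
        if identifier in self.family_to_genes:
            return self.family_to_genes[identifier]
        if identifier in self.gene_to_family:
            return (identifier,)
        return ()


@dataclass
class EvexRejects:
    """Events skipped during network construction, with reasons."""

    unknown_identifier: list[EventRecord] = field(default_factory=list)
    self_event: list[EventRecord] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.unknown_identifier) + len(self.self_event)


def taxonomic_distance(parent_of: dict[int, int], a: int, b: int) -> Optional[int]:
    """Hop count from a to b via their nearest common ancestor, or None."""
    if a == b:
        return 0
    anc_a = {a: 0}
    node, d = a, 0
    while node in parent_of:
        node = parent_of[node]
        d += 1
        if node in anc_a:
            break
        anc_a[node] = d
    node, d = b, 0
    while True:
        if node in anc_a:
            return anc_a[node] + d
        if node not in parent_of:
            return None
        node = parent_of[node]
        d += 1


def build_evex_network(
    events: Iterable[EventRecord],
    fam: FamilyMap,
    target_taxon: int,
    taxonomy: Optional[dict[int, int]] = None,
) -> tuple[IntegratedNetwork, EvexRejects]:
    """Project family-level events onto target-species gene pairs.

    Every (subject-member, object-member) gene pair gets one EVEX edge;
    events hitting an existing pair merge into it (union of articles,
    organisms and event types; max confidence; a flag survives merging
    only if every contributing event carries it).  ``is_self_species``
    is set when any contributing event's organism list includes
    ``target_taxon``.  Events whose subject or object maps to no known
    family or gene are skipped and reported.
    """
    rejects = EvexRejects()
    merged: dict[tuple[str, str], list[EventRecord]] = {}
    for ev in events:
        genes_a = fam.members(ev.subject)
        genes_b = fam.members(ev.object)
        if not genes_a or not genes_b:
            log.warning("event %s--%s references unknown family/gene; skipped", ev.subject, ev.object)
            rejects.unknown_identifier.append(ev)
            continue
        hit = False
        for ga in genes_a:
            for gb in genes_b:
                if ga == gb:
                    continue  # within-family self-event on one gene
                hit = True
                merged.setdefault(tuple(sorted((ga, gb))), []).append(ev)
        if not hit:
            rejects.self_event.append(ev)

    net = IntegratedNetwork(provenance=["evex"])
    for (a, b), evs in sorted(merged.items()):
        best = max(evs, key=lambda e: e.confidence)
        organisms = sorted({t for e in evs for t in e.organism_taxa})
        dist = None
        if taxonomy is not None and organisms:
            dists = [taxonomic_distance(taxonomy, t, target_taxon) for t in organisms]
            dists = [d for d in dists if d is not None]
            dist = min(dists) if dists else None
        attrs = EvexAttrs(
            event_types=frozenset(e.event_type for e in evs),
            polarity=best.polarity,
            speculation=all(e.speculation for e in evs),
            negation=all(e.negation for e in evs),
            confidence=max(e.confidence for e in evs),
            source_organisms=tuple(organisms),
            taxonomic_distance=dist,
            article_ids=tuple(sorted({p for e in evs for p in e.article_ids})),
            is_self_species=any(target_taxon in e.organism_taxa for e in evs),
        )
        net.add_edge(EvidenceEdge(a, b, DataType.EVEX, evex=attrs))
    return net, rejects


def canonical_form(description: str) -> str:
    """Lowercase and strip every non-alphanumeric character."""
    return _NON_ALNUM.sub("", description.lower())


def canonicalize(descriptions: Sequence[str]) -> tuple[str, str]:
    """Pick the majority canonical form and its representative surface form.

    Returns ``(canonical, representative)`` where *canonical* is the
    normalized form shared by the most descriptions and *representative*
    the most frequent original spelling among the winners.  Ties are
    broken deterministically: lexicographically smallest canonical form;
    shortest-then-lexicographic representative.
    """
    forms = [(canonical_form(d), d) for d in descriptions if d and d.strip()]
    forms = [(c, d) for c, d in forms if c]
    if not forms:
        raise ValueError("no non-empty descriptions to canonicalize")
    counts = Counter(c for c, _ in forms)
    top = max(counts.values())
    canonical = min(c for c, n in counts.items() if n == top)
    surface = Counter(d for c, d in forms if c == canonical)
    top_s = max(surface.values())
    representative = min((d for d, n in surface.items() if n == top_s), key=lambda d: (len(d), d))
    return canonical, representative


@dataclass
class EnrichmentReport:
    """Annotation coverage before/after family-description transfer."""

    n_nodes: int
    newly_annotated: int
    coverage_before: float
    coverage_after: float
    newly_annotated_genes: tuple[str, ...] = ()

    @property
    def coverage_gain(self) -> float:
        return self.coverage_after - self.coverage_before


def _is_meaningful(node: GeneNode) -> bool:
    return (
        node.annotation_status is AnnotationStatus.ANNOTATED
        or bool(node.family_description)
    )


def enrich_annotations(
    net: IntegratedNetwork, fams: Sequence[FamilyRecord]
) -> tuple[IntegratedNetwork, EnrichmentReport]:
    """Fill hypothetical/unknown/unannotated genes with family descriptions.

    Genes keeping a meaningful annotation are never overwritten.  The
    returned network is a copy; the report gives the coverage (fraction
    of genes with a meaningful annotation) before and after.
    """
    by_family = {f.family_id: f for f in fams}
    out = net.copy()
    n = out.n_nodes
    before = sum(_is_meaningful(g) for g in out.genes())
    gained: list[str] = []
    for node in list(out.genes()):
        if node.annotation_status is AnnotationStatus.ANNOTATED:
            continue
        if node.family_description:
            continue
        fam = by_family.get(node.family_id) if node.family_id else None
        if fam is None or not fam.canonical_description:
            continue
        node = GeneNode(
            gene_id=node.gene_id,
            entrez_id=node.entrez_id,
            symbol=node.symbol,
            synonyms=node.synonyms,
            description=node.description,
            family_id=node.family_id,
            family_description=fam.canonical_description,
            annotation_status=node.annotation_status,
        )
        out.set_gene(node)
        gained.append(node.gene_id)
    after = sum(_is_meaningful(g) for g in out.genes())
    report = EnrichmentReport(
        n_nodes=n,
        newly_annotated=len(gained),
        coverage_before=before / n if n else 0.0,
        coverage_after=after / n if n else 0.0,
        newly_annotated_genes=tuple(gained),
    )
    return out, report


def compare_annotations(a: str, b: str) -> str:
    """Compare two annotations: ``identical``, ``substring`` or ``other``.

    Identity is up to surrounding whitespace and case; the substring
    test runs on canonical forms so punctuation and spacing differences
    do not mask containment.
    """
    if not a or not b:
        raise ValueError("both annotations must be non-empty")
    if a.strip().casefold() == b.strip().casefold():
        return "identical"
    ca, cb = canonical_form(a), canonical_form(b)
    if ca and cb and (ca in cb or cb in ca):
        return "substring"
    return "other"


# ------------------------------------------------------------- file I/O

_TRUE = ("true", "1", "yes")


def read_event_table(path: Union[str, Path]) -> list[EventRecord]:
    """Read a headered event TSV (lists pipe-delimited).

    Expected columns: subject_family, object_family, event_type,
    polarity, speculation, negation, confidence, taxa, article_ids.
    """
    path = Path(path)
    out: list[EventRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return out
    header = lines[0].split("\t")
    idx = {h: i for i, h in enumerate(header)}
    required = ("subject_family", "object_family")
    for col in required:
        if col not in idx:
            raise ValueError(f"{path}: missing column {col!r}")

    def get(cells: list[str], col: str, default: str = "") -> str:
        i = idx.get(col)
        return cells[i] if i is not None and i < len(cells) else default

    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        try:
            out.append(
                EventRecord(
                    subject=get(cells, "subject_family"),
                    object=get(cells, "object_family"),
                    event_type=get(cells, "event_type") or "regulation",
                    polarity=get(cells, "polarity") or "unspecified",
                    speculation=get(cells, "speculation").lower() in _TRUE,
                    negation=get(cells, "negation").lower() in _TRUE,
                    confidence=float(get(cells, "confidence") or 0.0),
                    organism_taxa=tuple(
                        int(t) for t in get(cells, "taxa").split("|") if t.strip()
                    ),
                    article_ids=tuple(
                        p for p in get(cells, "article_ids").split("|") if p.strip()
                    ),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from exc
    return out


def read_family_map(path: Union[str, Path]) -> FamilyMap:
    """Read a gene-to-family TSV with columns gene_id, family_id."""
    fam_to_genes: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 1 if lines and lines[0].lower().startswith("gene_id") else 0
    for line in lines[start:]:
        if not line.strip():
            continue
        gene, fam = line.split("\t")[:2]
        fam_to_genes.setdefault(fam.strip(), []).append(gene.strip())
    return FamilyMap({f: tuple(gs) for f, gs in fam_to_genes.items()})


def read_family_records(path: Union[str, Path]) -> list[FamilyRecord]:
    """Read member descriptions (columns family_id, description; one row per member)."""
    members: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 1 if lines and lines[0].lower().startswith("family_id") else 0
    for line in lines[start:]:
        if not line.strip():
            continue
        fam, desc = line.split("\t")[:2]
        members.setdefault(fam.strip(), []).append(desc.strip())
    return [FamilyRecord(f, tuple(ds)) for f, ds in sorted(members.items())]
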