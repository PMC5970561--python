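"""Triad-motif enumeration and the rule-based candidate filters.

A *triad motif* is three genes pairwise connected by three edges.  Two
rule-based filters mine them from the integrated network:

* the **candidate-gene (CG) filter** anchors motifs at user-declared
  *key genes* and nominates the non-key members as candidates, keeping
  a motif only if (i) its three edges span at least two distinct
  evidence types and (ii) no text-mining edge from a study of the
  target species itself links a key gene to a candidate anywhere in the
  network — such a pair is already known and carries no novelty;

* the **hypothetical-protein (HP) filter** is the same machinery with
  the roles swapped: the anchor is an unannotated/hypothetical *entry
  gene*, at least one motif member must carry a real annotation
  (the source of the role hypothesis), and rule (ii) guards the
  entry–annotated pairs.

Accepted motifs are ranked by a lexicographic tuple: first the sorted
per-edge evidence ranks (self-species text-mining best, then foreign
text-mining, co-expression, yeast two-hybrid), then three tie-breaking
counts of additional support (extra key-gene links of the candidate,
indirect two-step support, extra parallel edges inside the motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .model import (
    AnnotationStatus,
    DataType,
    EvidenceEdge,
    IntegratedNetwork,
    TriadMotif,
)

__all__ = [
    "RankTuple",
    "edge_rank",
    "enumerate_triangles",
    "rank_motif",
    "filter_candidates",
    "filter_hypotheticals",
    "motif_table",
    "candidate_table",
    "hypothesis_table",
    "motifs_to_network",
]

#: evidence ranks: self-species EVEX (1) beats foreign EVEX (2), CoEx (3), Y2H (4)
_TYPE_RANK = {DataType.COEX: 3, DataType.Y2H: 4}

UNANNOTATED_STATUSES = (
    AnnotationStatus.HYPOTHETICAL,
    AnnotationStatus.UNKNOWN,
    AnnotationStatus.UNANNOTATED,
)


def edge_rank(edge: EvidenceEdge) -> int:
    """Evidence rank of one edge (smaller is stronger support)."""
    if edge.data_type is DataType.EVEX:
        return 1 if edge.evex.is_self_species else 2
    return _TYPE_RANK[edge.data_type]


@dataclass(frozen=True)
class RankTuple:
    """Total order on motifs: edge ranks first, then support counts.

    ``edge_rank_profile`` compares elementwise (smaller better); the
    three counts compare larger-better, in the order extra key links,
    indirect support, extra in-motif parallel edges.
    """

    edge_rank_profile: tuple[int, int, int]
    extra_key_links: int = 0
    indirect_support: int = 0
    extra_pattern_links: int = 0

    @property
    def sort_key(self) -> tuple:
        return (
            self.edge_rank_profile,
            -self.extra_key_links,
            -self.indirect_support,
            -self.extra_pattern_links,
        )

    def __lt__(self, other: "RankTuple") -> bool:
        return self.sort_key < other.sort_key

    def __le__(self, other: "RankTuple") -> bool:
        return self.sort_key <= other.sort_key


EdgeFilter = Callable[[EvidenceEdge], bool]


def _usable(edge_filter: Optional[EdgeFilter]) -> EdgeFilter:
    return edge_filter if edge_filter is not None else (lambda e: True)


def enumerate_triangles(
    net: IntegratedNetwork,
    anchors: Sequence[str],
    edge_filter: Optional[EdgeFilter] = None,
) -> list[TriadMotif]:
    """All triad motifs containing at least one anchor gene.

    A node triple whose three pairs are each connected yields one motif
    per combination of parallel-edge choices; each motif is emitted
    once, in canonical (sorted node triple) order.  ``edge_filter``
    restricts which edges may serve as motif sides.
    """
    if not anchors:
        raise ValueError("anchor list is empty")
    ok = _usable(edge_filter)
    anchor_set = set(anchors)
    triples: set[tuple[str, str, str]] = set()
    for a in anchor_set:
        if a not in net:
            continue
        nbrs = [u for u in net.neighbors(a) if any(ok(e) for e in net.edges_between(a, u))]
        for u, v in combinations(nbrs, 2):
            if net.has_any_edge(u, v) and any(ok(e) for e in net.edges_between(u, v)):
                triples.add(tuple(sorted((a, u, v))))
    motifs: list[TriadMotif] = []
    for tri in sorted(triples):
        pairs = [(tri[0], tri[1]), (tri[0], tri[2]), (tri[1], tri[2])]
        choices = [[e for e in net.edges_between(x, y) if ok(e)] for x, y in pairs]
        for combo in product(*choices):
            motifs.append(TriadMotif(nodes=tri, edges=tuple(combo)))
    return motifs


def _has_self_species_evex(net: IntegratedNetwork, a: str, b: str) -> bool:
    e = net.get_edge(a, b, DataType.EVEX)
    return e is not None and e.evex.is_self_species


def rank_motif(
    motif: TriadMotif,
    net: IntegratedNetwork,
    key_genes: Sequence[str],
    candidates: Optional[Sequence[str]] = None,
) -> RankTuple:
    """Rank an accepted motif.

    ``candidates`` defaults to the motif members that are not key
    genes.  The three support counts are evaluated per candidate and
    the best (largest) value is kept, so a motif is ranked by its
    strongest candidate.
    """
    keys = set(key_genes)
    if candidates is None:
        candidates = [n for n in motif.nodes if n not in keys]
    profile = tuple(sorted(edge_rank(e) for e in motif.edges))
    motif_nodes = set(motif.nodes)

    extra_key_links = 0
    indirect = 0
    for cand in candidates:
        direct = sum(
            1
            for k in keys - motif_nodes
            if k in net and net.has_any_edge(cand, k)
        )
        extra_key_links = max(extra_key_links, direct)
        paths = 0
        if cand in net:
            for w in net.neighbors(cand):
                if w in motif_nodes:
                    continue
                paths += sum(1 for k in keys if k != cand and k in net and net.has_any_edge(w, k))
        indirect = max(indirect, paths)

    chosen = {(e.pair, e.data_type) for e in motif.edges}
    extra_links = 0
    for x, y in combinations(motif.nodes, 2):
        for e in net.edges_between(x, y):
            if (e.pair, e.data_type) not in chosen:
                extra_links += 1
    return RankTuple(profile, extra_key_links, indirect, extra_links)


def _default_edge_filter(allow_negated: bool) -> EdgeFilter:
    if allow_negated:
        return lambda e: True
    return lambda e: not (e.data_type is DataType.EVEX and e.evex.negation)


def _sorted_motifs(motifs: list[TriadMotif]) -> list[TriadMotif]:
    return sorted(motifs, key=lambda m: (m.rank.sort_key, m.nodes, m.identity))


def filter_candidates(
    net: IntegratedNetwork,
    key_genes: Sequence[str],
    allow_negated: bool = False,
) -> list[TriadMotif]:
    """Candidate-gene filter: ranked motifs nominating novel partners of key genes.

    Keeps a motif iff its three edges span >=2 evidence types and no
    key–candidate pair inside it is linked anywhere in the network by a
    self-species text-mining edge (the association would already be
    known).  Motifs whose members are all key genes nominate nothing
    and are dropped.  Negated text-mining edges are not used as motif
    sides unless ``allow_negated``.
    """
    if not key_genes:
        raise ValueError("key gene list is empty")
    missing = sorted(k for k in key_genes if k not in net)
    if missing:
        raise KeyError(f"key gene(s) not in network: {', '.join(missing)}")
    keys = set(key_genes)
    ok = _default_edge_filter(allow_negated)
    accepted: list[TriadMotif] = []
    for motif in enumerate_triangles(net, sorted(keys), edge_filter=ok):
        if len(motif.data_types) < 2:
            continue
        members_keys = [n for n in motif.nodes if n in keys]
        members_cand = [n for n in motif.nodes if n not in keys]
        if not members_cand:
            continue
        if any(
            _has_self_species_evex(net, k, c)
            for k in members_keys
            for c in members_cand
        ):
            continue
        motif.roles = {n: ("key" if n in keys else "candidate") for n in motif.nodes}
        motif.rank = rank_motif(motif, net, key_genes=sorted(keys), candidates=members_cand)
        accepted.append(motif)
    return _sorted_motifs(accepted)


def filter_hypotheticals(
    net: IntegratedNetwork,
    entry_genes: Optional[Sequence[str]] = None,
    allow_negated: bool = False,
) -> list[TriadMotif]:
    """Hypothetical-protein filter: infer roles for unannotated genes.

    For each entry gene (default: every gene whose annotation is
    hypothetical/unknown/absent), keeps triangles through it whose
    edges span >=2 evidence types, that contain at least one member
    with a real annotation, and where no self-species text-mining edge
    links the entry gene to an annotated member.  Roles:
    ``hypothetical`` (entry), ``functional`` (annotated members),
    ``context`` (the rest).
    """
    if entry_genes is None:
        entry_genes = [
            g.gene_id for g in net.genes() if g.annotation_status in UNANNOTATED_STATUSES
        ]
    else:
        missing = sorted(g for g in entry_genes if g not in net)
        if missing:
            raise KeyError(f"entry gene(s) not in network: {', '.join(missing)}")
    ok = _default_edge_filter(allow_negated)
    accepted: list[TriadMotif] = []
    seen: set[tuple] = set()
    for entry in sorted(set(entry_genes)):
        if entry not in net:
            continue
        for motif in enumerate_triangles(net, [entry], edge_filter=ok):
            if len(motif.data_types) < 2:
                continue
            annotated = [
                n
                for n in motif.nodes
                if n != entry and net.gene(n).annotation_status is AnnotationStatus.ANNOTATED
            ]
            if not annotated:
                continue
            if any(_has_self_species_evex(net, entry, m) for m in annotated):
                continue
            ident = (entry, motif.identity)
            if ident in seen:
                continue
            seen.add(ident)
            m = TriadMotif(nodes=motif.nodes, edges=motif.edges)
            m.roles = {
                n: (
                    "hypothetical"
                    if n == entry
                    else ("functional" if n in annotated else "context")
                )
                for n in m.nodes
            }
            m.rank = rank_motif(m, net, key_genes=annotated, candidates=[entry])
            accepted.append(m)
    return _sorted_motifs(accepted)


# ------------------------------------------------------------- reporting


def motif_table(motifs: Sequence[TriadMotif]) -> pd.DataFrame:
    """One row per motif: id, roles, edges as ``a-b:type`` and rank fields."""
    rows = []
    for i, m in enumerate(motifs):
        rows.append(
            {
                "motif_id": i,
                "nodes": "|".join(m.nodes),
                "roles": "|".join(f"{n}={m.roles.get(n, '?')}" for n in m.nodes),
                "edges": "|".join(
                    f"{e.pair[0]}-{e.pair[1]}:{e.data_type.value}" for e in m.edges
                ),
                "edge_rank_profile": ",".join(map(str, m.rank.edge_rank_profile)),
                "extra_key_links": m.rank.extra_key_links,
                "indirect_support": m.rank.indirect_support,
                "extra_pattern_links": m.rank.extra_pattern_links,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "nodes",
            "roles",
            "edges",
            "edge_rank_profile",
            "extra_key_links",
            "indirect_support",
            "extra_pattern_links",
        ],
    )


def candidate_table(motifs: Sequence[TriadMotif]) -> pd.DataFrame:
    """Deduplicated candidates with their best motif rank and motif count."""
    best: dict[str, RankTuple] = {}
    count: dict[str, int] = {}
    for m in motifs:
        for n, role in m.roles.items():
            if role not in ("candidate", "hypothetical"):
                continue
            count[n] = count.get(n, 0) + 1
            if n not in best or m.rank < best[n]:
                best[n] = m.rank
    rows = [
        {
            "candidate": n,
            "motif_count": count[n],
            "best_edge_rank_profile": ",".join(map(str, best[n].edge_rank_profile)),
            "best_extra_key_links": best[n].extra_key_links,
            "best_indirect_support": best[n].indirect_support,
            "best_extra_pattern_links": best[n].extra_pattern_links,
        }
        for n in sorted(count, key=lambda n: (best[n].sort_key, n))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "candidate",
            "motif_count",
            "best_edge_rank_profile",
            "best_extra_key_links",
            "best_indirect_support",
            "best_extra_pattern_links",
        ],
    )


def hypothesis_table(motifs: Sequence[TriadMotif], net: IntegratedNetwork) -> pd.DataFrame:
    """Entry gene -> annotated partners and their descriptions, best rank first."""
    rows = []
    seen = set()
    for m in motifs:
        entry = next((n for n, r in m.roles.items() if r == "hypothetical"), None)
        if entry is None:
            continue
        for n, role in m.roles.items():
            if role != "functional" or (entry, n) in seen:
                continue
            seen.add((entry, n))
            node = net.gene(n)
            rows.append(
                {
                    "entry_gene": entry,
                    "annotated_partner": n,
                    "partner_description": node.description or node.family_description or "",
                    "edge_rank_profile": ",".join(map(str, m.rank.edge_rank_profile)),
                }
            )
    return pd.DataFrame(
        rows, columns=["entry_gene", "annotated_partner", "partner_description", "edge_rank_profile"]
    )


def motifs_to_network(motifs: Sequence[TriadMotif], net: IntegratedNetwork) -> IntegratedNetwork:
    """Combined network of motifs: union of all motif nodes and chosen edges."""
    out = IntegratedNetwork(provenance=["motifs"])
    for m in motifs:
        for n in m.nodes:
            out.add_gene(net.gene(n))
        for e in m.edges:
            out.add_edge(e, on_duplicate="skip")
    return out
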