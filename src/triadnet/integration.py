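"""Network integration: merge evidence networks, keep sources independent.

Merging takes the union of nodes and of ``(pair, evidence-type)`` edge
keys across input networks, translating foreign identifiers to the
common locus-tag space first when a mapping is given.  To guarantee the
merged evidence really is independent, text-mining edges that cite only
the publication(s) behind an experimental input network ("circular
evidence") are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .model import DataType, EvexAttrs, EvidenceEdge, GeneNode, IntegratedNetwork

__all__ = [
    "MergeReport",
    "OverlapReport",
    "RemovalLog",
    "merge_networks",
    "exclude_circular_evidence",
    "overlap_stats",
    "gba_first_neighbors",
]

log = logging.getLogger(__name__)


@dataclass
class MergeReport:
    """Bookkeeping from a merge: attribute conflicts and unmappable ids."""

    attribute_conflicts: list[str] = field(default_factory=list)
    unmapped_ids: list[str] = field(default_factory=list)
    dropped_nodes: list[str] = field(default_factory=list)


def _remap_node(node: GeneNode, id_map: Mapping[str, str]) -> GeneNode:
    new_id = id_map.get(node.gene_id)
    return node if new_id is None else replace(node, gene_id=new_id)


def merge_networks(
    nets: Sequence[IntegratedNetwork],
    id_map: Optional[Mapping[str, str]] = None,
    strict: bool = False,
) -> tuple[IntegratedNetwork, MergeReport]:
    """Union-merge evidence networks into one integrated multigraph.

    Node attributes merge first-non-empty in input order; conflicting
    non-empty values are kept from the earlier network and logged.  Edge
    keys ``(pair, data_type)`` union; a key present in several inputs
    keeps its first occurrence.  ``id_map`` translates foreign node ids
    to the common gene-id space before the union; ids absent from a
    non-empty map are reported and, under ``strict``, dropped.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to merge")
    id_map = dict(id_map or {})
    report = MergeReport()
    merged = IntegratedNetwork()
    for net in nets:
        merged.provenance.extend(p for p in net.provenance if p not in merged.provenance)
        dropped: set[str] = set()
        for node in net.genes():
            mapped = _remap_node(node, id_map)
            if id_map and node.gene_id not in id_map:
                report.unmapped_ids.append(node.gene_id)
                if strict:
                    report.dropped_nodes.append(node.gene_id)
                    dropped.add(node.gene_id)
                    continue
            if mapped.gene_id in merged:
                new, conflicts = merged.gene(mapped.gene_id).merged_with(mapped)
                merged.set_gene(new)
                for c in conflicts:
                    log.warning("merge conflict: %s", c)
                report.attribute_conflicts.extend(conflicts)
            else:
                merged.add_gene(mapped)
        for edge in net.edges():
            if edge.gene_a in dropped or edge.gene_b in dropped:
                continue
            a = id_map.get(edge.gene_a, edge.gene_a)
            b = id_map.get(edge.gene_b, edge.gene_b)
            if (a, b) != (edge.gene_a, edge.gene_b):
                edge = replace(edge, gene_a=a, gene_b=b)
            merged.add_edge(edge, on_duplicate="skip")
    return merged, report


@dataclass
class RemovalLog:
    """Edges removed or stripped by circular-evidence exclusion."""

    removed: list[tuple[str, str]] = field(default_factory=list)
    stripped: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)


def exclude_circular_evidence(
    net: IntegratedNetwork, tainted_articles: Iterable[str]
) -> tuple[IntegratedNetwork, RemovalLog]:
    """Drop text-mining edges supported only by tainted publications.

    An EVEX edge whose article ids are all in ``tainted_articles`` —
    typically the paper that produced an experimental input network —
    is removed; an edge with at least one independent article survives
    with the tainted ids stripped.  Co-expression and Y2H edges are
    never touched.
    """
    tainted = set(tainted_articles)
    out = net.copy()
    logrec = RemovalLog()
    for edge in list(net.edges()):
        if edge.data_type is not DataType.EVEX:
            continue
        articles = set(edge.evex.article_ids)
        if not articles & tainted:
            continue
        keep = articles - tainted
        a, b = edge.pair
        if keep:
            new_attrs = replace(edge.evex, article_ids=tuple(sorted(keep)))
            out.remove_edge(a, b, DataType.EVEX)
            out.add_edge(replace(edge, evex=new_attrs))
            logrec.stripped.append((a, b, tuple(sorted(articles & tainted))))
        else:
            out.remove_edge(a, b, DataType.EVEX)
            logrec.removed.append((a, b))
    return out, logrec


@dataclass
class OverlapReport:
    """Venn-style distribution of genes across the source networks."""

    labels: tuple[str, ...]
    per_source: dict[str, int]
    nodes_in_exactly: dict[int, int]
    n_union: int

    @property
    def fraction_in_at_least_two(self) -> float:
        if not self.n_union:
            return 0.0
        return sum(v for k, v in self.nodes_in_exactly.items() if k >= 2) / self.n_union

    @property
    def fraction_in_all(self) -> float:
        if not self.n_union:
            return 0.0
        return self.nodes_in_exactly.get(len(self.labels), 0) / self.n_union

    def to_rows(self) -> list[dict]:
        rows = [{"metric": f"nodes_{lab}", "value": self.per_source[lab]} for lab in self.labels]
        for k in sorted(self.nodes_in_exactly):
            rows.append({"metric": f"nodes_in_exactly_{k}", "value": self.nodes_in_exactly[k]})
        rows.append({"metric": "nodes_union", "value": self.n_union})
        rows.append({"metric": "fraction_in_at_least_two", "value": round(self.fraction_in_at_least_two, 6)})
        rows.append({"metric": "fraction_in_all", "value": round(self.fraction_in_all, 6)})
        return rows


def overlap_stats(nets: Sequence[tuple[str, IntegratedNetwork]]) -> OverlapReport:
    """Count how genes distribute across >=2 labeled source networks."""
    if len(nets) < 2:
        raise ValueError("need at least 2 labeled networks")
    labels = tuple(lab for lab, _ in nets)
    membership: dict[str, int] = {}
    for _, net in nets:
        for gid in net.gene_ids():
            membership[gid] = membership.get(gid, 0) + 1
    exactly = {k: 0 for k in range(1, len(nets) + 1)}
    for count in membership.values():
        exactly[count] += 1
    return OverlapReport(
        labels=labels,
        per_source={lab: net.n_nodes for lab, net in nets},
        nodes_in_exactly=exactly,
        n_union=len(membership),
    )


def gba_first_neighbors(net: IntegratedNetwork, seeds: Sequence[str]) -> IntegratedNetwork:
    """Guilt-by-association: induced subnetwork on seeds plus their neighbors.

    All edges of any evidence type among the selected genes are kept.
    Unknown seeds raise, listing the offenders; an empty seed list is an
    error.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    missing = sorted(s for s in seeds if s not in net)
    if missing:
        raise KeyError(f"seed gene(s) not in network: {', '.join(missing)}")
    keep = set(seeds)
    for s in seeds:
        keep.update(net.neighbors(s))
    return net.induced_subnetwork(keep)
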