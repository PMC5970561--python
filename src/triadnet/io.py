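"""Readers and writers for network interchange formats.

Three formats are supported:

``graphml``
    Self-contained GraphML 1.0 via networkx; all node and edge
    attributes travel in the file (lists pipe-joined).
``sif``
    Cytoscape simple-interaction format, ``node <tab> type <tab> node``
    with the lowercase evidence type as the interaction label.  SIF
    cannot carry attributes, so they are written to sidecar TSV tables
    (``<stem>.nodes.tsv`` and ``<stem>.edges.tsv``) and re-attached on
    read when the sidecars are present.
``tsv_edgelist``
    A headered TSV of edges with typed attribute columns; node
    attributes in a ``<path>.nodes.tsv`` sidecar.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import networkx as nx

from .model import (
    AnnotationStatus,
    DataType,
    EvexAttrs,
    EvidenceEdge,
    GeneNode,
    IntegratedNetwork,
)

__all__ = ["read_network", "write_network", "read_y2h_edgelist", "NetworkFormatError"]

FORMATS = ("sif", "graphml", "tsv_edgelist")

NODE_COLUMNS = (
    "gene_id",
    "entrez_id",
    "symbol",
    "synonyms",
    "description",
    "family_id",
    "family_description",
    "annotation_status",
)
EDGE_COLUMNS = (
    "gene_a",
    "gene_b",
    "data_type",
    "pearson_r",
    "event_types",
    "polarity",
    "speculation",
    "negation",
    "confidence",
    "source_organisms",
    "taxonomic_distance",
    "article_ids",
    "is_self_species",
)

_LIST_SEP = "|"


class NetworkFormatError(ValueError):
    """Malformed network file; message names the offending line/element."""


def _fmt_float(x: float) -> str:
    return format(x, ".10g")


def _join(items) -> str:
    return _LIST_SEP.join(str(i) for i in items)


def _split(text: str) -> list[str]:
    return [t for t in text.split(_LIST_SEP) if t != ""]


def _node_row(n: GeneNode) -> dict[str, str]:
    return {
        "gene_id": n.gene_id,
        "entrez_id": "" if n.entrez_id is None else str(n.entrez_id),
        "symbol": n.symbol or "",
        "synonyms": _join(n.synonyms),
        "description": n.description or "",
        "family_id": n.family_id or "",
        "family_description": n.family_description or "",
        "annotation_status": n.annotation_status.value,
    }


def _node_from_row(row: dict[str, str], where: str) -> GeneNode:
    gid = row.get("gene_id", "").strip()
    if not gid:
        raise NetworkFormatError(f"{where}: missing gene_id")
    status = row.get("annotation_status", "").strip()
    return GeneNode(
        gene_id=gid,
        entrez_id=int(row["entrez_id"]) if row.get("entrez_id", "").strip() else None,
        symbol=row.get("symbol", "").strip() or None,
        synonyms=tuple(_split(row.get("synonyms", ""))),
        description=row.get("description", "").strip() or None,
        family_id=row.get("family_id", "").strip() or None,
        family_description=row.get("family_description", "").strip() or None,
        annotation_status=AnnotationStatus(status) if status else None,
    )


def _edge_row(e: EvidenceEdge) -> dict[str, str]:
    a, b = e.pair
    row = dict.fromkeys(EDGE_COLUMNS, "")
    row.update(gene_a=a, gene_b=b, data_type=e.data_type.value)
    if e.pearson_r is not None and e.pearson_r == e.pearson_r:
        row["pearson_r"] = _fmt_float(e.pearson_r)
    if e.evex is not None:
        ev = e.evex
        row.update(
            event_types=_join(sorted(ev.event_types)),
            polarity=ev.polarity,
            speculation=str(ev.speculation).lower(),
            negation=str(ev.negation).lower(),
            confidence=_fmt_float(ev.confidence),
            source_organisms=_join(sorted(ev.source_organisms)),
            taxonomic_distance="" if ev.taxonomic_distance is None else str(ev.taxonomic_distance),
            article_ids=_join(sorted(ev.article_ids)),
            is_self_species=str(ev.is_self_species).lower(),
        )
    for k, v in sorted(e.meta.items()):
        row[k] = str(v)
    return row


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def _edge_from_row(row: dict[str, str], where: str) -> EvidenceEdge:
    a = row.get("gene_a", "").strip()
    b = row.get("gene_b", "").strip()
    if not a or not b:
        raise NetworkFormatError(f"{where}: missing endpoint")
    try:
        dt = DataType.parse(row.get("data_type", ""))
    except ValueError as exc:
        raise NetworkFormatError(f"{where}: {exc}") from exc
    pearson_r = None
    if row.get("pearson_r", "").strip():
        pearson_r = float(row["pearson_r"])
    elif dt is DataType.COEX:
        pearson_r = float("nan")  # attribute-less source (bare SIF)
    evex: Optional[EvexAttrs] = None
    if dt is DataType.EVEX:
        evex = EvexAttrs(
            event_types=frozenset(_split(row.get("event_types", ""))) or frozenset({"regulation"}),
            polarity=row.get("polarity", "").strip() or "unspecified",
            speculation=_parse_bool(row.get("speculation", "")),
            negation=_parse_bool(row.get("negation", "")),
            confidence=float(row["confidence"]) if row.get("confidence", "").strip() else 0.0,
            source_organisms=tuple(int(t) for t in _split(row.get("source_organisms", ""))),
            taxonomic_distance=(
                int(row["taxonomic_distance"]) if row.get("taxonomic_distance", "").strip() else None
            ),
            article_ids=tuple(_split(row.get("article_ids", ""))),
            is_self_species=_parse_bool(row.get("is_self_species", "")),
        )
    meta = {
        k: v
        for k, v in row.items()
        if k not in EDGE_COLUMNS and v is not None and str(v).strip() != ""
    }
    try:
        return EvidenceEdge(a, b, dt, pearson_r=pearson_r, evex=evex, meta=meta)
    except ValueError as exc:
        raise NetworkFormatError(f"{where}: {exc}") from exc


# ----------------------------------------------------------------- TSV


def _write_tsv(path: Path, columns: tuple[str, ...], rows: list[dict[str, str]]) -> None:
    extra = sorted({k for r in rows for k in r} - set(columns))
    header = list(columns) + extra
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row.get(c, "") for c in header) + "\n")


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    out = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) > len(header):
            raise NetworkFormatError(f"{path}:{i}: {len(cells)} cells for {len(header)} columns")
        cells += [""] * (len(header) - len(cells))
        out.append({h: c for h, c in zip(header, cells)})
    return out


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    return Path(str(path) + ".nodes.tsv"), Path(str(path) + ".edges.tsv")


# --------------------------------------------------------------- public


def write_network(net: IntegratedNetwork, path: Union[str, Path], format: str) -> None:
    """Write ``net`` to ``path``; see module docstring for format details."""
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    node_rows = [_node_row(n) for n in net.genes()]
    edge_rows = [_edge_row(e) for e in net.edges()]
    nodes_path, edges_path = _sidecar_paths(path)

    if format == "sif":
        with open(path, "w") as fh:
            connected = set()
            for e in net.edges():
                a, b = e.pair
                fh.write(f"{a}\t{e.data_type.value.lower()}\t{b}\n")
                connected.update((a, b))
            for gid in net.gene_ids():
                if gid not in connected:
                    fh.write(f"{gid}\n")
        _write_tsv(nodes_path, NODE_COLUMNS, node_rows)
        _write_tsv(edges_path, EDGE_COLUMNS, edge_rows)
    elif format == "tsv_edgelist":
        _write_tsv(path, EDGE_COLUMNS, edge_rows)
        _write_tsv(nodes_path, NODE_COLUMNS, node_rows)
    else:  # graphml
        g = nx.MultiGraph()
        for row in node_rows:
            gid = row.pop("gene_id")
            g.add_node(gid, **{k: v for k, v in row.items() if v != ""})
        for row in edge_rows:
            a, b = row.pop("gene_a"), row.pop("gene_b")
            g.add_edge(a, b, key=row["data_type"], **{k: v for k, v in row.items() if v != ""})
        nx.write_graphml(g, path, named_key_ids=True)


def read_network(path: Union[str, Path], format: str) -> IntegratedNetwork:
    """Read a network written by :func:`write_network` (or compatible files).

    Raises :class:`NetworkFormatError` on malformed content and on
    duplicate ``(pair, data_type)`` edge keys.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    net = IntegratedNetwork()
    nodes_path, edges_path = _sidecar_paths(path)

    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        for gid, attrs in g.nodes(data=True):
            net.add_gene(_node_from_row({"gene_id": str(gid), **{k: str(v) for k, v in attrs.items()}}, f"{path}:node {gid}"))
        for a, b, attrs in g.edges(data=True):
            row = {"gene_a": str(a), "gene_b": str(b), **{k: str(v) for k, v in attrs.items()}}
            edge = _edge_from_row(row, f"{path}:edge {a}-{b}")
            _insert(net, edge, path)
        return net

    if format == "tsv_edgelist":
        for i, row in enumerate(_read_tsv(path), start=2):
            _insert(net, _edge_from_row(row, f"{path}:{i}"), path)
        if nodes_path.exists():
            for row in _read_tsv(nodes_path):
                net.add_gene(_node_from_row(row, str(nodes_path)))
        return net

    # sif
    edge_attrs: dict[tuple[tuple[str, str], str], dict[str, str]] = {}
    if edges_path.exists():
        for row in _read_tsv(edges_path):
            a, b = sorted((row["gene_a"], row["gene_b"]))
            edge_attrs[((a, b), row["data_type"].lower())] = row
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if len(parts) == 1:
                net.ensure_gene(parts[0].strip())
                continue
            if len(parts) == 2:
                raise NetworkFormatError(f"{path}:{i}: expected 'node<TAB>type<TAB>node'")
            src, itype = parts[0], parts[1]
            for tgt in parts[2:]:
                pair = tuple(sorted((src, tgt)))
                row = edge_attrs.get((pair, itype.lower()))
                if row is None:
                    row = {"gene_a": src, "gene_b": tgt, "data_type": itype}
                _insert(net, _edge_from_row(row, f"{path}:{i}"), path)
    if nodes_path.exists():
        for row in _read_tsv(nodes_path):
            net.add_gene(_node_from_row(row, str(nodes_path)))
    return net


def _insert(net: IntegratedNetwork, edge: EvidenceEdge, path: Path) -> None:
    try:
        net.add_edge(edge, on_duplicate="error")
    except ValueError as exc:
        raise NetworkFormatError(f"{path}: {exc}") from exc


def read_y2h_edgelist(path: Union[str, Path]) -> IntegratedNetwork:
    """Read a two-column TSV of interacting gene pairs as a Y2H network.

    A header row is detected (and skipped) if its first field is
    ``gene_a``; duplicate pairs collapse to one edge; self-pairs are
    ignored, matching the no-self-loop invariant.
    """
    path = Path(path)
    net = IntegratedNetwork(provenance=[f"y2h:{path.name}"])
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise NetworkFormatError(f"{path}:{i}: expected two tab-separated gene ids")
            a, b = parts[0].strip(), parts[1].strip()
            if i == 1 and a.lower() in ("gene_a", "source", "gene1"):
                continue
            if a == b:
                continue
            net.add_edge(EvidenceEdge(a, b, DataType.Y2H), on_duplicate="skip")
    return net
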