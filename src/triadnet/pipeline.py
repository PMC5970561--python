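"""End-to-end pipeline: build, merge, clean, annotate, filter, report.

The pipeline wires the library stages into the full analysis: build the
co-expression network from the fold-change matrix, ingest the Y2H edge
list and the text-mining event table, union-merge them, strip circular
text-mining evidence, transfer family descriptions onto unannotated
genes, and (when key/entry genes are given) extract guilt-by-association
subnetworks and run the candidate-gene and hypothetical-protein motif
filters.  Every run writes a config snapshot, a MANIFEST of outputs and
a stage-tagged log with node/edge counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import io as netio
from .coexpression import (
    DEFAULT_MIN_OVERLAP,
    DEFAULT_THRESHOLD,
    ExpressionMatrix,
    build_coex_network,
)
from .integration import exclude_circular_evidence, gba_first_neighbors, merge_networks, overlap_stats
from .model import GeneNode, IntegratedNetwork
from .motifs import (
    candidate_table,
    filter_candidates,
    filter_hypotheticals,
    hypothesis_table,
    motif_table,
    motifs_to_network,
)
from .simulate import TARGET_TAXON
from .textmining import (
    build_evex_network,
    enrich_annotations,
    read_event_table,
    read_family_map,
    read_family_records,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    expression: Optional[Path] = None
    y2h: Optional[Path] = None
    events: Optional[Path] = None
    families: Optional[Path] = None
    family_descriptions: Optional[Path] = None
    annotations: Optional[Path] = None
    key_genes: Optional[Path] = None
    entry_genes: Optional[Path] = None
    tainted_articles: Optional[Path] = None
    output_dir: Path = Path("triadnet_out")
    threshold: float = DEFAULT_THRESHOLD
    min_overlap: int = DEFAULT_MIN_OVERLAP
    target_taxon: int = TARGET_TAXON
    seed: int = 0
    strict: bool = False
    allow_negated: bool = False
    hp_all_unannotated: bool = False

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = str(v) if isinstance(v, Path) else v
        return out


_PATH_FIELDS = (
    "expression",
    "y2h",
    "events",
    "families",
    "family_descriptions",
    "annotations",
    "key_genes",
    "entry_genes",
    "tainted_articles",
)


def validate_config(path: Union[str, Path]) -> RunConfig:
    """Parse and validate a YAML run config; errors name the offending field."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config field(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(
        **{
            k: (Path(v) if k in _PATH_FIELDS or k == "output_dir" else v)
            for k, v in raw.items()
            if v is not None
        }
    )
    if not 0 < cfg.threshold <= 1:
        raise ValueError(f"threshold: must be in (0, 1], got {cfg.threshold}")
    if cfg.min_overlap < 2:
        raise ValueError(f"min_overlap: must be >= 2, got {cfg.min_overlap}")
    base = path.parent
    for name in _PATH_FIELDS:
        p = getattr(cfg, name)
        if p is None:
            continue
        if not p.is_absolute():
            p = base / p
            setattr(cfg, name, p)
        if not p.exists():
            raise FileNotFoundError(f"{name}: input path does not exist: {p}")
    if not cfg.output_dir.is_absolute():
        cfg.output_dir = base / cfg.output_dir
    return cfg


def _read_lines(path: Path) -> list[str]:
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def _read_annotation_table(path: Path) -> list[GeneNode]:
    nodes = []
    lines = path.read_text().splitlines()
    if not lines:
        return nodes
    header = lines[0].split("\t")
    idx = {h: i for i, h in enumerate(header)}
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")

        def get(col: str) -> str:
            i = idx.get(col)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        nodes.append(
            GeneNode(
                gene_id=get("gene_id"),
                description=get("description") or None,
                family_id=get("family_id") or None,
                symbol=get("symbol") or None,
            )
        )
    return nodes


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the output directory.

    Outputs (when their stage runs): ``intnet.graphml``, ``intnet.sif``
    (+ sidecars), ``overlap_report.tsv``, ``enrichment_report.json``,
    ``gba.graphml``, ``cg_motifs.tsv``/``cg_candidates.tsv``/
    ``cg_motifs.graphml``, ``hp_motifs.tsv``/``hp_hypotheses.tsv``,
    ``config.yaml``, ``MANIFEST.txt`` and ``run.log``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("triadnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: list[str] = []
    counts: dict[str, dict] = {}

    def stage(name: str):
        log.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        manifest.append("config.yaml")

        sources: list[tuple[str, IntegratedNetwork]] = []
        if config.expression is not None:
            with stage("build-coex"):
                m = ExpressionMatrix.from_tsv(config.expression)
                coex = build_coex_network(m, threshold=config.threshold, min_overlap=config.min_overlap)
                counts["coex"] = {"nodes": coex.n_nodes, "edges": coex.n_edges}
                log.info("coex: %d nodes, %d edges", coex.n_nodes, coex.n_edges)
                sources.append(("CoEx", coex))
        if config.y2h is not None:
            with stage("ingest-y2h"):
                y2h = netio.read_y2h_edgelist(config.y2h)
                counts["y2h"] = {"nodes": y2h.n_nodes, "edges": y2h.n_edges}
                log.info("y2h: %d nodes, %d edges", y2h.n_nodes, y2h.n_edges)
                sources.append(("Y2H", y2h))
        if config.events is not None:
            with stage("build-evex"):
                if config.families is None:
                    raise ValueError("events given without a families map")
                events = read_event_table(config.events)
                fam = read_family_map(config.families)
                evex, rejects = build_evex_network(events, fam, target_taxon=config.target_taxon)
                counts["evex"] = {
                    "nodes": evex.n_nodes,
                    "edges": evex.n_edges,
                    "rejected_events": rejects.total,
                }
                log.info(
                    "evex: %d nodes, %d edges (%d events rejected)",
                    evex.n_nodes,
                    evex.n_edges,
                    rejects.total,
                )
                sources.append(("EVEX", evex))
        if len(sources) < 2:
            raise PipelineError("need at least two evidence sources to integrate")

        with stage("merge"):
            intnet, merge_report = merge_networks([n for _, n in sources], strict=config.strict)
            counts["merged"] = {"nodes": intnet.n_nodes, "edges": intnet.n_edges}
            log.info("merged: %d nodes, %d edges", intnet.n_nodes, intnet.n_edges)

        if config.tainted_articles is not None:
            with stage("exclude-circular"):
                tainted = _read_lines(config.tainted_articles)
                intnet, removal = exclude_circular_evidence(intnet, tainted)
                counts["circular_evidence"] = {
                    "removed_edges": len(removal.removed),
                    "stripped_edges": len(removal.stripped),
                }
                log.info(
                    "circular evidence: removed %d, stripped %d",
                    len(removal.removed),
                    len(removal.stripped),
                )

        if config.annotations is not None:
            with stage("apply-annotations"):
                for node in _read_annotation_table(config.annotations):
                    if node.gene_id in intnet:
                        intnet.add_gene(node)

        if config.family_descriptions is not None:
            with stage("annotate"):
                fams = read_family_records(config.family_descriptions)
                intnet, report = enrich_annotations(intnet, fams)
                counts["enrichment"] = {
                    "newly_annotated": report.newly_annotated,
                    "coverage_before": round(report.coverage_before, 6),
                    "coverage_after": round(report.coverage_after, 6),
                }
                with open(out / "enrichment_report.json", "w") as fh:
                    json.dump(counts["enrichment"], fh, indent=1, sort_keys=True)
                    fh.write("\n")
                manifest.append("enrichment_report.json")

        with stage("write-intnet"):
            netio.write_network(intnet, out / "intnet.graphml", "graphml")
            netio.write_network(intnet, out / "intnet.sif", "sif")
            manifest += ["intnet.graphml", "intnet.sif", "intnet.sif.nodes.tsv", "intnet.sif.edges.tsv"]

        with stage("stats"):
            report = overlap_stats(sources)
            rows = report.to_rows()
            with open(out / "overlap_report.tsv", "w") as fh:
                fh.write("metric\tvalue\n")
                for row in rows:
                    fh.write(f"{row['metric']}\t{row['value']}\n")
            manifest.append("overlap_report.tsv")
            counts["overlap"] = {
                "fraction_in_at_least_two": round(report.fraction_in_at_least_two, 6),
                "fraction_in_all": round(report.fraction_in_all, 6),
            }

        if config.key_genes is not None:
            keys = _read_lines(config.key_genes)
            with stage("gba"):
                present = [k for k in keys if k in intnet]
                if present:
                    gba = gba_first_neighbors(intnet, present)
                    netio.write_network(gba, out / "gba.graphml", "graphml")
                    manifest.append("gba.graphml")
                    counts["gba"] = {"nodes": gba.n_nodes, "edges": gba.n_edges}
            with stage("filter-cg"):
                motifs = filter_candidates(intnet, keys, allow_negated=config.allow_negated)
                motif_table(motifs).to_csv(out / "cg_motifs.tsv", sep="\t", index=False)
                candidate_table(motifs).to_csv(out / "cg_candidates.tsv", sep="\t", index=False)
                netio.write_network(motifs_to_network(motifs, intnet), out / "cg_motifs.graphml", "graphml")
                manifest += ["cg_motifs.tsv", "cg_candidates.tsv", "cg_motifs.graphml"]
                counts["cg"] = {"motifs": len(motifs)}
                log.info("candidate filter: %d motifs", len(motifs))

        if config.entry_genes is not None or config.hp_all_unannotated:
            with stage("filter-hp"):
                entries = (
                    None
                    if config.entry_genes is None
                    else _read_lines(config.entry_genes)
                )
                motifs = filter_hypotheticals(intnet, entries, allow_negated=config.allow_negated)
                motif_table(motifs).to_csv(out / "hp_motifs.tsv", sep="\t", index=False)
                hypothesis_table(motifs, intnet).to_csv(out / "hp_hypotheses.tsv", sep="\t", index=False)
                manifest += ["hp_motifs.tsv", "hp_hypotheses.tsv"]
                counts["hp"] = {"motifs": len(motifs)}
                log.info("hypothetical filter: %d motifs", len(motifs))

        with open(out / "counts.json", "w") as fh:
            json.dump(counts, fh, indent=1, sort_keys=True)
            fh.write("\n")
        manifest.append("counts.json")
        with open(out / "MANIFEST.txt", "w") as fh:
            fh.write("status: complete\n")
            for name in manifest:
                fh.write(name + "\n")
    except Exception:
        with open(out / "MANIFEST.txt", "w") as fh:
            fh.write("status: failed\n")
            for name in manifest:
                fh.write(name + "\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
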