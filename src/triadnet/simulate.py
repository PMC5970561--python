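"""Synthetic inputs with planted, recorded ground truth.

Every stage of the pipeline can be exercised without any external
download: the generators here emulate the three evidence sources — a
log2 fold-change expression compendium with planted co-expression
blocks, a yeast two-hybrid edge list, and a family-level text-mining
event table — plus node annotations, and record exactly what was
planted so tests can compare filter output against known truth.

All randomness flows from one integer seed; each generator draws from
an independent deterministic substream (``seed`` + a stream tag), so
adding one generator never shifts the output of another.  The same seed
and parameters reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .coexpression import ExpressionMatrix
from .model import (
    AnnotationStatus,
    DataType,
    EvexAttrs,
    EvidenceEdge,
    GeneNode,
    IntegratedNetwork,
)
from .textmining import EventRecord, FamilyMap

__all__ = [
    "SyntheticTruth",
    "PlantedScenario",
    "simulate_expression",
    "simulate_event_table",
    "plant_scenario",
    "plant_hp_scenario",
    "generate_preset",
    "PRESETS",
]

#: NCBI taxon id of Synechocystis sp. PCC 6803, the default target species
TARGET_TAXON = 1148
#: foreign organisms typical of literature-derived edges (E. coli, human, mouse, rat, yeast)
FOREIGN_TAXA = (511145, 9606, 10090, 10116, 559292)

_STREAMS = {"expression": 1, "events": 2, "scenario": 3, "hp": 4, "preset": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass
class SyntheticTruth:
    """Everything that was planted, fully determined by seed + parameters."""

    seed: int
    params: dict = field(default_factory=dict)
    coex_blocks: list = field(default_factory=list)
    y2h_edges: list = field(default_factory=list)
    evex_events: list = field(default_factory=list)
    tainted_articles: list = field(default_factory=list)
    candidate_triads: list = field(default_factory=list)
    decoy_triads: dict = field(default_factory=dict)
    hp_entries: list = field(default_factory=list)
    hp_decoy_entries: dict = field(default_factory=dict)
    key_genes: list = field(default_factory=list)
    annotation_fractions: dict = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


# ------------------------------------------------------------ expression


def simulate_expression(
    n_genes: int,
    n_conditions: int,
    blocks: Sequence[int],
    sigma: float = 0.05,
    missing_rate: float = 0.0,
    seed: int = 0,
    gene_prefix: str = "g",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression matrix with planted co-expression blocks.

    Genes in a block share one latent condition profile plus
    independent Gaussian noise of scale ``sigma``; remaining genes are
    independent.  ``missing_rate`` of the cells are blanked at random.
    """
    if n_genes <= 0 or n_conditions <= 0:
        raise ValueError("n_genes and n_conditions must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if sum(blocks) > n_genes:
        raise ValueError(f"blocks cover {sum(blocks)} genes but matrix has {n_genes}")
    rng = _rng(seed, "expression")
    gene_ids = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    values = rng.normal(0.0, 1.0, size=(n_genes, n_conditions))
    planted = []
    start = 0
    for size in blocks:
        latent = rng.normal(0.0, 1.0, size=n_conditions)
        members = gene_ids[start : start + size]
        for i in range(start, start + size):
            values[i] = latent + rng.normal(0.0, sigma, size=n_conditions)
        planted.append({"genes": members, "sigma": sigma})
        start += size
    if missing_rate > 0:
        mask = rng.random(size=values.shape) < missing_rate
        values[mask] = np.nan
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_conditions": n_conditions,
            "blocks": list(blocks),
            "sigma": sigma,
            "missing_rate": missing_rate,
        },
        coex_blocks=planted,
    )
    conditions = [f"c{j:03d}" for j in range(n_conditions)]
    return ExpressionMatrix(gene_ids, conditions, values), truth


# ---------------------------------------------------------------- events


def simulate_event_table(
    families: FamilyMap,
    n_events: int = 200,
    self_species_fraction: float = 0.3,
    taint_fraction: float = 0.1,
    seed: int = 0,
    target_taxon: int = TARGET_TAXON,
    n_tainted_articles: int = 2,
) -> tuple[list[EventRecord], SyntheticTruth]:
    """Random family-level events with controlled self-species and taint rates.

    A ``self_species_fraction`` of events lists the target taxon among
    its source organisms; a ``taint_fraction`` of events cites *only*
    tainted article ids (recorded in the truth), emulating text-mining
    hits that merely restate an experimental input publication.
    """
    rng = _rng(seed, "events")
    fam_ids = sorted(families.family_to_genes)
    if len(fam_ids) < 2:
        raise ValueError("need at least 2 families")
    tainted = [f"PMID:tainted{k:02d}" for k in range(n_tainted_articles)]
    events: list[EventRecord] = []
    truth_rows = []
    event_types = ("binding", "regulation", "indirect_regulation")
    polarities = ("positive", "negative", "unspecified")
    for i in range(n_events):
        a, b = rng.choice(len(fam_ids), size=2, replace=False)
        is_self = bool(rng.random() < self_species_fraction)
        is_tainted = bool(rng.random() < taint_fraction)
        taxa = [int(rng.choice(FOREIGN_TAXA))]
        if is_self:
            taxa.append(target_taxon)
        if is_tainted:
            articles = [tainted[int(rng.integers(len(tainted)))]]
        else:
            articles = [f"PMID:{int(rng.integers(10_000_000, 30_000_000))}"]
        ev = EventRecord(
            subject=fam_ids[a],
            object=fam_ids[b],
            event_type=event_types[int(rng.integers(3))],
            polarity=polarities[int(rng.integers(3))],
            speculation=bool(rng.random() < 0.05),
            negation=bool(rng.random() < 0.03),
            confidence=float(np.round(rng.uniform(0.0, 1.0), 4)),
            organism_taxa=tuple(sorted(taxa)),
            article_ids=tuple(articles),
        )
        events.append(ev)
        truth_rows.append(
            {
                "subject": ev.subject,
                "object": ev.object,
                "is_self_species": is_self,
                "is_tainted": is_tainted,
                "article_ids": list(ev.article_ids),
            }
        )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_events": n_events,
            "self_species_fraction": self_species_fraction,
            "taint_fraction": taint_fraction,
            "target_taxon": target_taxon,
        },
        evex_events=truth_rows,
        tainted_articles=tainted,
    )
    return events, truth


# ------------------------------------------------------------- scenarios


@dataclass
class PlantedScenario:
    """Three evidence networks plus the exact expected filter output."""

    coex: IntegratedNetwork
    y2h: IntegratedNetwork
    evex: IntegratedNetwork
    key_genes: list[str]
    entry_genes: list[str]
    expected_triples: list[tuple[str, str, str]]
    decoy_triples: dict[str, list[tuple[str, str, str]]]
    truth: SyntheticTruth

    def merged(self) -> IntegratedNetwork:
        from .integration import merge_networks

        net, _ = merge_networks([self.coex, self.y2h, self.evex])
        return net


def _coex_edge(a: str, b: str, rng: np.random.Generator) -> EvidenceEdge:
    r = float(np.round(rng.uniform(0.8, 0.99) * (1 if rng.random() < 0.7 else -1), 4))
    return EvidenceEdge(a, b, DataType.COEX, pearson_r=r)


def _evex_edge(
    a: str,
    b: str,
    rng: np.random.Generator,
    self_species: bool,
    target_taxon: int = TARGET_TAXON,
) -> EvidenceEdge:
    taxa = [int(rng.choice(FOREIGN_TAXA))]
    if self_species:
        taxa.append(target_taxon)
    return EvidenceEdge(
        a,
        b,
        DataType.EVEX,
        evex=EvexAttrs(
            event_types=frozenset({"regulation"}),
            confidence=float(np.round(rng.uniform(0.3, 0.9), 4)),
            source_organisms=tuple(sorted(taxa)),
            article_ids=(f"PMID:{int(rng.integers(10_000_000, 30_000_000))}",),
            is_self_species=self_species,
        ),
    )


def plant_scenario(
    n_planted: int = 5,
    n_type_decoys: int = 3,
    n_self_decoys: int = 2,
    seed: int = 0,
    prefix: str = "cg",
) -> PlantedScenario:
    """Candidate-gene scenario: planted acceptable triads plus rule decoys.

    Each planted triad (key k, candidate c, context x) uses a rotating
    assignment of evidence types so all type mixes are represented.
    Decoys violate exactly one rule: *type* decoys are single-evidence
    triangles (rule i); *self* decoys add a self-species text-mining
    edge between key and candidate (rule ii).  Triads are node-disjoint
    and keys touch nothing else, so the expected accepted set is exact.
    """
    rng = _rng(seed, "scenario")
    coex = IntegratedNetwork(provenance=["coex"])
    y2h = IntegratedNetwork(provenance=["y2h"])
    evex = IntegratedNetwork(provenance=["evex"])
    nets = {DataType.COEX: coex, DataType.Y2H: y2h, DataType.EVEX: evex}

    def typed_edge(a: str, b: str, dt: DataType, self_species: bool = False) -> None:
        if dt is DataType.COEX:
            nets[dt].add_edge(_coex_edge(a, b, rng))
        elif dt is DataType.Y2H:
            nets[dt].add_edge(EvidenceEdge(a, b, DataType.Y2H))
        else:
            nets[dt].add_edge(_evex_edge(a, b, rng, self_species))

    rotations = [
        (DataType.Y2H, DataType.COEX, DataType.EVEX),
        (DataType.COEX, DataType.EVEX, DataType.Y2H),
        (DataType.EVEX, DataType.Y2H, DataType.COEX),
    ]
    keys: list[str] = []
    expected: list[tuple[str, str, str]] = []
    decoys: dict[str, list[tuple[str, str, str]]] = {"type": [], "self_species": []}
    counter = 0

    def fresh(role: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{role}{counter:03d}"

    for i in range(n_planted):
        k, c, x = fresh("k"), fresh("c"), fresh("x")
        t_kc, t_kx, t_cx = rotations[i % 3]
        typed_edge(k, c, t_kc)
        typed_edge(k, x, t_kx)
        typed_edge(c, x, t_cx)
        keys.append(k)
        expected.append(tuple(sorted((k, c, x))))

    single = [DataType.COEX, DataType.Y2H, DataType.EVEX]
    for i in range(n_type_decoys):
        k, c, x = fresh("k"), fresh("c"), fresh("x")
        dt = single[i % 3]
        for a, b in ((k, c), (k, x), (c, x)):
            typed_edge(a, b, dt)
        keys.append(k)
        decoys["type"].append(tuple(sorted((k, c, x))))

    for i in range(n_self_decoys):
        k, c, x = fresh("k"), fresh("c"), fresh("x")
        t_kc, t_kx, t_cx = rotations[i % 3]
        typed_edge(k, c, t_kc, self_species=False)
        typed_edge(k, x, t_kx, self_species=False)
        typed_edge(c, x, t_cx, self_species=False)
        # the disqualifying "already known" link between key and candidate
        if t_kc is DataType.EVEX:
            evex.remove_edge(k, c, DataType.EVEX)
            evex.add_edge(_evex_edge(k, c, rng, self_species=True))
        else:
            typed_edge(k, c, DataType.EVEX, self_species=True)
        keys.append(k)
        decoys["self_species"].append(tuple(sorted((k, c, x))))

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_planted": n_planted,
            "n_type_decoys": n_type_decoys,
            "n_self_decoys": n_self_decoys,
        },
        candidate_triads=[list(t) for t in expected],
        decoy_triads={k: [list(t) for t in v] for k, v in decoys.items()},
        key_genes=keys,
    )
    return PlantedScenario(
        coex=coex,
        y2h=y2h,
        evex=evex,
        key_genes=keys,
        entry_genes=[],
        expected_triples=expected,
        decoy_triples=decoys,
        truth=truth,
    )


_DESCRIPTIONS = (
    "photosystem I subunit",
    "ferredoxin-NADP oxidoreductase",
    "cysteine desulfurase",
    "ABC transporter ATP-binding protein",
    "glucose 6-phosphate dehydrogenase",
    "RNA polymerase sigma factor",
    "nitrate transport protein",
    "bacterioferritin",
)


def plant_hp_scenario(
    n_planted: int = 4,
    n_type_decoys: int = 2,
    n_annotation_decoys: int = 2,
    seed: int = 0,
    prefix: str = "hp",
) -> PlantedScenario:
    """Hypothetical-protein scenario: role-swapped planted triads.

    Planted: an unannotated entry gene in a two-evidence-type triangle
    with two annotated partners.  *type* decoys give the entry a
    single-type triangle; *annotation* decoys build a valid triangle
    whose members are all unannotated, so no role can be transferred.
    """
    rng = _rng(seed, "hp")
    coex = IntegratedNetwork(provenance=["coex"])
    y2h = IntegratedNetwork(provenance=["y2h"])
    evex = IntegratedNetwork(provenance=["evex"])
    counter = 0

    def fresh(role: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{role}{counter:03d}"

    def annotate(net_list: list[IntegratedNetwork], gid: str, desc: Optional[str]) -> None:
        node = GeneNode(gene_id=gid, description=desc)
        for net in net_list:
            if gid in net:
                net.add_gene(node)

    entries: list[str] = []
    expected: list[tuple[str, str, str]] = []
    decoys: dict[str, list[tuple[str, str, str]]] = {"type": [], "annotation": []}

    def build_triangle(e: str, p: str, q: str, types: tuple[DataType, DataType, DataType]) -> None:
        for (a, b), dt in zip(((e, p), (e, q), (p, q)), types):
            if dt is DataType.COEX:
                coex.add_edge(_coex_edge(a, b, rng))
            elif dt is DataType.Y2H:
                y2h.add_edge(EvidenceEdge(a, b, DataType.Y2H))
            else:
                evex.add_edge(_evex_edge(a, b, rng, self_species=False))

    mixes = [
        (DataType.COEX, DataType.Y2H, DataType.COEX),
        (DataType.Y2H, DataType.COEX, DataType.Y2H),
        (DataType.COEX, DataType.EVEX, DataType.Y2H),
    ]
    for i in range(n_planted):
        e, p, q = fresh("e"), fresh("p"), fresh("q")
        build_triangle(e, p, q, mixes[i % len(mixes)])
        annotate([coex, y2h, evex], e, "hypothetical protein")
        annotate([coex, y2h, evex], p, _DESCRIPTIONS[(2 * i) % len(_DESCRIPTIONS)])
        annotate([coex, y2h, evex], q, _DESCRIPTIONS[(2 * i + 1) % len(_DESCRIPTIONS)])
        entries.append(e)
        expected.append(tuple(sorted((e, p, q))))

    for i in range(n_type_decoys):
        e, p, q = fresh("e"), fresh("p"), fresh("q")
        dt = (DataType.COEX, DataType.Y2H)[i % 2]
        build_triangle(e, p, q, (dt, dt, dt))
        annotate([coex, y2h, evex], e, None)
        annotate([coex, y2h, evex], p, _DESCRIPTIONS[i % len(_DESCRIPTIONS)])
        annotate([coex, y2h, evex], q, _DESCRIPTIONS[(i + 1) % len(_DESCRIPTIONS)])
        decoys["type"].append(tuple(sorted((e, p, q))))

    for i in range(n_annotation_decoys):
        e, p, q = fresh("e"), fresh("p"), fresh("q")
        build_triangle(e, p, q, mixes[i % len(mixes)])
        for gid in (e, p, q):
            annotate([coex, y2h, evex], gid, "unknown protein")
        decoys["annotation"].append(tuple(sorted((e, p, q))))

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_planted": n_planted,
            "n_type_decoys": n_type_decoys,
            "n_annotation_decoys": n_annotation_decoys,
        },
        hp_entries=entries,
        hp_decoy_entries={k: [list(t) for t in v] for k, v in decoys.items()},
    )
    return PlantedScenario(
        coex=coex,
        y2h=y2h,
        evex=evex,
        key_genes=[],
        entry_genes=entries,
        expected_triples=expected,
        decoy_triples=decoys,
        truth=truth,
    )


# --------------------------------------------------------------- presets

PRESETS: dict[str, dict] = {
    # quick smoke-scale inputs
    "small": {
        "n_background": 120,
        "n_conditions": 36,
        "block_size": 4,
        "n_blocks": 12,
        "sigma": 0.2,
        "missing_rate": 0.02,
        "coex_span": (0, 80),
        "y2h_span": (40, 120),
        "evex_span": (60, 110),
        "n_y2h_extra": 40,
        "n_events": 120,
        "family_size_max": 3,
        "self_species_fraction": 0.3,
        "taint_fraction": 0.05,
        "n_planted": 3,
        "n_type_decoys": 2,
        "n_self_decoys": 1,
        "n_hp_planted": 2,
        "n_hp_type_decoys": 1,
        "n_hp_annotation_decoys": 1,
        "unannotated_fraction": 0.4,
    },
    # approximates the source-data scales (~1,900 / 1,900 / 800 network nodes)
    "paper-shaped": {
        "n_background": 2850,
        "n_conditions": 68,
        "block_size": 5,
        "n_blocks": 380,
        "sigma": 0.25,
        "missing_rate": 0.02,
        "coex_span": (0, 1900),
        "y2h_span": (950, 2850),
        "evex_span": (1500, 2300),
        "n_y2h_extra": 1300,
        "n_events": 900,
        "family_size_max": 3,
        "self_species_fraction": 0.1,
        "taint_fraction": 0.02,
        "n_planted": 5,
        "n_type_decoys": 3,
        "n_self_decoys": 2,
        "n_hp_planted": 4,
        "n_hp_type_decoys": 2,
        "n_hp_annotation_decoys": 2,
        "unannotated_fraction": 0.465,
    },
}


def generate_preset(out_dir: Union[str, Path], preset: str = "small", seed: int = 0) -> SyntheticTruth:
    """Write a complete synthetic input set (plus its truth) to ``out_dir``.

    Emits the same TSV formats the ingestion operations read:
    ``expression.tsv``, ``y2h.tsv``, ``events.tsv``, ``families.tsv``,
    ``family_descriptions.tsv``, ``annotations.tsv``, ``key_genes.txt``,
    ``entry_genes.txt``, ``tainted_articles.txt`` and ``truth.json``.
    Background evidence never touches the planted key genes, so the
    candidate filter's expected output is known exactly.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed, "preset")

    universe = [f"g{i:05d}" for i in range(p["n_background"])]
    coex_genes = universe[p["coex_span"][0] : p["coex_span"][1]]
    y2h_genes = universe[p["y2h_span"][0] : p["y2h_span"][1]]
    evex_genes = universe[p["evex_span"][0] : p["evex_span"][1]]

    # --- expression: blocks tile the CoEx gene span
    n_blocks = min(p["n_blocks"], len(coex_genes) // p["block_size"])
    blocks = [p["block_size"]] * n_blocks
    expr, expr_truth = simulate_expression(
        n_genes=len(coex_genes),
        n_conditions=p["n_conditions"],
        blocks=blocks,
        sigma=p["sigma"],
        missing_rate=p["missing_rate"],
        seed=seed,
    )
    # relabel matrix rows onto the background gene universe
    expr = ExpressionMatrix(coex_genes, expr.condition_ids, expr.values)
    for blk, start in zip(expr_truth.coex_blocks, range(0, len(coex_genes), p["block_size"])):
        blk["genes"] = coex_genes[start : start + p["block_size"]]

    # --- planted CG + HP structure on dedicated genes
    cg = plant_scenario(
        n_planted=p["n_planted"],
        n_type_decoys=p["n_type_decoys"],
        n_self_decoys=p["n_self_decoys"],
        seed=seed,
        prefix="pcg",
    )
    hp = plant_hp_scenario(
        n_planted=p["n_hp_planted"],
        n_type_decoys=p["n_hp_type_decoys"],
        n_annotation_decoys=p["n_hp_annotation_decoys"],
        seed=seed,
        prefix="php",
    )

    # planted CoEx edges become tight expression profiles: one latent per
    # connected component of the planted co-expression subgraph, sign
    # propagated along edges by BFS
    import networkx as nx

    planted_coex = nx.Graph()
    for scen in (cg, hp):
        for e in scen.coex.edges():
            planted_coex.add_edge(e.gene_a, e.gene_b, sign=1.0 if (e.pearson_r or 1.0) >= 0 else -1.0)
    extra_rows: list[tuple[str, np.ndarray]] = []
    for comp in sorted(nx.connected_components(planted_coex), key=min):
        latent = rng.normal(0.0, 1.0, size=p["n_conditions"])
        signs = {min(comp): 1.0}
        for a, b in nx.bfs_edges(planted_coex.subgraph(comp), min(comp)):
            signs[b] = signs[a] * planted_coex[a][b]["sign"]
        for gid in sorted(comp):
            extra_rows.append(
                (gid, signs[gid] * latent + rng.normal(0.0, 0.02, size=p["n_conditions"]))
            )
    if extra_rows:
        ids = expr.gene_ids + [g for g, _ in extra_rows]
        vals = np.vstack([expr.values] + [row[None, :] for _, row in extra_rows])
        expr = ExpressionMatrix(ids, expr.condition_ids, vals)
    expr.to_tsv(out / "expression.tsv")

    # --- Y2H background: one partner per gene for coverage, plus extras
    y2h_pairs: set[tuple[str, str]] = set()
    for g in y2h_genes:
        partner = y2h_genes[int(rng.integers(len(y2h_genes)))]
        if partner != g:
            y2h_pairs.add(tuple(sorted((g, partner))))
    for _ in range(p["n_y2h_extra"]):
        a, b = rng.choice(len(y2h_genes), size=2, replace=False)
        y2h_pairs.add(tuple(sorted((y2h_genes[a], y2h_genes[b]))))
    for scen in (cg, hp):
        for e in scen.y2h.edges():
            y2h_pairs.add(e.pair)
    with open(out / "y2h.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(y2h_pairs):
            fh.write(f"{a}\t{b}\n")

    # --- families over the EVEX span + singleton families for planted genes
    families: dict[str, list[str]] = {}
    i = 0
    fam_n = 0
    while i < len(evex_genes):
        size = int(rng.integers(1, p["family_size_max"] + 1))
        families[f"fam{fam_n:04d}"] = evex_genes[i : i + size]
        fam_n += 1
        i += size
    planted_family_of: dict[str, str] = {}
    for scen in (cg, hp):
        for e in scen.evex.edges():
            for gid in e.pair:
                if gid not in planted_family_of:
                    fam_id = f"pfam{len(planted_family_of):04d}"
                    planted_family_of[gid] = fam_id
                    families[fam_id] = [gid]
    with open(out / "families.tsv", "w") as fh:
        fh.write("gene_id\tfamily_id\n")
        for fam_id in sorted(families):
            for gid in families[fam_id]:
                fh.write(f"{gid}\t{fam_id}\n")
    fam_map = FamilyMap({f: tuple(gs) for f, gs in families.items()})

    # --- background events + planted events
    background_fams = FamilyMap(
        {f: tuple(gs) for f, gs in families.items() if not f.startswith("pfam")}
    )
    events, ev_truth = simulate_event_table(
        background_fams,
        n_events=p["n_events"],
        self_species_fraction=p["self_species_fraction"],
        taint_fraction=p["taint_fraction"],
        seed=seed,
    )
    planted_event_rows = []
    for scen in (cg, hp):
        for e in scen.evex.edges():
            ev = e.evex
            planted_event_rows.append(
                EventRecord(
                    subject=planted_family_of[e.pair[0]],
                    object=planted_family_of[e.pair[1]],
                    event_type=sorted(ev.event_types)[0],
                    polarity=ev.polarity,
                    confidence=ev.confidence,
                    organism_taxa=ev.source_organisms,
                    article_ids=ev.article_ids,
                )
            )
    all_events = events + planted_event_rows
    with open(out / "events.tsv", "w") as fh:
        fh.write(
            "subject_family\tobject_family\tevent_type\tpolarity\tspeculation\t"
            "negation\tconfidence\ttaxa\tarticle_ids\n"
        )
        for ev in all_events:
            fh.write(
                "\t".join(
                    [
                        ev.subject,
                        ev.object,
                        ev.event_type,
                        ev.polarity,
                        str(ev.speculation).lower(),
                        str(ev.negation).lower(),
                        format(ev.confidence, ".10g"),
                        "|".join(map(str, ev.organism_taxa)),
                        "|".join(ev.article_ids),
                    ]
                )
                + "\n"
            )

    # --- annotations: a fraction of background genes lack a real one
    planted_desc: dict[str, Optional[str]] = {}
    for scen in (cg, hp):
        for net in (scen.coex, scen.y2h, scen.evex):
            for node in net.genes():
                if node.description is not None or node.gene_id not in planted_desc:
                    planted_desc[node.gene_id] = node.description
    n_hypo = 0
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("gene_id\tdescription\tfamily_id\n")
        for gid in universe:
            fam_id = background_fams.gene_to_family.get(gid, "")
            u = rng.random()
            if u < p["unannotated_fraction"]:
                desc = "hypothetical protein" if rng.random() < 0.5 else "unknown protein"
                n_hypo += 1
            else:
                desc = _DESCRIPTIONS[int(rng.integers(len(_DESCRIPTIONS)))]
            fh.write(f"{gid}\t{desc}\t{fam_id}\n")
        for gid in sorted(planted_desc):
            fam_id = planted_family_of.get(gid, "")
            fh.write(f"{gid}\t{planted_desc[gid] or ''}\t{fam_id}\n")

    # --- family description table (drives annotation enrichment)
    with open(out / "family_descriptions.tsv", "w") as fh:
        fh.write("family_id\tdescription\n")
        for k, fam_id in enumerate(sorted(f for f in families if not f.startswith("pfam"))):
            base = _DESCRIPTIONS[k % len(_DESCRIPTIONS)]
            for _ in range(len(families[fam_id])):
                fh.write(f"{fam_id}\t{base}\n")

    with open(out / "key_genes.txt", "w") as fh:
        fh.write("\n".join(cg.key_genes) + "\n")
    with open(out / "entry_genes.txt", "w") as fh:
        fh.write("\n".join(hp.entry_genes) + "\n")
    with open(out / "tainted_articles.txt", "w") as fh:
        fh.write("\n".join(ev_truth.tainted_articles) + "\n")

    truth = SyntheticTruth(
        seed=seed,
        params={"preset": preset, **p},
        coex_blocks=expr_truth.coex_blocks,
        y2h_edges=[list(pair) for pair in sorted(y2h_pairs)],
        evex_events=ev_truth.evex_events,
        tainted_articles=ev_truth.tainted_articles,
        candidate_triads=[list(t) for t in cg.expected_triples],
        decoy_triads={k: [list(t) for t in v] for k, v in cg.decoy_triples.items()},
        hp_entries=hp.entry_genes,
        hp_decoy_entries={k: [list(t) for t in v] for k, v in hp.decoy_triples.items()},
        key_genes=cg.key_genes,
        annotation_fractions={"unannotated_background": n_hypo / len(universe)},
    )
    truth.to_json(out / "truth.json")
    return truth
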