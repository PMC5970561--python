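import numpy as np
import pytest

from triadnet.model import (
    DataType,
    EvexAttrs,
    EvidenceEdge,
    GeneNode,
    IntegratedNetwork,
)


def make_evex_attrs(
    confidence=0.5,
    is_self_species=False,
    article_ids=("PMID:1",),
    negation=False,
    speculation=False,
    polarity="unspecified",
    event_types=("regulation",),
    source_organisms=(511145,),
):
    return EvexAttrs(
        event_types=frozenset(event_types),
        polarity=polarity,
        speculation=speculation,
        negation=negation,
        confidence=confidence,
        source_organisms=source_organisms,
        article_ids=article_ids,
        is_self_species=is_self_species,
    )


def make_edge(a, b, dt, **kw):
    dt = DataType(dt)
    if dt is DataType.COEX:
        return EvidenceEdge(a, b, dt, pearson_r=kw.pop("pearson_r", 0.9), **kw)
    if dt is DataType.EVEX:
        evex = kw.pop("evex", None) or make_evex_attrs(**kw)
        return EvidenceEdge(a, b, dt, evex=evex)
    return EvidenceEdge(a, b, dt, **kw)


def random_network(rng: np.random.Generator, n_nodes=20, p_edge=0.15, p_parallel=0.2,
                   p_self_species=0.3, p_negation=0.05) -> IntegratedNetwork:
    """Random evidence-typed multigraph for oracle comparisons."""
    net = IntegratedNetwork()
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    for gid in ids:
        net.add_gene(GeneNode(gid))
    types = list(DataType)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() >= p_edge:
                continue
            k = 1 + (rng.random() < p_parallel) + (rng.random() < p_parallel * 0.5)
            chosen = rng.choice(3, size=min(k, 3), replace=False)
            for t in chosen:
                dt = types[int(t)]
                if dt is DataType.EVEX:
                    e = make_edge(
                        ids[i], ids[j], dt,
                        is_self_species=bool(rng.random() < p_self_species),
                        negation=bool(rng.random() < p_negation),
                        confidence=float(np.round(rng.uniform(0, 1), 4)),
                        article_ids=(f"PMID:{int(rng.integers(1, 999))}",),
                    )
                elif dt is DataType.COEX:
                    e = make_edge(ids[i], ids[j], dt,
                                  pearson_r=float(np.round(rng.uniform(-1, 1), 4)))
                else:
                    e = make_edge(ids[i], ids[j], dt)
                net.add_edge(e)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20240523)


@pytest.fixture
def triangle_net():
    """One triangle a-b-c with three single edges of distinct types."""
    net = IntegratedNetwork()
    net.add_edge(make_edge("a", "b", DataType.Y2H))
    net.add_edge(make_edge("a", "c", DataType.COEX))
    net.add_edge(make_edge("b", "c", DataType.EVEX, is_self_species=False))
    return net
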