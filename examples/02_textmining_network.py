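"""Project family-level text-mining events onto target-species gene pairs.

Events connect gene families; every pair of target-species members of
the two families receives one text-mining edge.  Edges whose supporting
article studies the target organism itself are flagged self-species —
the motif filters later treat those associations as already known.
"""

from triadnet import build_evex_network, canonicalize
from triadnet.textmining import EventRecord, FamilyMap

TARGET = 1148  # Synechocystis sp. PCC 6803

fam = FamilyMap({
    "sigma_factors": ("sll1689", "sll0306"),
    "anti_sigma": ("slr1055",),
    "ferredoxins": ("ssl0020",),
})

events = [
    EventRecord("sigma_factors", "anti_sigma", event_type="binding",
                confidence=0.82, organism_taxa=(511145,), article_ids=("PMID:111",)),
    EventRecord("sigma_factors", "anti_sigma", event_type="regulation",
                confidence=0.55, organism_taxa=(TARGET,), article_ids=("PMID:222",)),
    EventRecord("anti_sigma", "ferredoxins", event_type="regulation",
                confidence=0.40, organism_taxa=(9606,), article_ids=("PMID:333",)),
]

net, rejects = build_evex_network(events, fam, target_taxon=TARGET)
print(f"EVEX network: {net.n_nodes} nodes, {net.n_edges} edges "
      f"({rejects.total} events rejected)")
for e in net.edges():
    ev = e.evex
    print(f"  {e.gene_a} -- {e.gene_b}: types={sorted(ev.event_types)}, "
          f"conf={ev.confidence}, self-species={ev.is_self_species}, "
          f"articles={list(ev.article_ids)}")
print("\nThe two sigma-factor events merged into one edge per gene pair "
      "(max confidence, article union); the edge is self-species because one "
      "supporting article studied the target organism.")

canonical, rep = canonicalize([
    "Hypothetical protein", "hypothetical-protein", "HYPOTHETICAL (protein)",
    "cysteine desulfurase",
])
print(f"\nfamily description canonicalization: canonical={canonical!r}, "
      f"representative={rep!r} (majority form wins after lowercasing and "
      "stripping punctuation)")
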