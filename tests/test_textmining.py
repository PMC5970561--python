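from collections import Counter

import numpy as np
import pytest

from _oracles import expand_events_brute
from triadnet.model import AnnotationStatus, DataType, FamilyRecord, GeneNode, IntegratedNetwork
from triadnet.textmining import (
    EventRecord,
    FamilyMap,
    build_evex_network,
    canonical_form,
    canonicalize,
    compare_annotations,
    enrich_annotations,
    read_event_table,
    read_family_map,
    taxonomic_distance,
)

TARGET = 1148


def ev(subject, object, confidence=0.5, taxa=(511145,), articles=("PMID:1",), **kw):
    return EventRecord(subject=subject, object=object, confidence=confidence,
                       organism_taxa=taxa, article_ids=articles, **kw)


class TestBuildEvexNetwork:
    def test_single_event_single_edge(self):
        fam = FamilyMap({"A": ("g1",), "B": ("g2",)})
        net, rejects = build_evex_network([ev("A", "B")], fam, TARGET)
        assert net.n_edges == 1 and rejects.total == 0
        assert net.get_edge("g1", "g2", DataType.EVEX) is not None

    def test_family_cartesian_expansion(self):
        fam = FamilyMap({"A": ("a1", "a2"), "B": ("b1", "b2", "b3")})
        net, _ = build_evex_network([ev("A", "B")], fam, TARGET)
        assert net.n_edges == 6

    def test_self_event_within_family_dropped(self):
        fam = FamilyMap({"A": ("g1",)})
        net, rejects = build_evex_network([ev("A", "A")], fam, TARGET)
        assert net.n_edges == 0
        assert len(rejects.self_event) == 1

    def test_unknown_family_rejected_with_report(self):
        fam = FamilyMap({"A": ("g1",)})
        net, rejects = build_evex_network([ev("A", "NOPE")], fam, TARGET)
        assert net.n_edges == 0
        assert len(rejects.unknown_identifier) == 1

    def test_duplicate_events_merge_max_confidence_union_articles(self):
        fam = FamilyMap({"A": ("g1",), "B": ("g2",)})
        events = [
            ev("A", "B", confidence=0.4, articles=("PMID:1",), speculation=True),
            ev("B", "A", confidence=0.9, taxa=(TARGET,), articles=("PMID:2",)),
        ]
        net, _ = build_evex_network(events, fam, TARGET)
        e = net.get_edge("g1", "g2", DataType.EVEX).evex
        assert e.confidence == pytest.approx(0.9)
        assert sorted(e.article_ids) == ["PMID:1", "PMID:2"]
        assert e.is_self_species  # one contributing article studies the target
        assert not e.speculation  # one plain assertion outweighs a hedge

    def test_random_events_match_bruteforce_expansion(self, rng):
        fams = {f"F{k}": tuple(f"g{k}_{i}" for i in range(int(rng.integers(1, 4))))
                for k in range(40)}
        fam = FamilyMap(fams)
        names = sorted(fams)
        events = []
        for _ in range(500):
            a, b = rng.choice(40, size=2, replace=False)
            events.append(ev(names[a], names[b],
                             confidence=float(np.round(rng.uniform(), 3)),
                             taxa=(TARGET,) if rng.random() < 0.3 else (9606,),
                             articles=(f"PMID:{int(rng.integers(1, 200))}",)))
        net, rejects = build_evex_network(events, fam, TARGET)
        brute = expand_events_brute(events, fam)
        assert net.edge_key_set() == {(pair, DataType.EVEX) for pair in brute}
        for pair, evs in brute.items():
            edge = net.get_edge(*pair, DataType.EVEX).evex
            assert edge.confidence == pytest.approx(max(e.confidence for e in evs))
            assert set(edge.article_ids) == {p for e in evs for p in e.article_ids}
            assert edge.is_self_species == any(TARGET in e.organism_taxa for e in evs)

    def test_output_contains_only_evex_edges(self, rng):
        fam = FamilyMap({"A": ("g1", "g2"), "B": ("g3",)})
        net, _ = build_evex_network([ev("A", "B"), ev("B", "A")], fam, TARGET)
        assert all(e.data_type is DataType.EVEX for e in net.edges())


class TestCanonicalize:
    def test_majority_rule_example(self):
        canonical, rep = canonicalize(
            ["Hypothetical protein", "hypothetical-protein", "oxidoreductase"]
        )
        assert canonical == "hypotheticalprotein"
        assert rep == "Hypothetical protein"

    def test_singleton(self):
        assert canonicalize(["x"]) == ("x", "x")

    def test_all_empty_is_error(self):
        with pytest.raises(ValueError):
            canonicalize(["", "   "])

    def test_idempotent_on_representative(self):
        _, rep = canonicalize(["Ferredoxin I", "ferredoxin-I", "ferredoxin (I)"])
        canonical, rep2 = canonicalize([rep])
        assert canonical == canonical_form(rep)
        assert rep2 == rep

    def test_fuzzed_variants_recover_mode(self, rng):
        bases = ["cysteine desulfurase", "abc transporter", "ferredoxin",
                 "sigma factor", "bacterioferritin"]
        variants, truth_counts = [], Counter()
        for _ in range(1000):
            base = bases[int(rng.integers(5))]
            truth_counts[canonical_form(base)] += 1
            chars = []
            for ch in base:
                chars.append(ch.upper() if rng.random() < 0.5 else ch)
                if rng.random() < 0.1:
                    chars.append("-( '" [int(rng.integers(4))])
            variants.append("".join(chars))
        canonical, _ = canonicalize(variants)
        assert canonical == truth_counts.most_common(1)[0][0]

    def test_tie_breaks_are_deterministic(self):
        # equal counts: lexicographically smallest canonical form wins
        canonical, rep = canonicalize(["beta", "alpha"])
        assert canonical == "alpha" and rep == "alpha"


class TestEnrichAnnotations:
    def build(self, n_unannotated, n_total, described_fraction):
        net = IntegratedNetwork()
        fams = []
        for i in range(n_total):
            if i < n_unannotated:
                in_fam = i < n_unannotated * described_fraction
                net.add_gene(GeneNode(f"g{i}", family_id=f"f{i}" if in_fam else None))
                if in_fam:
                    fams.append(FamilyRecord(f"f{i}", ("cysteine desulfurase",)))
            else:
                net.add_gene(GeneNode(f"g{i}", description="ferredoxin I"))
        return net, fams

    def test_hypothetical_gains_family_description(self):
        net = IntegratedNetwork()
        net.add_gene(GeneNode("g1", description="hypothetical protein", family_id="f1"))
        out, report = enrich_annotations(net, [FamilyRecord("f1", ("cysteine desulfurase",))])
        assert out.gene("g1").family_description == "cysteine desulfurase"
        assert report.newly_annotated == 1

    def test_annotated_node_never_overwritten(self):
        net = IntegratedNetwork()
        net.add_gene(GeneNode("g1", description="ferredoxin I", family_id="f1"))
        out, report = enrich_annotations(net, [FamilyRecord("f1", ("something else",))])
        assert out.gene("g1").family_description is None
        assert report.newly_annotated == 0

    def test_coverage_arithmetic(self):
        # 40% unannotated, 60% of those in described families -> +24 points
        net, fams = self.build(n_unannotated=40, n_total=100, described_fraction=0.6)
        _, report = enrich_annotations(net, fams)
        assert report.coverage_before == pytest.approx(0.60)
        assert report.coverage_after == pytest.approx(0.84)
        assert report.coverage_gain == pytest.approx(0.24)


class TestCompareAnnotations:
    def test_substring_via_canonical_forms(self):
        assert compare_annotations(
            "FeS assembly protein", "hypothetical protein (FeS assembly protein)"
        ) == "substring"

    def test_identical_up_to_case_and_space(self):
        assert compare_annotations("ferredoxin I", " Ferredoxin I ") == "identical"

    def test_unrelated(self):
        assert compare_annotations("ferredoxin", "sigma factor") == "other"

    def test_agrees_with_naive_containment(self, rng):
        words = ["iron", "sulfur", "cluster", "assembly", "protein", "transport"]
        for _ in range(200):
            a = " ".join(words[i] for i in rng.choice(6, size=int(rng.integers(1, 4)), replace=False))
            b = " ".join(words[i] for i in rng.choice(6, size=int(rng.integers(1, 4)), replace=False))
            got = compare_annotations(a, b)
            ca, cb = canonical_form(a), canonical_form(b)
            if a.strip().casefold() == b.strip().casefold():
                assert got == "identical"
            elif ca in cb or cb in ca:
                assert got == "substring"
            else:
                assert got == "other"


def test_taxonomic_distance_hop_count():
    #      1
    #     / \
    #    2   3
    #   / \    \
    #  4   5    6
    tree = {2: 1, 3: 1, 4: 2, 5: 2, 6: 3}
    assert taxonomic_distance(tree, 4, 5) == 2
    assert taxonomic_distance(tree, 4, 6) == 4
    assert taxonomic_distance(tree, 4, 4) == 0
    assert taxonomic_distance(tree, 4, 99) is None


def test_event_and_family_table_readers(tmp_path):
    evp = tmp_path / "events.tsv"
    evp.write_text(
        "subject_family\tobject_family\tevent_type\tpolarity\tspeculation\tnegation\t"
        "confidence\ttaxa\tarticle_ids\n"
        "A\tB\tbinding\tpositive\ttrue\tfalse\t0.8\t1148|9606\tPMID:7|PMID:8\n"
    )
    events = read_event_table(evp)
    assert len(events) == 1
    assert events[0].event_type == "binding"
    assert events[0].organism_taxa == (1148, 9606)
    assert events[0].article_ids == ("PMID:7", "PMID:8")
    fmp = tmp_path / "fam.tsv"
    fmp.write_text("gene_id\tfamily_id\ng1\tA\ng2\tA\ng3\tB\n")
    fam = read_family_map(fmp)
    assert fam.family_to_genes["A"] == ("g1", "g2")
    assert fam.gene_to_family["g3"] == "B"


def test_family_map_consistency_enforced():
    with pytest.raises(ValueError):
        FamilyMap({"A": ("g1",), "B": ("g1",)})
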