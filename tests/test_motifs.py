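import pytest

from _oracles import triangles_brute
from conftest import make_edge, random_network
from triadnet.model import AnnotationStatus, DataType, GeneNode, IntegratedNetwork
from triadnet.motifs import (
    RankTuple,
    candidate_table,
    edge_rank,
    enumerate_triangles,
    filter_candidates,
    filter_hypotheticals,
    hypothesis_table,
    motif_table,
    rank_motif,
)
from triadnet.simulate import plant_hp_scenario, plant_scenario


def motif_set(motifs):
    return {(m.nodes, tuple((e.pair, e.data_type) for e in m.edges)) for m in motifs}


class TestEnumerateTriangles:
    def test_single_triangle_single_motif(self, triangle_net):
        motifs = enumerate_triangles(triangle_net, ["a"])
        assert len(motifs) == 1
        assert motifs[0].nodes == ("a", "b", "c")

    def test_parallel_edges_expand_combinatorially(self, triangle_net):
        triangle_net.add_edge(make_edge("a", "b", DataType.COEX))  # second a-b edge
        motifs = enumerate_triangles(triangle_net, ["a"])
        assert len(motifs) == 2

    def test_each_motif_emitted_once_regardless_of_anchor_count(self, triangle_net):
        motifs = enumerate_triangles(triangle_net, ["a", "b", "c"])
        assert len(motifs) == 1

    def test_matches_exhaustive_bruteforce(self, rng):
        for _ in range(20):
            net = random_network(rng, n_nodes=18, p_edge=0.25, p_parallel=0.3)
            anchors = [f"n{i:03d}" for i in range(0, 18, 5)]
            got = motif_set(enumerate_triangles(net, anchors))
            assert got == triangles_brute(net, anchors)

    def test_empty_anchor_list_rejected(self, triangle_net):
        with pytest.raises(ValueError):
            enumerate_triangles(triangle_net, [])


class TestRanking:
    def test_edge_ranks(self):
        assert edge_rank(make_edge("a", "b", DataType.EVEX, is_self_species=True)) == 1
        assert edge_rank(make_edge("a", "b", DataType.EVEX, is_self_species=False)) == 2
        assert edge_rank(make_edge("a", "b", DataType.COEX)) == 3
        assert edge_rank(make_edge("a", "b", DataType.Y2H)) == 4

    def test_plain_motif_profile_and_counts(self, triangle_net):
        [motif] = enumerate_triangles(triangle_net, ["a"])
        rank = rank_motif(motif, triangle_net, key_genes=["a"])
        assert rank.edge_rank_profile == (2, 3, 4)
        assert (rank.extra_key_links, rank.indirect_support, rank.extra_pattern_links) == (0, 0, 0)

    def test_parallel_edge_strictly_improves_rank(self, triangle_net):
        [motif] = enumerate_triangles(triangle_net, ["a"])
        before = rank_motif(motif, triangle_net, key_genes=["a"])
        triangle_net.add_edge(make_edge("b", "c", DataType.COEX))
        # same chosen edges, one extra parallel edge inside the motif
        matching = [m for m in enumerate_triangles(triangle_net, ["a"])
                    if motif_set([m]) == motif_set([motif])]
        after = rank_motif(matching[0], triangle_net, key_genes=["a"])
        assert after.extra_pattern_links == before.extra_pattern_links + 1
        assert after < before  # smaller sorts first = better

    def test_extra_key_links_and_indirect_support(self, triangle_net):
        # extra key k2 outside the motif adjacent to candidate b
        triangle_net.add_edge(make_edge("b", "k2", DataType.Y2H))
        # two-step path b - w - a (w outside the motif)
        triangle_net.add_edge(make_edge("b", "w", DataType.COEX))
        triangle_net.add_edge(make_edge("w", "a", DataType.COEX))
        [motif] = [m for m in enumerate_triangles(triangle_net, ["a"])
                   if m.nodes == ("a", "b", "c")]
        rank = rank_motif(motif, triangle_net, key_genes=["a", "k2"], candidates=["b", "c"])
        assert rank.extra_key_links == 1
        assert rank.indirect_support == 1

    def test_sorting_agrees_with_pairwise_comparison(self, rng):
        ranks = [
            RankTuple(
                tuple(sorted(int(rng.integers(1, 5)) for _ in range(3))),
                int(rng.integers(3)), int(rng.integers(3)), int(rng.integers(3)),
            )
            for _ in range(50)
        ]
        ordered = sorted(ranks)
        for i in range(len(ordered) - 1):
            assert not (ordered[i + 1] < ordered[i])


class TestCandidateFilter:
    def build_case_study_motif(self, with_known_link=False):
        """SigE-like pattern: key sll1689, candidate slr1055, context sll0306."""
        net = IntegratedNetwork()
        net.add_edge(make_edge("sll1689", "slr1055", DataType.Y2H))
        net.add_edge(make_edge("sll1689", "sll0306", DataType.EVEX, is_self_species=False))
        net.add_edge(make_edge("sll0306", "slr1055", DataType.EVEX, is_self_species=False))
        if with_known_link:
            net.add_edge(make_edge("sll1689", "slr1055", DataType.EVEX, is_self_species=True))
        return net

    def test_two_type_motif_without_known_link_accepted(self):
        net = self.build_case_study_motif()
        motifs = filter_candidates(net, ["sll1689"])
        assert len(motifs) == 1
        assert motifs[0].roles == {
            "sll0306": "candidate", "sll1689": "key", "slr1055": "candidate",
        }

    def test_self_species_evex_between_key_and_candidate_rejects(self):
        net = self.build_case_study_motif(with_known_link=True)
        assert filter_candidates(net, ["sll1689"]) == []

    def test_single_data_type_motif_rejected(self):
        net = IntegratedNetwork()
        for a, b in (("k", "c"), ("k", "x"), ("c", "x")):
            net.add_edge(make_edge(a, b, DataType.COEX))
        assert filter_candidates(net, ["k"]) == []

    def test_all_key_motif_nominates_nothing(self, triangle_net):
        assert filter_candidates(triangle_net, ["a", "b", "c"]) == []

    def test_planted_scenario_recovered_exactly(self):
        for seed in range(5):
            scen = plant_scenario(n_planted=5, n_type_decoys=3, n_self_decoys=2, seed=seed)
            motifs = filter_candidates(scen.merged(), scen.key_genes)
            assert {m.nodes for m in motifs} == set(scen.expected_triples)

    def test_negated_evex_edges_excluded_by_default(self):
        net = IntegratedNetwork()
        net.add_edge(make_edge("k", "c", DataType.Y2H))
        net.add_edge(make_edge("k", "x", DataType.COEX))
        net.add_edge(make_edge("c", "x", DataType.EVEX, negation=True))
        assert filter_candidates(net, ["k"]) == []
        assert len(filter_candidates(net, ["k"], allow_negated=True)) == 1

    def test_unknown_key_gene_is_error(self, triangle_net):
        with pytest.raises(KeyError, match="ghost"):
            filter_candidates(triangle_net, ["ghost"])
        with pytest.raises(ValueError):
            filter_candidates(triangle_net, [])

    def test_output_invariants_on_random_networks(self, rng):
        for _ in range(10):
            net = random_network(rng, n_nodes=20, p_edge=0.25, p_parallel=0.3)
            keys = [f"n{i:03d}" for i in range(0, 20, 7)]
            motifs = filter_candidates(net, keys)
            keyset = set(keys)
            for m in motifs:
                assert len(m.data_types) >= 2
                for e in m.edges:
                    assert net.get_edge(e.gene_a, e.gene_b, e.data_type) is not None
                # global rule (ii) re-check
                for k in keyset & set(m.nodes):
                    for c in set(m.nodes) - keyset:
                        evex = net.get_edge(k, c, DataType.EVEX)
                        assert evex is None or not evex.evex.is_self_species

    def test_removing_non_motif_edge_preserves_membership(self, rng):
        net = random_network(rng, n_nodes=18, p_edge=0.25, p_parallel=0.2)
        keys = ["n001", "n008"]
        motifs = filter_candidates(net, keys)
        used = {(e.pair, e.data_type) for m in motifs for e in m.edges}
        spare = next(
            (e for e in net.edges()
             if (e.pair, e.data_type) not in used
             and not set(e.pair) & {n for m in motifs for n in m.nodes}
             and not (e.data_type is DataType.EVEX and e.evex.is_self_species)),
            None,
        )
        if spare is None:
            pytest.skip("random instance has no removable spare edge")
        net.remove_edge(spare.gene_a, spare.gene_b, spare.data_type)
        assert motif_set(filter_candidates(net, keys)) == motif_set(motifs)

    def test_deterministic_output_order(self, rng):
        net = random_network(rng, n_nodes=20, p_edge=0.3, p_parallel=0.3)
        keys = ["n000", "n005", "n010"]
        a = filter_candidates(net, keys)
        b = filter_candidates(net, keys)
        assert [m.identity for m in a] == [m.identity for m in b]
        ranks = [m.rank.sort_key for m in a]
        assert ranks == sorted(ranks)


class TestHypotheticalFilter:
    def build_psi_cluster(self):
        """sll0543-like entry clustered with annotated photosystem partners."""
        net = IntegratedNetwork()
        net.add_edge(make_edge("sll0543", "psaC", DataType.COEX))
        net.add_edge(make_edge("sll0543", "psaD", DataType.Y2H))
        net.add_edge(make_edge("psaC", "psaD", DataType.COEX))
        net.add_gene(GeneNode("sll0543", description="hypothetical protein"))
        net.add_gene(GeneNode("psaC", description="photosystem I subunit VII"))
        net.add_gene(GeneNode("psaD", description="photosystem I subunit II"))
        return net

    def test_entry_with_annotated_partners_accepted(self):
        net = self.build_psi_cluster()
        motifs = filter_hypotheticals(net)
        assert len(motifs) == 1
        assert motifs[0].roles["sll0543"] == "hypothetical"
        assert motifs[0].roles["psaC"] == "functional"
        table = hypothesis_table(motifs, net)
        assert set(table["annotated_partner"]) == {"psaC", "psaD"}
        assert "photosystem" in table["partner_description"].iloc[0]

    def test_all_unannotated_triangle_rejected(self):
        net = IntegratedNetwork()
        net.add_edge(make_edge("u1", "u2", DataType.COEX))
        net.add_edge(make_edge("u1", "u3", DataType.Y2H))
        net.add_edge(make_edge("u2", "u3", DataType.COEX))
        assert filter_hypotheticals(net) == []

    def test_self_species_evex_to_annotated_member_rejects(self):
        net = self.build_psi_cluster()
        net.add_edge(make_edge("sll0543", "psaC", DataType.EVEX, is_self_species=True))
        assert filter_hypotheticals(net, ["sll0543"]) == []

    def test_planted_hp_scenario_recovered_exactly(self):
        for seed in range(5):
            scen = plant_hp_scenario(n_planted=4, n_type_decoys=2, n_annotation_decoys=2, seed=seed)
            motifs = filter_hypotheticals(scen.merged())
            recovered = {n for m in motifs for n, r in m.roles.items() if r == "hypothetical"}
            assert recovered == set(scen.entry_genes)
            assert {m.nodes for m in motifs} == set(scen.expected_triples)

    def test_role_swap_duality_with_candidate_filter(self):
        """Treating the annotated partners as keys, the CG filter accepts the
        same planted triangles with the entry gene in the nominated role."""
        scen = plant_hp_scenario(n_planted=3, n_type_decoys=0, n_annotation_decoys=0, seed=7)
        net = scen.merged()
        annotated = [
            g.gene_id for g in net.genes()
            if g.annotation_status is AnnotationStatus.ANNOTATED
        ]
        cg = filter_candidates(net, annotated)
        assert {m.nodes for m in cg} == set(scen.expected_triples)
        for m in cg:
            entry = [n for n, r in m.roles.items() if r == "candidate"]
            assert entry == [e for e in scen.entry_genes if e in m.nodes]


def test_tables_are_well_formed(rng):
    scen = plant_scenario(seed=3)
    net = scen.merged()
    motifs = filter_candidates(net, scen.key_genes)
    mt = motif_table(motifs)
    assert len(mt) == len(motifs)
    assert set(mt.columns) >= {"motif_id", "nodes", "roles", "edges", "edge_rank_profile"}
    ct = candidate_table(motifs)
    # both non-key members of every planted triad are nominated
    assert len(ct) == 2 * len(scen.expected_triples)
    assert ct["motif_count"].ge(1).all()
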