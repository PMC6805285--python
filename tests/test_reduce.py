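"""Reduction passes: transitive shortcuts, spur clipping, chain contraction."""

import pytest

import olcreduce as olc
from olcreduce.errors import GraphError
from olcreduce.reduce import default_max_tip_bp

from conftest import chain_reads, graph_edges, random_read_graph, spur_fixture, tiled_reads


class TestTransitiveReduce:
    def test_triangle_shortcut_removed_and_spelling_preserved(self, triangle):
        graph, _ = triangle
        spelled_before = graph.spell_walk(["a", "c"])
        reduced, stats = olc.transitive_reduce(graph, fuzz=0)
        assert graph_edges(reduced) == {("a", "b"), ("b", "c")}
        assert (stats.edges_before, stats.edges_after) == (3, 2)
        assert reduced.spell_walk(["a", "b", "c"]) == spelled_before

    def test_plain_path_unchanged(self, chain10):
        graph, _ = chain10
        reduced, stats = olc.transitive_reduce(graph)
        assert graph_edges(reduced) == graph_edges(graph)
        assert stats.edges_after == stats.edges_before

    def test_does_not_mutate_input(self, triangle):
        graph, _ = triangle
        olc.transitive_reduce(graph)
        assert graph.edge_count == 3
        assert all(not e.marked for e in graph.edges())

    def test_vertex_count_unchanged(self, triangle):
        graph, _ = triangle
        reduced, _ = olc.transitive_reduce(graph)
        assert sorted(reduced.vertex_ids()) == sorted(graph.vertex_ids())

    def test_rejects_composite_input(self, chain10):
        graph, _ = chain10
        contracted, _ = olc.contract_composite_edges(graph)
        with pytest.raises(GraphError, match="composite"):
            olc.transitive_reduce(contracted)

    @pytest.mark.parametrize("fuzz", [0, 2])
    def test_matches_brute_force_on_random_graphs(self, fuzz):
        for seed in range(30):
            graph = random_read_graph(seed)
            fast, _ = olc.transitive_reduce(graph, fuzz)
            brute = olc.brute_force_transitive_reduction(graph, fuzz)
            assert graph_edges(fast) == graph_edges(brute)

    def test_idempotent(self):
        for seed in range(10):
            graph = random_read_graph(seed)
            once, _ = olc.transitive_reduce(graph)
            twice, stats = olc.transitive_reduce(once)
            assert graph_edges(twice) == graph_edges(once)
            assert stats.edges_after == stats.edges_before


class TestDeadEndRemoval:
    def test_single_spur_clipped_chain_intact(self):
        graph, spurs, long_spur, _ = spur_fixture(1)
        reduced, stats = olc.remove_dead_ends(graph)
        removed = graph_edges(graph) - graph_edges(reduced)
        assert removed == spurs[0]
        assert stats.edges_after == stats.edges_before - len(spurs[0])

    def test_long_spur_survives(self):
        graph, _, long_spur, _ = spur_fixture(2)
        reduced, _ = olc.remove_dead_ends(graph)
        assert long_spur <= graph_edges(reduced)

    def test_pure_chain_component_never_clipped(self, chain10):
        graph, _ = chain10
        reduced, stats = olc.remove_dead_ends(graph)
        assert graph_edges(reduced) == graph_edges(graph)
        assert stats.edges_after == stats.edges_before

    def test_edge_count_cap_selects_among_hanging_paths(self):
        # spur paths of 1..3 edges clipped, the 5-edge path kept
        graph, spurs, long_spur, _ = spur_fixture(5)
        reduced, _ = olc.remove_dead_ends(graph, olc.ReductionParams(max_tip_edges=3))
        removed = graph_edges(graph) - graph_edges(reduced)
        assert removed == set().union(*spurs)
        assert long_spur <= graph_edges(reduced)

    def test_max_tip_bp_cap(self):
        graph, spurs, _, _ = spur_fixture(1)
        # the 1-edge spur spells 60 novel bases; a 10 bp cap protects it
        reduced, _ = olc.remove_dead_ends(
            graph, olc.ReductionParams(max_tip_bp=10))
        assert graph_edges(reduced) == graph_edges(graph)

    def test_source_tip_clipping_flag(self):
        # mirror-image spur: a dangling entry path into a convergence vertex
        reads, genome, mo = chain_reads(8)
        import numpy as np
        rng = np.random.default_rng(3)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=4))
        # source tip read: random head + genuine 8 bp prefix of read c04
        tip = olc.Read("tip", junk + reads[4].seq[:8])
        allreads = reads + [tip]
        graph = olc.build_graph(allreads, olc.find_overlaps(allreads, mo))
        assert graph.degrees()["tip"] == (0, 1)
        clipped, _ = olc.remove_dead_ends(graph, olc.ReductionParams(clip_sources=True))
        assert ("tip", "c04") not in graph_edges(clipped)
        kept, _ = olc.remove_dead_ends(graph, olc.ReductionParams(clip_sources=False))
        assert ("tip", "c04") in graph_edges(kept)

    def test_default_tip_bp_is_twice_mean_read_length(self, chain10):
        graph, _ = chain10
        assert default_max_tip_bp(graph) == 24  # reads are 12 bp

    def test_vertices_retained(self):
        graph, spurs, _, _ = spur_fixture(1)
        reduced, _ = olc.remove_dead_ends(graph)
        assert sorted(reduced.vertex_ids()) == sorted(graph.vertex_ids())


class TestCompositeEdgeContraction:
    def test_three_vertex_chain_contracts_to_one_edge(self):
        reads, genome, mo = chain_reads(3)
        graph = olc.build_graph(reads, olc.find_overlaps(reads, mo))
        before = graph.spell_walk(sorted(graph.vertex_ids()))
        contracted, stats = olc.contract_composite_edges(graph)
        assert contracted.edge_count == 1
        edge = next(contracted.edges())
        assert edge.members == ("c01",)
        assert contracted.spell_walk([edge.src, edge.dst]) == before == genome
        assert (stats.edges_before, stats.edges_after) == (2, 1)

    def test_ten_vertex_chain_spells_template(self, chain10):
        graph, genome = chain10
        contracted, _ = olc.contract_composite_edges(graph)
        assert contracted.edge_count == 1
        edge = next(contracted.edges())
        assert edge.members == tuple(f"c{i:02d}" for i in range(1, 9))
        assert contracted.spell_walk([edge.src, edge.dst]) == genome
        assert edge.label_len == len(genome) - graph.read(edge.src).length

    def test_no_simple_vertices_no_change(self):
        # four staggered reads, all six pairwise overlaps: no simple vertex
        genome = olc.generate_unique_genome(13, 5, seed=23)
        reads = tiled_reads(genome, [(f"r{i}", i, 10) for i in range(4)])
        graph = olc.build_graph(reads, olc.find_overlaps(reads, 5))
        assert graph.edge_count == 6
        assert not any(d == (1, 1) for d in graph.degrees().values())
        contracted, stats = olc.contract_composite_edges(graph)
        assert graph_edges(contracted) == graph_edges(graph)
        assert stats.skipped_contractions == 0

    def test_colliding_contraction_skipped(self, triangle):
        # b is simple but a->c already exists: the chain must stay put
        graph, _ = triangle
        contracted, stats = olc.contract_composite_edges(graph)
        assert graph_edges(contracted) == graph_edges(graph)
        assert stats.skipped_contractions == 1

    def test_all_simple_cycle_reported_not_contracted(self):
        # circular template tiled by 5 reads: a pure cycle of simple vertices
        genome = olc.generate_unique_genome(60, 5, seed=21, circular=True)
        reads = [olc.Read(f"v{i}", (genome + genome)[12 * i : 12 * i + 20])
                 for i in range(5)]
        graph = olc.build_graph(reads, olc.find_overlaps(reads, 6))
        assert all(d == (1, 1) for d in graph.degrees().values())
        contracted, stats = olc.contract_composite_edges(graph)
        assert graph_edges(contracted) == graph_edges(graph)
        assert stats.circular_components == (tuple(f"v{i}" for i in range(5)),)

    def test_anchored_cycle_contracts_to_composite_self_loop(self, tmp_path):
        # a simple-vertex cycle entered at v0: contracts to a v0 -> v0 composite
        genome = olc.generate_unique_genome(60, 5, seed=25, circular=True)
        reads = [olc.Read(f"v{i}", (genome + genome)[12 * i : 12 * i + 20])
                 for i in range(5)]
        import numpy as np
        rng = np.random.default_rng(25)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=12))
        reads.append(olc.Read("entry", junk + reads[0].seq[:8]))
        graph = olc.build_graph(reads, olc.find_overlaps(reads, 6))
        assert graph.degrees()["v0"] == (2, 1)
        loop_spell = graph.spell_walk(["v0", "v1", "v2", "v3", "v4", "v0"])

        contracted, _ = olc.contract_composite_edges(graph)
        edge = contracted.edge("v0", "v0")
        assert edge.is_composite and edge.members == ("v1", "v2", "v3", "v4")
        assert contracted.spell_walk(["v0", "v0"]) == loop_spell
        # composite self-loops survive GFA serialization with spelling intact
        p = tmp_path / "loop.gfa"
        olc.write_gfa(contracted, p)
        back = olc.read_gfa(p)
        assert back.spell_walk(["v0", "cmp|v0|v0", "v0"]) == loop_spell

    def test_idempotent(self, chain10):
        graph, _ = chain10
        once, _ = olc.contract_composite_edges(graph)
        twice, stats = olc.contract_composite_edges(once)
        assert graph_edges(twice) == graph_edges(once)
        assert stats.edges_after == stats.edges_before

    def test_components_preserved(self):
        reads1, _, mo = chain_reads(5, seed=31, prefix="x")
        reads2, _, _ = chain_reads(5, seed=32, prefix="y")
        reads = reads1 + reads2
        graph = olc.build_graph(reads, olc.find_overlaps(reads, mo))
        if len(graph.weakly_connected_components()) != 2:
            pytest.skip("templates accidentally overlap")
        contracted, _ = olc.contract_composite_edges(graph)
        assert len(contracted.weakly_connected_components()) == 2


class TestPipeline:
    def test_empty_graph(self):
        reduced, stats = olc.reduce_pipeline(olc.OverlapGraph())
        assert reduced.edge_count == 0
        assert [s.stage for s in stats] == ["TER", "DER", "CEC"]
        assert all(s.edges_before == s.edges_after == 0 for s in stats)

    def test_chain_with_shortcut_and_spur_stage_counts(self):
        """10-tile chain + 1 transitive shortcut + 1 spur: hand-counted stages.

        Chain reads are 100 bp at stride 50 (9 adjacent edges).  Read c03
        is lengthened to 140 bp so it also reaches c05 (overlap 40, a
        transitive shortcut).  A spur read dangles off c02, early enough
        that the genuine chain tail stays longer than max_tip_edges.
        Expected: TER 11 -> 10, DER 10 -> 9, CEC 9 -> 1.
        """
        import numpy as np
        genome = olc.generate_unique_genome(550, 40, seed=41)
        spec = [(f"c{i:02d}", 50 * i, 100) for i in range(10)]
        spec[3] = ("c03", 150, 140)
        reads = tiled_reads(genome, spec)
        rng = np.random.default_rng(41)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        reads.append(olc.Read("spur", genome[160:220] + junk))
        graph = olc.build_graph(reads, olc.find_overlaps(reads, 40))
        assert graph.edge_count == 11

        reduced, stats = olc.reduce_pipeline(graph)
        counts = [(s.stage, s.edges_before, s.edges_after) for s in stats]
        assert counts == [("TER", 11, 10), ("DER", 10, 9), ("CEC", 9, 1)]
        edge = next(reduced.edges())
        assert reduced.spell_walk([edge.src, edge.dst]) == genome

    def test_monotone_stage_stats(self):
        for seed in range(8):
            graph = random_read_graph(seed, error_rate=0.01)
            _, stats = olc.reduce_pipeline(graph, olc.ReductionParams(der_cec_rounds=2))
            assert all(s.edges_after <= s.edges_before for s in stats)
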