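"""Shared fixtures: small sequence-grounded overlap graphs.

Every structural fixture here is built from actual DNA strings tiled from
a repeat-screened template, so edge verification in ``build_graph`` holds
and spelled walks reconstruct genuine template windows.
"""

from __future__ import annotations

import numpy as np
import pytest

import olcreduce as olc


def graph_edges(graph: olc.OverlapGraph) -> set[tuple[str, str]]:
    return {(e.src, e.dst) for e in graph.edges()}


def tiled_reads(genome: str, starts_lengths: list[tuple[str, int, int]]) -> list[olc.Read]:
    """Reads as named genome windows [(id, start, length), ...]."""
    return [olc.Read(rid, genome[s : s + ln]) for rid, s, ln in starts_lengths]


@pytest.fixture
def triangle():
    """Graph a->b (label 2), b->c (label 3), a->c (label 5): one transitive shortcut.

    Same-length reads at offsets 0, 2, 5 of a repeat-free 13 bp template;
    with min_overlap 3 exactly the three geometric overlaps appear.
    """
    genome = olc.generate_unique_genome(13, 3, seed=11)
    reads = tiled_reads(genome, [("a", 0, 8), ("b", 2, 8), ("c", 5, 8)])
    overlaps = olc.find_overlaps(reads, 3)
    graph = olc.build_graph(reads, overlaps)
    assert graph_edges(graph) == {("a", "b"), ("b", "c"), ("a", "c")}
    return graph, genome


def chain_reads(n: int, read_len: int = 12, stride: int = 4, seed: int = 7,
                prefix: str = "c") -> tuple[list[olc.Read], str, int]:
    """n reads tiling a repeat-free template; adjacent overlap = read_len - stride.

    Returns (reads, genome, min_overlap) where min_overlap admits only
    adjacent-tile overlaps.
    """
    length = stride * (n - 1) + read_len
    min_overlap = read_len - 2 * stride + 1  # excludes next-but-one tiles
    genome = olc.generate_unique_genome(length, min_overlap, seed=seed)
    reads = tiled_reads(genome, [(f"{prefix}{i:02d}", stride * i, read_len)
                                 for i in range(n)])
    return reads, genome, min_overlap


@pytest.fixture
def chain10():
    """Pure 10-read chain graph (9 edges) spelling its template."""
    reads, genome, mo = chain_reads(10)
    graph = olc.build_graph(reads, olc.find_overlaps(reads, mo))
    assert graph.edge_count == 9
    return graph, genome


def random_read_graph(seed: int, genome_len: int = 300, read_len: int = 50,
                      coverage: float = 4.0, error_rate: float = 0.0,
                      min_overlap: int = 12) -> olc.OverlapGraph:
    """Overlap graph of a small simulated read set (seeded)."""
    genome = olc.generate_genome(genome_len, seed=seed)
    ds = olc.sample_reads(genome, read_len, coverage, error_rate, seed=seed + 10_000)
    result = olc.overlap_reads(ds.reads, min_overlap)
    return olc.build_graph(result.kept_reads, result.overlaps)


def _junk(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def spur_fixture(n_spurs: int, seed: int = 5):
    """A 12-read chain with ``n_spurs`` short planted spurs and one long spur.

    Chain reads are 100 bp at stride 50 (adjacent overlap 50, min_overlap
    40).  Each short spur is a path of 1..3 tip reads hanging off a
    distinct chain read: the first tip read copies 60 genuine bases after
    the branch point and ends in random sequence, each further tip read
    extends the previous one by 50 random bases.  The long spur is built
    the same way with 5 tip reads, exceeding max_tip_edges=3.  Returns
    (graph, spur_edge_sets, long_spur_edges, min_overlap).
    """
    assert 1 <= n_spurs <= 5
    n_chain = 12
    rng = np.random.default_rng(seed)
    genome = olc.generate_unique_genome(50 * (n_chain - 1) + 100, 40, seed=seed)
    reads = [olc.Read(f"c{i:02d}", genome[50 * i : 50 * i + 100])
             for i in range(n_chain)]

    def plant(branch_idx: int, n_tip_reads: int, tag: str) -> list[tuple[str, str]]:
        p = 50 * branch_idx + 60  # overlap with the branch read is exactly 40
        tip0 = genome[p : p + 60] + _junk(rng, 40)
        tips = [tip0]
        for _ in range(1, n_tip_reads):
            tips.append(tips[-1][50:] + _junk(rng, 50))
        edges = [(f"c{branch_idx:02d}", f"{tag}0")]
        for i, seq in enumerate(tips):
            reads.append(olc.Read(f"{tag}{i}", seq))
            if i:
                edges.append((f"{tag}{i-1}", f"{tag}{i}"))
        return edges

    # branches sit early in the chain so the genuine chain tail behind the
    # last branch stays longer than max_tip_edges and is never clippable
    spur_edge_sets = []
    for k in range(n_spurs):
        spur_edge_sets.append(plant(1 + k, 1 + k % 3, f"s{k}_"))
    long_edges = plant(7, 5, "long_")

    result = olc.overlap_reads(reads, 40)
    graph = olc.build_graph(result.kept_reads, result.overlaps)
    chain_edges = {(f"c{i:02d}", f"c{i+1:02d}") for i in range(n_chain - 1)}
    expected = chain_edges | {e for s in spur_edge_sets for e in s} | set(long_edges)
    assert graph_edges(graph) == expected, "fixture construction drifted"
    return graph, [set(s) for s in spur_edge_sets], set(long_edges), 40
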