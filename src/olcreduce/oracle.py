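"""Brute-force oracles, deliberately independent of the production code paths.

Every oracle here recomputes its answer from first principles — all-pairs
string scans, all-triples transitivity tests, exhaustive walk enumeration —
sharing only the data types with the rest of the package.  They are the
reference against which the hash-table overlap finder and the marking-based
transitive reduction are verified, and they are only ever run on small
inputs (quadratic and worse costs are accepted by design).
"""

from __future__ import annotations

from .model import Overlap, OverlapGraph, Read


def brute_force_overlaps(reads: list[Read], min_overlap: int) -> list[Overlap]:
    """All-pairs, all-lengths suffix--prefix scan; maximal overlap per pair.

    For each ordered pair the lengths are scanned from ``min(len)`` down to
    ``min_overlap`` and the first (hence maximal) exact match is recorded.
    A maximal match spanning a whole read means containment, which the
    graph excludes upstream; such pairs contribute nothing.
    """
    overlaps: list[Overlap] = []
    for a in reads:
        for b in reads:
            if a.id == b.id:
                continue
            for L in range(min(a.length, b.length), min_overlap - 1, -1):
                if a.seq[-L:] == b.seq[:L]:
                    if L < a.length and L < b.length:
                        overlaps.append(Overlap(a.id, b.id, L))
                    break
    overlaps.sort()
    return overlaps


def brute_force_transitive_reduction(graph: OverlapGraph, fuzz: int = 0) -> OverlapGraph:
    """All-triples transitive reduction, decided against the original edge set.

    Edge a->c is removed iff some b gives edges a->b and b->c with
    ``label(a->b) + label(b->c) <= label(a->c) + fuzz``; every decision
    reads the input graph, so removals are simultaneous.
    """
    work = graph.copy()
    for e_ac in work.edges():
        for e_ab in work.out_edges(e_ac.src):
            b = e_ab.dst
            if b == e_ac.dst:
                continue
            if not work.has_edge(b, e_ac.dst):
                continue
            e_bc = work.edge(b, e_ac.dst)
            if e_ab.label_len + e_bc.label_len <= e_ac.label_len + fuzz:
                e_ac.marked = True
                break
    return work.subgraph_unmarked()


def enumerate_walk_language(graph: OverlapGraph, source: str, target: str,
                            max_edges: int) -> set[str]:
    """Spelled strings of every source->target walk of at most ``max_edges`` edges.

    Walks may revisit vertices (cycles count up to the edge bound); the
    zero-edge walk contributes ``seq(source)`` when source == target.
    Exponential in the worst case — small graphs only.
    """
    results: set[str] = set()

    def go(v: str, spelled: str, depth: int) -> None:
        if v == target:
            results.add(spelled)
        if depth == max_edges:
            return
        for e in graph.out_edges(v):
            go(e.dst, spelled + graph.edge_label(e), depth + 1)

    go(source, graph.read(source).seq, 0)
    return results


def walk_spells_string(graph: OverlapGraph, source: str, target: str,
                       text: str) -> bool:
    """True if some source->target walk spells exactly ``text``.

    Label-guided DFS: every edge label has length >= 1, so the consumed
    position strictly increases and memoising (vertex, position) pairs
    bounds the search by |V| * len(text).
    """
    start = graph.read(source).seq
    if not text.startswith(start):
        return False
    seen: set[tuple[str, int]] = set()

    def go(v: str, pos: int) -> bool:
        if v == target and pos == len(text):
            return True
        if (v, pos) in seen:
            return False
        seen.add((v, pos))
        for e in graph.out_edges(v):
            lab = graph.edge_label(e)
            end = pos + len(lab)
            if end <= len(text) and text[pos:end] == lab:
                if go(e.dst, end):
                    return True
        return False

    return go(source, len(start))
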