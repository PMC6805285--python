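"""Overlap-graph data model for OLC assembly.

Reads are vertices; a directed edge a -> b records that a suffix of ``a``
equals a prefix of ``b``.  The edge *label* is the novel sequence appended
when the edge is traversed: ``seq(b)`` with its first ``overlap_len``
characters dropped.  Spelling a walk therefore yields the assembled
sequence the walk represents, and every reduction pass below is judged by
whether it preserves the set of spellable sequences.

The graph is a simple directed graph: no atomic self-loops and at most one
edge per ordered vertex pair.  The single sanctioned exception is a
*composite* self-loop u -> u produced by contracting a cycle of simple
vertices anchored at u (a circular structure hanging off an anchor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import networkx as nx

from .errors import DuplicateIdError, GraphError

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A named DNA sequence over {A,C,G,T,N}; vertex payload of the graph."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.id!r}: invalid characters {sorted(bad)!r} "
                "(sequences must be uppercase A/C/G/T/N)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


class Overlap(NamedTuple):
    """An exact suffix->prefix overlap between two distinct reads.

    The suffix of the source of length ``overlap_len`` equals the prefix of
    the target of the same length; ``overlap_len`` is the maximal such
    length for the ordered pair.
    """

    source_id: str
    target_id: str
    overlap_len: int


@dataclass
class OverlapEdge:
    """Directed overlap edge, atomic or composite.

    ``label_len`` is the number of novel bases the edge contributes; for an
    atomic edge it is ``len(dst) - overlap_len`` and is at least 1 because
    contained reads are excluded upstream.  Composite edges (non-empty
    ``members``) carry the concatenated labels of the chain they replaced in
    ``label_seq`` and remember the chain's last overlap in
    ``dst_overlap_len`` so serialization can reconstruct anchor overlaps.
    """

    src: str
    dst: str
    overlap_len: int
    label_len: int
    marked: bool = False
    members: tuple[str, ...] = ()
    label_seq: str | None = None
    # overlap of the final atomic edge into dst; == overlap_len when atomic
    dst_overlap_len: int | None = None

    @property
    def is_composite(self) -> bool:
        return bool(self.members)

    def copy(self) -> "OverlapEdge":
        return OverlapEdge(
            self.src, self.dst, self.overlap_len, self.label_len,
            False, self.members, self.label_seq, self.dst_overlap_len,
        )


class OverlapGraph:
    """Directed overlap graph with marking support.

    Backed by a :class:`networkx.DiGraph` holding ``Read`` payloads on
    vertices and ``OverlapEdge`` payloads on edges.  Marks are pass-local
    scratch state used by the reduction passes; ``subgraph_unmarked``
    realises the mark-then-filter idiom and never propagates marks into its
    output.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_read(self, read: Read) -> None:
        if read.id in self._g:
            raise DuplicateIdError(f"duplicate read id {read.id!r}")
        self._g.add_node(read.id, read=read)

    def add_edge(self, edge: OverlapEdge) -> None:
        if edge.src not in self._g or edge.dst not in self._g:
            missing = edge.src if edge.src not in self._g else edge.dst
            raise GraphError(f"edge {edge.src}->{edge.dst}: unknown vertex {missing!r}")
        if edge.src == edge.dst and not edge.is_composite:
            raise GraphError(f"atomic self-loop {edge.src}->{edge.dst} is not allowed")
        if self._g.has_edge(edge.src, edge.dst):
            raise GraphError(f"duplicate edge {edge.src}->{edge.dst}")
        if edge.dst_overlap_len is None:
            edge.dst_overlap_len = edge.overlap_len
        self._g.add_edge(edge.src, edge.dst, edge=edge)

    # -- vertex / edge access -----------------------------------------

    def __contains__(self, vertex_id: str) -> bool:
        return vertex_id in self._g

    def read(self, vertex_id: str) -> Read:
        return self._g.nodes[vertex_id]["read"]

    def vertex_ids(self) -> list[str]:
        return list(self._g.nodes)

    def edge(self, src: str, dst: str) -> OverlapEdge:
        try:
            return self._g.edges[src, dst]["edge"]
        except KeyError:
            raise GraphError(f"no edge {src}->{dst}") from None

    def has_edge(self, src: str, dst: str) -> bool:
        return self._g.has_edge(src, dst)

    def edges(self) -> Iterator[OverlapEdge]:
        for _, _, data in self._g.edges(data=True):
            yield data["edge"]

    def out_edges(self, vertex_id: str) -> list[OverlapEdge]:
        return [d["edge"] for _, _, d in self._g.out_edges(vertex_id, data=True)]

    def in_edges(self, vertex_id: str) -> list[OverlapEdge]:
        return [d["edge"] for _, _, d in self._g.in_edges(vertex_id, data=True)]

    @property
    def vertex_count(self) -> int:
        return self._g.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self._g.number_of_edges()

    # -- degrees and structure ----------------------------------------

    def degrees(self) -> dict[str, tuple[int, int]]:
        """(in_degree, out_degree) per vertex, counting unmarked edges only."""
        result = {v: [0, 0] for v in self._g.nodes}
        for e in self.edges():
            if not e.marked:
                result[e.src][1] += 1
                result[e.dst][0] += 1
        return {v: (i, o) for v, (i, o) in result.items()}

    def weakly_connected_components(self) -> list[set[str]]:
        return [set(c) for c in nx.weakly_connected_components(self._g)]

    # -- marking / filtering ------------------------------------------

    def reset_marks(self) -> None:
        for e in self.edges():
            e.marked = False

    def subgraph_unmarked(self) -> "OverlapGraph":
        """New graph with all vertices and exactly the unmarked edges."""
        out = OverlapGraph()
        for v in self._g.nodes:
            out.add_read(self.read(v))
        for e in self.edges():
            if not e.marked:
                out.add_edge(e.copy())
        return out

    def copy(self) -> "OverlapGraph":
        out = OverlapGraph()
        for v in self._g.nodes:
            out.add_read(self.read(v))
        for e in self.edges():
            out.add_edge(e.copy())
        return out

    def without_vertices(self, vertex_ids: Iterable[str]) -> "OverlapGraph":
        drop = set(vertex_ids)
        out = OverlapGraph()
        for v in self._g.nodes:
            if v not in drop:
                out.add_read(self.read(v))
        for e in self.edges():
            if e.src not in drop and e.dst not in drop:
                out.add_edge(e.copy())
        return out

    # -- spelling ------------------------------------------------------

    def edge_label(self, edge: OverlapEdge) -> str:
        """Spelled extension contributed by traversing ``edge``."""
        if edge.label_seq is not None:
            return edge.label_seq
        return self.read(edge.dst).seq[edge.overlap_len:]

    def spell_walk(self, path: list[str]) -> str:
        """Spell the sequence of a walk given as a vertex-id list.

        Consecutive vertices must be joined by unmarked edges; the result
        is the first vertex's sequence extended by each edge's label.
        """
        if not path:
            raise GraphError("cannot spell an empty walk")
        for v in path:
            if v not in self._g:
                raise GraphError(f"unknown vertex {v!r} in walk")
        parts = [self.read(path[0]).seq]
        for a, b in zip(path, path[1:]):
            if not self._g.has_edge(a, b):
                raise GraphError(f"walk broken: no edge {a}->{b}")
            e = self.edge(a, b)
            if e.marked:
                raise GraphError(f"walk broken: edge {a}->{b} is marked")
            parts.append(self.edge_label(e))
        return "".join(parts)

    # -- diagnostics ---------------------------------------------------

    def check_invariants(self) -> None:
        """Raise GraphError if any structural invariant is violated."""
        for e in self.edges():
            if e.src == e.dst and not e.is_composite:
                raise GraphError(f"atomic self-loop {e.src}")
            if e.label_len < 1:
                raise GraphError(f"edge {e.src}->{e.dst}: label_len {e.label_len} < 1")
        degs = self.degrees()
        n_out = sum(o for _, o in degs.values())
        n_in = sum(i for i, _ in degs.values())
        unmarked = sum(1 for e in self.edges() if not e.marked)
        if not (n_out == n_in == unmarked):
            raise GraphError("in/out adjacency views inconsistent")

    def __repr__(self) -> str:
        return f"OverlapGraph(vertices={self.vertex_count}, edges={self.edge_count})"
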