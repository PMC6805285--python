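"""Overlap-graph reduction passes: TER, DER, CEC.

Each pass is a mark-then-filter transformation: edges (or chains) are
flagged on a working copy of the input graph and a subgraph of the
unflagged structure is returned, together with before/after edge counts.
Marks are pass-local and never leak into the output.

* **Transitive Edge Reduction (TER)** deletes an edge a->c whenever a
  two-edge path a->b->c spells the same extension (within ``fuzz`` bases):
  the shortcut is redundant for assembly.  The scan is the linear
  expected-time marking strategy for string graphs: per vertex, neighbours
  are examined in increasing label order and second-hop scans stop as soon
  as path lengths exceed the longest out-label, so each edge is touched a
  bounded number of times.  Removal itself requires the per-edge length
  inequality ``label(a->b) + label(b->c) <= label(a->c) + fuzz`` evaluated
  against the *original* edge set, which keeps the pass well defined even
  on graphs whose labels are not globally consistent (repeats).

* **Dead-End Removal (DER)** clips short spurs: maximal paths that dangle
  off a branch vertex and terminate at a vertex with no continuation.
  Spurs are the classic signature of sequencing errors and chimeric joins.
  A path that is an entire weakly-connected component has no branch anchor
  and is never clipped.

* **Composite Edge Contraction (CEC)** replaces every maximal chain of
  *simple* vertices (in-degree 1, out-degree 1) with a single composite
  edge carrying the concatenated labels — the unitig step.  Spelled
  sequences of walks are unchanged.  Cycles made entirely of simple
  vertices have no anchor endpoints; they are reported as circular
  components and left intact.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

from .errors import GraphError, ParameterError
from .model import OverlapEdge, OverlapGraph


@dataclass
class ReductionParams:
    """Thresholds for the reduction passes.

    ``fuzz`` is the slack (bp) tolerated in TER's length comparison; with
    exact overlaps the default 0 is the right choice and any transitive
    shortcut matches exactly.  ``max_tip_edges`` and ``max_tip_bp`` bound
    the edge count and spelled extension of a clippable dead-end;
    ``max_tip_bp=None`` means "2x the mean read length of the input graph",
    resolved when DER runs.  ``clip_sources`` additionally clips
    in-degree-0 source tips (the mirror image of sink spurs).
    ``der_cec_rounds`` repeats the DER->CEC pair to let clipping expose new
    chains.
    """

    fuzz: int = 0
    max_tip_edges: int = 3
    max_tip_bp: int | None = None
    clip_sources: bool = True
    der_cec_rounds: int = 1

    def __post_init__(self) -> None:
        if self.fuzz < 0:
            raise ParameterError(f"fuzz must be >= 0, got {self.fuzz}")
        if self.max_tip_edges < 1:
            raise ParameterError(f"max_tip_edges must be >= 1, got {self.max_tip_edges}")
        if self.max_tip_bp is not None and self.max_tip_bp < 0:
            raise ParameterError(f"max_tip_bp must be >= 0, got {self.max_tip_bp}")
        if self.der_cec_rounds < 1:
            raise ParameterError(f"der_cec_rounds must be >= 1, got {self.der_cec_rounds}")


@dataclass
class StageStats:
    """Edge bookkeeping for one reduction stage (one row of the run report)."""

    stage: str
    edges_before: int
    edges_after: int
    elapsed: float = 0.0
    #: CEC only: vertex ids of all-simple cycles left uncontracted
    circular_components: tuple[tuple[str, ...], ...] = ()
    #: CEC only: contractions skipped because the composite would collide
    skipped_contractions: int = 0

    @property
    def reduction_fraction(self) -> float:
        if self.edges_before == 0:
            return 0.0
        return 1.0 - self.edges_after / self.edges_before


def _check_atomic(graph: OverlapGraph, stage: str) -> None:
    for e in graph.edges():
        if e.is_composite:
            raise GraphError(
                f"{stage}: composite edge {e.src}->{e.dst} present; "
                "this pass must run before contraction"
            )


def transitive_reduce(graph: OverlapGraph, fuzz: int = 0) -> tuple[OverlapGraph, StageStats]:
    """Remove every transitive shortcut edge.

    An edge a->c is removed iff the original graph holds edges a->b and
    b->c with ``label(a->b) + label(b->c) <= label(a->c) + fuzz``.  All
    removal decisions are taken simultaneously against the input edge set.
    """
    if fuzz < 0:
        raise ParameterError(f"fuzz must be >= 0, got {fuzz}")
    _check_atomic(graph, "transitive_reduce")
    t0 = time.perf_counter()
    work = graph.copy()
    before = work.edge_count

    # deterministic sorted adjacency, computed once
    sorted_out: dict[str, list[OverlapEdge]] = {
        v: sorted(work.out_edges(v), key=lambda e: (e.label_len, e.dst))
        for v in work.vertex_ids()
    }
    for v in work.vertex_ids():
        out = sorted_out[v]
        if len(out) < 1:
            continue
        by_dst = {e.dst: e for e in out}
        longest = out[-1].label_len + fuzz
        for e_vw in out:
            for e_wx in sorted_out[e_vw.dst]:
                total = e_vw.label_len + e_wx.label_len
                if total > longest:
                    break
                shortcut = by_dst.get(e_wx.dst)
                if shortcut is not None and total <= shortcut.label_len + fuzz:
                    shortcut.marked = True

    reduced = work.subgraph_unmarked()
    stats = StageStats("TER", before, reduced.edge_count,
                       elapsed=time.perf_counter() - t0)
    return reduced, stats


def default_max_tip_bp(graph: OverlapGraph) -> int:
    """Default dead-end length cap: twice the mean read length of the graph."""
    ids = graph.vertex_ids()
    if not ids:
        return 0
    mean_len = sum(graph.read(v).length for v in ids) / len(ids)
    return 2 * math.ceil(mean_len)


def _sink_tip(work: OverlapGraph, degs, t: str, params: ReductionParams,
              max_bp: int | None) -> list[OverlapEdge] | None:
    """Clippable tip ending at sink ``t``, or None."""
    edges: list[OverlapEdge] = []
    spelled = 0
    u = t
    while True:
        e = work.in_edges(u)[0]
        edges.append(e)
        spelled += e.label_len
        if len(edges) > params.max_tip_edges:
            return None
        p = e.src
        if degs[p][1] >= 2:  # branch anchor
            if max_bp is not None and spelled > max_bp:
                return None
            return edges
        if degs[p] == (1, 1):
            u = p
            continue
        return None  # whole-component chain or unanchored join


def _source_tip(work: OverlapGraph, degs, s: str, params: ReductionParams,
                max_bp: int | None) -> list[OverlapEdge] | None:
    """Clippable tip starting at source ``s``, or None (mirror of sink tips)."""
    edges: list[OverlapEdge] = []
    spelled = 0
    u = s
    while True:
        e = work.out_edges(u)[0]
        edges.append(e)
        # novel prefix sequence the tip contributes relative to the anchor
        spelled += work.read(e.src).length - e.overlap_len
        if len(edges) > params.max_tip_edges:
            return None
        p = e.dst
        if degs[p][0] >= 2:  # convergence anchor
            if max_bp is not None and spelled > max_bp:
                return None
            return edges
        if degs[p] == (1, 1):
            u = p
            continue
        return None


def remove_dead_ends(graph: OverlapGraph,
                     params: ReductionParams | None = None) -> tuple[OverlapGraph, StageStats]:
    """Clip short dead-end spurs (sink tips, and source tips if configured).

    A sink tip is a maximal path of interior in-1/out-1 vertices hanging
    off a branch vertex (out-degree >= 2) and terminating at out-degree 0,
    with at most ``max_tip_edges`` edges and spelled extension at most
    ``max_tip_bp``.  All tips are identified against the input graph's
    degrees and clipped simultaneously.
    """
    params = params or ReductionParams()
    t0 = time.perf_counter()
    work = graph.copy()
    before = work.edge_count
    degs = work.degrees()
    max_bp = params.max_tip_bp
    if max_bp is None:
        max_bp = default_max_tip_bp(work)

    for v, (din, dout) in degs.items():
        if dout == 0 and din == 1:
            tip = _sink_tip(work, degs, v, params, max_bp)
            if tip:
                for e in tip:
                    e.marked = True
        if params.clip_sources and din == 0 and dout == 1:
            tip = _source_tip(work, degs, v, params, max_bp)
            if tip:
                for e in tip:
                    e.marked = True

    reduced = work.subgraph_unmarked()
    stats = StageStats("DER", before, reduced.edge_count,
                       elapsed=time.perf_counter() - t0)
    return reduced, stats


def _chain_members(path_edges: list[OverlapEdge]) -> tuple[str, ...]:
    members: list[str] = []
    for e in path_edges[:-1]:
        members.extend(e.members)
        members.append(e.dst)
    members.extend(path_edges[-1].members)
    return tuple(members)


def contract_composite_edges(graph: OverlapGraph) -> tuple[OverlapGraph, StageStats]:
    """Contract every maximal chain of simple vertices into one composite edge.

    The composite edge runs between the chain's two anchors (possibly the
    same vertex, yielding a composite self-loop for an anchored cycle),
    carries the interior read ids in ``members`` and the concatenated edge
    labels in ``label_seq``; spelled walk sequences are unchanged.
    All-simple cycles are reported, not contracted.
    """
    t0 = time.perf_counter()
    work = graph.copy()
    before = work.edge_count
    degs = work.degrees()
    simple = {v for v, (i, o) in degs.items()
              if i == 1 and o == 1 and not work.has_edge(v, v)}

    visited: set[str] = set()
    circular: list[tuple[str, ...]] = []
    merges: list[tuple[str, list[str], str]] = []
    for v in sorted(simple):
        if v in visited:
            continue
        # walk left to the head of the chain, detecting all-simple cycles
        left = v
        is_cycle = False
        while True:
            p = work.in_edges(left)[0].src
            if p == v:
                is_cycle = True
                break
            if p not in simple:
                break
            left = p
        if is_cycle:
            # predecessors returned to v: every vertex on the loop is simple
            cycle = [v]
            cur = work.in_edges(v)[0].src
            while cur != v:
                cycle.append(cur)
                cur = work.in_edges(cur)[0].src
            cycle.reverse()
            cycle = cycle[cycle.index(v):] + cycle[: cycle.index(v)]
            visited.update(cycle)
            circular.append(tuple(cycle))
            continue
        chain = [left]
        cur = left
        while True:
            n = work.out_edges(cur)[0].dst
            if n not in simple:
                break
            chain.append(n)
            cur = n
        visited.update(chain)
        u = work.in_edges(chain[0])[0].src
        w = work.out_edges(chain[-1])[0].dst
        merges.append((u, chain, w))

    existing_pairs = {(e.src, e.dst) for e in work.edges()}
    taken: set[tuple[str, str]] = set()
    drop: set[str] = set()
    composites: list[OverlapEdge] = []
    skipped = 0
    for u, chain, w in merges:
        if (u, w) in existing_pairs or (u, w) in taken:
            skipped += 1
            continue
        path_edges = [work.edge(u, chain[0])]
        path_edges += [work.edge(a, b) for a, b in zip(chain, chain[1:])]
        path_edges.append(work.edge(chain[-1], w))
        label_seq = "".join(work.edge_label(e) for e in path_edges)
        composites.append(OverlapEdge(
            src=u, dst=w,
            overlap_len=path_edges[0].overlap_len,
            label_len=sum(e.label_len for e in path_edges),
            members=_chain_members(path_edges),
            label_seq=label_seq,
            dst_overlap_len=path_edges[-1].dst_overlap_len,
        ))
        taken.add((u, w))
        drop.update(chain)

    reduced = work.without_vertices(drop)
    for e in composites:
        reduced.add_edge(e)
    stats = StageStats("CEC", before, reduced.edge_count,
                       elapsed=time.perf_counter() - t0,
                       circular_components=tuple(sorted(circular)),
                       skipped_contractions=skipped)
    return reduced, stats


def reduce_pipeline(graph: OverlapGraph,
                    params: ReductionParams | None = None
                    ) -> tuple[OverlapGraph, list[StageStats]]:
    """TER once, then ``der_cec_rounds`` repetitions of DER followed by CEC."""
    params = params or ReductionParams()
    stats: list[StageStats] = []
    g, s = transitive_reduce(graph, fuzz=params.fuzz)
    stats.append(s)
    for _ in range(params.der_cec_rounds):
        g, s = remove_dead_ends(g, params)
        stats.append(s)
        g, s = contract_composite_edges(g)
        stats.append(s)
    return g, stats
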