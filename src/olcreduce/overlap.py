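"""Exact suffix--prefix overlap detection and graph construction.

Overlaps are found with the prefix-indexing technique standard in
overlap-based assembly: every read's first ``min_overlap`` bases are keyed
in a hash table; sliding a ``min_overlap`` window over each read then
surfaces every candidate partner whose prefix could start at that offset,
and each candidate is verified by full string comparison.  For a window at
offset ``p`` in read ``a`` the implied overlap length is ``len(a) - p``, so
scanning offsets left to right yields the maximal overlap per ordered pair
first.  Matching is literal (N pairs only with N); error tolerance belongs
to upstream read correction.

Contained reads (whole-read substrings of another read, including exact
duplicates) are excluded before overlap enumeration: a contained read adds
no assembly information and would produce zero-label edges that break the
length arithmetic of transitive reduction.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .errors import GraphError, ParameterError
from .model import Overlap, OverlapEdge, OverlapGraph, Read

log = logging.getLogger(__name__)


@dataclass
class ReadFilterReport:
    """Accounting of reads excluded before graph construction."""

    total: int = 0
    short_skipped: list[str] = field(default_factory=list)
    #: duplicate id -> id of the first-seen read with the same sequence
    duplicates: dict[str, str] = field(default_factory=dict)
    #: contained id -> id of a read containing it
    contained: dict[str, str] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return len(self.short_skipped) + len(self.duplicates) + len(self.contained)


@dataclass
class OverlapResult:
    overlaps: list[Overlap]
    kept_reads: list[Read]
    filter_report: ReadFilterReport


def _check_unique_ids(reads: list[Read]) -> None:
    seen: set[str] = set()
    for r in reads:
        if r.id in seen:
            raise GraphError(f"duplicate read id {r.id!r}")
        seen.add(r.id)


def filter_reads(reads: list[Read], min_overlap: int) -> tuple[list[Read], ReadFilterReport]:
    """Drop reads shorter than ``min_overlap``, exact duplicates, and contained reads.

    First-seen ids win among duplicates.  Containment is detected with the
    same prefix hash table used for overlap finding, so only reads of
    length >= ``min_overlap`` participate (shorter ones are dropped anyway).
    """
    if min_overlap < 1:
        raise ParameterError(f"min_overlap must be >= 1, got {min_overlap}")
    _check_unique_ids(reads)
    report = ReadFilterReport(total=len(reads))

    long_enough: list[Read] = []
    for r in reads:
        if r.length < min_overlap:
            report.short_skipped.append(r.id)
        else:
            long_enough.append(r)
    if report.short_skipped:
        log.info("skipped %d reads shorter than min_overlap=%d",
                 len(report.short_skipped), min_overlap)

    # exact duplicates: keep first-seen
    by_seq: dict[str, str] = {}
    unique: list[Read] = []
    for r in long_enough:
        keeper = by_seq.get(r.seq)
        if keeper is not None:
            report.duplicates[r.id] = keeper
        else:
            by_seq[r.seq] = r.id
            unique.append(r)

    # containment: read b is a proper substring of some read a
    k = min_overlap
    prefix_index: dict[str, list[Read]] = defaultdict(list)
    for r in unique:
        prefix_index[r.seq[:k]].append(r)
    contained: dict[str, str] = {}
    for a in unique:
        s = a.seq
        for p in range(0, len(s) - k + 1):
            for b in prefix_index.get(s[p : p + k], ()):
                if b.id == a.id or b.id in contained:
                    continue
                if b.length < a.length and s[p : p + b.length] == b.seq:
                    contained[b.id] = a.id
    report.contained = contained
    kept = [r for r in unique if r.id not in contained]
    if report.duplicates or contained:
        log.info("excluded %d duplicate and %d contained reads",
                 len(report.duplicates), len(contained))
    return kept, report


def _maximal_overlaps(kept: list[Read], min_overlap: int) -> list[Overlap]:
    """All maximal suffix->prefix overlaps >= min_overlap among containment-free reads."""
    k = min_overlap
    prefix_index: dict[str, list[Read]] = defaultdict(list)
    for r in kept:
        prefix_index[r.seq[:k]].append(r)
    overlaps: list[Overlap] = []
    for a in kept:
        s = a.seq
        found: set[str] = set()
        for p in range(0, len(s) - k + 1):
            candidates = prefix_index.get(s[p : p + k])
            if not candidates:
                continue
            ov_len = len(s) - p
            for b in candidates:
                if b.id == a.id or b.id in found:
                    continue
                if ov_len <= b.length and s[p:] == b.seq[:ov_len]:
                    overlaps.append(Overlap(a.id, b.id, ov_len))
                    found.add(b.id)
    overlaps.sort()
    return overlaps


def overlap_reads(reads: list[Read], min_overlap: int) -> OverlapResult:
    """Filter reads and enumerate their maximal suffix--prefix overlaps."""
    kept, report = filter_reads(reads, min_overlap)
    return OverlapResult(_maximal_overlaps(kept, min_overlap), kept, report)


def find_overlaps(reads: list[Read], min_overlap: int) -> list[Overlap]:
    """Maximal exact suffix->prefix overlaps of length >= ``min_overlap``.

    One overlap per ordered read pair, at the maximal length; contained and
    duplicate reads are excluded first (see :func:`filter_reads`).
    """
    return overlap_reads(reads, min_overlap).overlaps


def build_graph(reads: list[Read], overlaps: list[Overlap]) -> OverlapGraph:
    """Assemble the overlap graph, verifying every overlap against the sequences.

    Overlaps are checked, not trusted: unknown ids, self-overlaps, failed
    suffix/prefix identity, or conflicting duplicate entries raise
    :class:`GraphError`.  Equal duplicate entries collapse to one edge.
    """
    _check_unique_ids(reads)
    graph = OverlapGraph()
    by_id = {r.id: r for r in reads}
    for r in reads:
        graph.add_read(r)
    seen: dict[tuple[str, str], int] = {}
    for ov in overlaps:
        src, dst, L = ov.source_id, ov.target_id, ov.overlap_len
        if src not in by_id or dst not in by_id:
            missing = src if src not in by_id else dst
            raise GraphError(f"overlap references unknown read id {missing!r}")
        if src == dst:
            raise GraphError(f"self-overlap on read {src!r} is not allowed")
        a, b = by_id[src], by_id[dst]
        if not (1 <= L <= min(a.length, b.length)):
            raise GraphError(f"overlap {src}->{dst}: length {L} out of range")
        if a.seq[-L:] != b.seq[:L]:
            raise GraphError(f"overlap {src}->{dst}: sequences do not match at length {L}")
        if L == b.length:
            raise GraphError(f"overlap {src}->{dst}: target contained in source "
                             "(contained reads must be excluded upstream)")
        prev = seen.get((src, dst))
        if prev is not None:
            if prev != L:
                raise GraphError(f"conflicting overlaps for pair {src}->{dst}: {prev} vs {L}")
            continue
        seen[(src, dst)] = L
        graph.add_edge(OverlapEdge(src=src, dst=dst, overlap_len=L,
                                   label_len=b.length - L))
    return graph


def degrees(graph: OverlapGraph) -> dict[str, tuple[int, int]]:
    """Per-vertex (in_degree, out_degree) over unmarked edges."""
    return graph.degrees()
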