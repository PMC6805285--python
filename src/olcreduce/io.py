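"""Serialization: FASTA/FASTQ reads, OVL1 overlap TSV, GFA 1.0 graphs, contigs.

The OVL1 dialect is a three-column TSV (``#source  target  overlap_len``)
used for the intermediate overlap list so overlap finding and reduction
can run as separate stages.

GFA output is plain GFA 1.0 restricted to S and L lines with single ``NM``
CIGAR overlaps.  Composite edges are emitted as an extra segment holding
the chain's spelled interior sequence, linked to its two anchors with the
chain's original terminal overlaps; re-reading such a file yields an
equivalent atomic graph whose spelled walks are unchanged.  All output
ordering is deterministic (lexicographic), so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO

from . import __version__
from .errors import DuplicateIdError, FormatError, ParseError
from .model import Overlap, OverlapEdge, OverlapGraph, Read
from .simulate import SyntheticDataset

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn"}
_FASTQ_EXT = {".fq", ".fastq"}


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _guess_format(path: str | Path) -> str:
    suffixes = [s.lower() for s in Path(path).suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes:
        if suffixes[-1] in _FASTA_EXT:
            return "fasta"
        if suffixes[-1] in _FASTQ_EXT:
            return "fastq"
    raise ParseError(f"cannot infer sequence format from {path!s}; pass format=")


def read_sequences(path: str | Path, format: str | None = None) -> list[Read]:
    """Parse reads from FASTA or FASTQ (gzip transparent).

    Ids are record headers up to the first whitespace; sequences are
    uppercased; characters outside A/C/G/T/N, duplicate ids, or malformed
    records raise with the offending record named.
    """
    fmt = format or _guess_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ParseError(f"unsupported format {fmt!r}; expected fasta or fastq")
    reads: list[Read] = []
    seen: set[str] = set()
    index = 0
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, fmt)
        while True:
            try:
                record = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(f"malformed {fmt} record #{index + 1}: {exc}") from exc
            index += 1
            rid = record.id
            if rid in seen:
                raise DuplicateIdError(f"duplicate read id {rid!r} (record #{index})")
            seen.add(rid)
            seq = str(record.seq).upper()
            try:
                reads.append(Read(rid, seq))
            except ValueError as exc:
                raise ParseError(f"record #{index} ({rid!r}): {exc}") from exc
    return reads


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reads_fastq(reads: list[Read], path: str | Path, quality: str = "I") -> None:
    with open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quality * r.length}\n")


# -- OVL1 overlap TSV -------------------------------------------------

OVL1_HEADER = "#source\ttarget\toverlap_len"


def write_overlaps_tsv(overlaps: list[Overlap], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(OVL1_HEADER + "\n")
        for ov in sorted(overlaps):
            fh.write(f"{ov.source_id}\t{ov.target_id}\t{ov.overlap_len}\n")


def read_overlaps_tsv(path: str | Path) -> list[Overlap]:
    overlaps: list[Overlap] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"OVL1 line {lineno}: expected 3 fields, got {len(fields)}")
            try:
                length = int(fields[2])
            except ValueError:
                raise ParseError(f"OVL1 line {lineno}: overlap_len {fields[2]!r} "
                                 "is not an integer") from None
            overlaps.append(Overlap(fields[0], fields[1], length))
    return overlaps


# -- GFA 1.0 ----------------------------------------------------------

_CIGAR_RE = re.compile(r"^(\d+)M$")


def _composite_name(edge: OverlapEdge) -> str:
    return f"cmp|{edge.src}|{edge.dst}"


def _composite_interior(graph: OverlapGraph, edge: OverlapEdge) -> str:
    """Spelled sequence of a composite edge's interior chain."""
    assert edge.is_composite and edge.label_seq is not None
    last_label = graph.read(edge.dst).length - (edge.dst_overlap_len or 0)
    head = graph.read(edge.src).seq[-edge.overlap_len:] if edge.overlap_len else ""
    return head + edge.label_seq[: len(edge.label_seq) - last_label]


def write_gfa(graph: OverlapGraph, path: str | Path) -> None:
    """Write GFA 1.0: S-lines for vertices (and composite interiors), L-lines for edges."""
    seg_lines: list[str] = []
    link_lines: list[tuple[str, str, str]] = []
    for v in sorted(graph.vertex_ids()):
        seg_lines.append(f"S\t{v}\t{graph.read(v).seq}\tLN:i:{graph.read(v).length}")
    composite_segs: list[str] = []
    for e in sorted(graph.edges(), key=lambda e: (e.src, e.dst)):
        if e.is_composite:
            name = _composite_name(e)
            interior = _composite_interior(graph, e)
            composite_segs.append(f"S\t{name}\t{interior}\tLN:i:{len(interior)}")
            link_lines.append((e.src, name, f"L\t{e.src}\t+\t{name}\t+\t{e.overlap_len}M"))
            link_lines.append((name, e.dst, f"L\t{name}\t+\t{e.dst}\t+\t{e.dst_overlap_len}M"))
        else:
            link_lines.append((e.src, e.dst, f"L\t{e.src}\t+\t{e.dst}\t+\t{e.overlap_len}M"))
    with open(path, "wt") as fh:
        fh.write(f"H\tVN:Z:1.0\tpg:Z:olcreduce-{__version__}\n")
        for line in seg_lines:
            fh.write(line + "\n")
        for line in sorted(composite_segs):
            fh.write(line + "\n")
        for _, _, line in sorted(link_lines):
            fh.write(line + "\n")


def read_gfa(path: str | Path) -> OverlapGraph:
    """Read the GFA dialect written by :func:`write_gfa` back into a graph.

    Every segment becomes a vertex (composite segments become plain
    vertices carrying their interior sequence), every link an atomic edge;
    suffix/prefix identity of each overlap is re-verified.  ``*`` sequences,
    complex CIGARs, and ``-`` orientations are unsupported dialects.
    """
    graph = OverlapGraph()
    links: list[tuple[int, str, str, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("H") or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise FormatError(f"GFA line {lineno}: truncated S-line")
                name, seq = fields[1], fields[2]
                if seq == "*":
                    raise FormatError(f"GFA line {lineno}: '*' sequences are unsupported")
                try:
                    graph.add_read(Read(name, seq.upper()))
                except (ValueError, DuplicateIdError) as exc:
                    raise FormatError(f"GFA line {lineno}: {exc}") from exc
            elif tag == "L":
                if len(fields) < 6:
                    raise FormatError(f"GFA line {lineno}: truncated L-line")
                src, s_or, dst, d_or, cigar = fields[1:6]
                if s_or != "+" or d_or != "+":
                    raise FormatError(
                        f"GFA line {lineno}: '-' orientation unsupported "
                        "(reverse-complement reads are plain vertices here)")
                m = _CIGAR_RE.match(cigar)
                if not m:
                    raise FormatError(f"GFA line {lineno}: unsupported CIGAR {cigar!r}")
                links.append((lineno, src, dst, int(m.group(1))))
    for lineno, src, dst, ov in links:
        if src not in graph or dst not in graph:
            missing = src if src not in graph else dst
            raise FormatError(f"GFA line {lineno}: L-line references unknown "
                              f"segment {missing!r}")
        a, b = graph.read(src), graph.read(dst)
        if not (1 <= ov <= min(a.length, b.length)) or a.seq[-ov:] != b.seq[:ov]:
            raise FormatError(f"GFA line {lineno}: overlap of {ov} bp between "
                              f"{src} and {dst} fails sequence verification")
        graph.add_edge(OverlapEdge(src=src, dst=dst, overlap_len=ov,
                                   label_len=b.length - ov))
    return graph


# -- contigs ----------------------------------------------------------

def _all_simple_cycles(graph: OverlapGraph) -> list[list[str]]:
    degs = graph.degrees()
    simple = {v for v, (i, o) in degs.items()
              if i == 1 and o == 1 and not graph.has_edge(v, v)}
    cycles: list[list[str]] = []
    visited: set[str] = set()
    for v in sorted(simple):
        if v in visited:
            continue
        cur, loop = v, [v]
        while True:
            nxt = graph.out_edges(cur)[0].dst
            if nxt == v:
                cycles.append(loop)
                visited.update(loop)
                break
            if nxt not in simple or nxt in visited:
                break
            loop.append(nxt)
            cur = nxt
    return cycles


def contig_records(graph: OverlapGraph) -> list[tuple[str, str]]:
    """Draft contig records (name-with-description, sequence) for a reduced graph.

    One record per edge between anchor vertices (its spelled walk), one per
    isolated vertex (singleton), and one rotation per all-simple cycle
    (circular).  Records are named ``contig_00001...`` by decreasing length
    then source id.
    """
    degs = graph.degrees()
    cycles = _all_simple_cycles(graph)
    cycle_vertices = {v for c in cycles for v in c}

    drafts: list[tuple[str, str, str]] = []  # (seq, sort_id, description)
    for e in sorted(graph.edges(), key=lambda e: (e.src, e.dst)):
        if e.src in cycle_vertices and e.dst in cycle_vertices:
            continue
        seq = graph.spell_walk([e.src, e.dst])
        drafts.append((seq, e.src, f"src={e.src} dst={e.dst} reads={len(e.members) + 2}"))
    for v in sorted(graph.vertex_ids()):
        if degs[v] == (0, 0):
            drafts.append((graph.read(v).seq, v, f"singleton={v}"))
    for cyc in cycles:
        # rotation of the circular sequence: concatenated labels around the loop
        parts = []
        order = cyc  # starts at the lexicographically smallest simple vertex
        for a, b in zip(order, order[1:] + [order[0]]):
            parts.append(graph.edge_label(graph.edge(a, b)))
        drafts.append(("".join(parts), order[0],
                       f"circular=true reads={len(cyc)}"))

    drafts.sort(key=lambda t: (-len(t[0]), t[1]))
    records = []
    for i, (seq, _, desc) in enumerate(drafts, start=1):
        records.append((f"contig_{i:05d} len={len(seq)} {desc}", seq))
    return records


def emit_contigs(graph: OverlapGraph, path: str | Path) -> int:
    """Write draft contigs as FASTA (layout only); returns the contig count."""
    records = contig_records(graph)
    write_fasta(records, path)
    return len(records)


def write_dataset(ds: SyntheticDataset, prefix: str | Path) -> dict[str, Path]:
    """Write a simulated dataset: genome FASTA, reads FASTQ, truth TSV."""
    prefix = str(prefix)
    paths = {
        "genome": Path(prefix + ".genome.fasta"),
        "reads": Path(prefix + ".reads.fastq"),
        "truth": Path(prefix + ".truth.tsv"),
    }
    write_fasta([("genome", ds.genome)], paths["genome"])
    write_reads_fastq(ds.reads, paths["reads"])
    with open(paths["truth"], "wt") as fh:
        fh.write("#id\tstart\tstrand\n")
        for r in ds.reads:
            fh.write(f"{r.id}\t{ds.truth_positions[r.id]}\t+\n")
    return paths
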