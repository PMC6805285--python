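"""End-to-end orchestration: reads -> overlaps -> graph -> TER -> DER -> CEC.

The CLI is a thin shell over :func:`run_pipeline`; everything here is
equally usable as a library call.  The run report mirrors the per-stage
edge-count tables an assembler operator expects: one row per executed
stage with edges before/after, plus the read-filtering and contig
accounting around them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError
from .model import OverlapGraph, Read, reverse_complement
from .overlap import OverlapResult, build_graph, overlap_reads
from .reduce import ReductionParams, StageStats, reduce_pipeline


@dataclass
class PipelineConfig:
    min_overlap: int = 40
    params: ReductionParams = field(default_factory=ReductionParams)
    add_rc: bool = False
    output_prefix: str = "olcreduce_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ParameterError(f"min_overlap must be >= 1, got {self.min_overlap}")


@dataclass
class RunReport:
    stages: list[StageStats] = field(default_factory=list)
    reads_total: int = 0
    reads_kept: int = 0
    short_skipped: int = 0
    duplicates_removed: int = 0
    contained_removed: int = 0
    overlaps_found: int = 0
    circular_components: int = 0
    skipped_contractions: int = 0
    final_vertices: int = 0
    final_edges: int = 0
    contig_count: int = 0
    contig_total_bp: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = [
            {"stage": s.stage, "edges_before": s.edges_before,
             "edges_after": s.edges_after, "elapsed": s.elapsed}
            for s in self.stages
        ]
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        with open(path, "rt") as fh:
            d = json.load(fh)
        stages = [StageStats(**s) for s in d.pop("stages", [])]
        return cls(stages=stages, **d)

    def stage_table(self) -> str:
        """Human-readable stage table (the #EDGE before/after rows)."""
        lines = ["stage\tedges_before\tedges_after\treduction_pct\telapsed_s"]
        for s in self.stages:
            lines.append(f"{s.stage}\t{s.edges_before}\t{s.edges_after}"
                         f"\t{100.0 * s.reduction_fraction:.2f}\t{s.elapsed:.3f}")
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            fh.write(self.stage_table() + "\n")


def add_reverse_complements(reads: list[Read]) -> list[Read]:
    """Double a read set with reverse complements (ids suffixed ``/rc``).

    Represents both strands in the simple directed graph formalism without
    bidirected edges.
    """
    doubled = list(reads)
    for r in reads:
        doubled.append(Read(f"{r.id}/rc", reverse_complement(r.seq)))
    return doubled


def run_pipeline(reads: list[Read],
                 config: PipelineConfig | None = None
                 ) -> tuple[OverlapGraph, RunReport, OverlapResult]:
    """Full reduction pipeline on an in-memory read set."""
    config = config or PipelineConfig()
    if config.add_rc:
        reads = add_reverse_complements(reads)
    result = overlap_reads(reads, config.min_overlap)
    graph = build_graph(result.kept_reads, result.overlaps)
    reduced, stages = reduce_pipeline(graph, config.params)

    rep = result.filter_report
    report = RunReport(
        stages=stages,
        reads_total=rep.total,
        reads_kept=len(result.kept_reads),
        short_skipped=len(rep.short_skipped),
        duplicates_removed=len(rep.duplicates),
        contained_removed=len(rep.contained),
        overlaps_found=len(result.overlaps),
        circular_components=sum(len(s.circular_components) for s in stages),
        skipped_contractions=sum(s.skipped_contractions for s in stages),
        final_vertices=reduced.vertex_count,
        final_edges=reduced.edge_count,
    )
    return reduced, report, result


def reduce_graph(graph: OverlapGraph,
                 params: ReductionParams | None = None
                 ) -> tuple[OverlapGraph, RunReport]:
    """Run the reduction stages on an already-built graph."""
    reduced, stages = reduce_pipeline(graph, params or ReductionParams())
    report = RunReport(
        stages=stages,
        circular_components=sum(len(s.circular_components) for s in stages),
        skipped_contractions=sum(s.skipped_contractions for s in stages),
        final_vertices=reduced.vertex_count,
        final_edges=reduced.edge_count,
    )
    return reduced, report
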