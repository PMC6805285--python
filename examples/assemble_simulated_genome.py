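"""Assemble a simulated 10 kb genome end to end.

Simulates 20x error-free 100 bp reads from a repeat-free genome, builds
the exact suffix-prefix overlap graph, and reduces it with TER -> DER ->
CEC.  The printed stage table shows the edge count collapsing: TER strips
the ~90% of edges that are transitive shortcuts, and CEC contracts the
surviving chain into a single composite edge whose spelled sequence is
the genome, base for base.
"""

import olcreduce as olc

genome = olc.generate_unique_genome(10_000, 40, seed=1)
dataset = olc.sample_reads(genome, read_len=100, coverage=20, error_rate=0.0, seed=2)

reduced, report, _ = olc.run_pipeline(dataset.reads, olc.PipelineConfig(min_overlap=40))
print(report.stage_table())

edge = next(reduced.edges())
contig = reduced.spell_walk([edge.src, edge.dst])
print(f"final graph: {reduced.vertex_count} vertices, {reduced.edge_count} edge")
print(f"contig length: {len(contig)} bp; identical to genome: {contig == genome}")
print(f"reads subsumed by the composite edge: {len(edge.members) + 2}")
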