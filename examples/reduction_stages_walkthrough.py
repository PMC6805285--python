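"""Watch each reduction pass act on a hand-sized graph.

Ten 100 bp reads tile a 550 bp template at 50 bp stride.  One read is
lengthened so it also reaches the read after next (a transitive
shortcut), and one corrupted-tail read dangles off the chain (a spur).
TER deletes exactly the shortcut, DER exactly the spur, and CEC rolls the
remaining pure chain into one composite edge.
"""

import numpy as np

import olcreduce as olc

genome = olc.generate_unique_genome(550, 40, seed=41)
layout = [(f"c{i:02d}", 50 * i, 100) for i in range(10)]
layout[3] = ("c03", 150, 140)  # long read: overlaps both c04 and c05
reads = [olc.Read(rid, genome[s : s + ln]) for rid, s, ln in layout]

rng = np.random.default_rng(41)
junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
reads.append(olc.Read("spur", genome[160:220] + junk))  # dead end off c02

graph = olc.build_graph(reads, olc.find_overlaps(reads, min_overlap=40))
print(f"initial graph: {graph.edge_count} edges")

for stage_fn, note in [
    (lambda g: olc.transitive_reduce(g), "shortcut c03->c05 spelled by c03->c04->c05"),
    (lambda g: olc.remove_dead_ends(g), "spur read has no continuation"),
    (lambda g: olc.contract_composite_edges(g), "chain interior is unambiguous"),
]:
    graph, stats = stage_fn(graph)
    print(f"{stats.stage}: {stats.edges_before} -> {stats.edges_after} edges ({note})")

edge = next(graph.edges())
print(f"composite edge {edge.src} -> {edge.dst} carries {len(edge.members)} interior reads")
print("spelled sequence equals the template:",
      graph.spell_walk([edge.src, edge.dst]) == genome)
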