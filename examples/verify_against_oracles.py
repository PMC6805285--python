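"""Cross-check the fast paths against definitional brute-force oracles.

The hash-table overlap finder is compared with an all-pairs, all-lengths
scan, and the marking-based transitive reduction with an all-triples
test, on a stream of seeded random instances.  Any disagreement would
print the offending instance; complete agreement is the expected output.
"""

import numpy as np

import olcreduce as olc

rng = np.random.default_rng(99)
overlap_ok = ter_ok = trials = 0
for _ in range(50):
    genome = olc.generate_genome(int(rng.integers(150, 300)), seed=int(rng.integers(2**31)))
    ds = olc.sample_reads(genome, 50, 3.0, float(rng.choice([0.0, 0.02])),
                          seed=int(rng.integers(2**31)))
    kept, _ = olc.filter_reads(ds.reads, 15)
    fast = sorted(olc.find_overlaps(ds.reads, 15))
    brute = sorted(olc.brute_force_overlaps(kept, 15))
    overlap_ok += fast == brute

    graph = olc.build_graph(kept, fast)
    reduced, _ = olc.transitive_reduce(graph, fuzz=0)
    oracle = olc.brute_force_transitive_reduction(graph, fuzz=0)
    fast_edges = {(e.src, e.dst) for e in reduced.edges()}
    oracle_edges = {(e.src, e.dst) for e in oracle.edges()}
    ter_ok += fast_edges == oracle_edges
    if fast_edges != oracle_edges:
        print("TER mismatch:", fast_edges ^ oracle_edges)
    trials += 1

print(f"overlap finder vs all-pairs scan: {overlap_ok}/{trials} instances agree")
print(f"transitive reduction vs all-triples oracle: {ter_ok}/{trials} instances agree")
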