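# olcreduce

Overlap-graph construction and reduction for overlap-layout-consensus
(OLC) genome assembly, as a single-machine Python library and CLI.

In OLC assembly, sequencing reads become the vertices of a directed
*overlap graph*: an edge a → b records that a suffix of read *a* equals a
prefix of read *b* (an exact suffix–prefix overlap of at least
`min_overlap` bases).  The edge's **label** is the novel sequence the
edge appends, `seq(b)` minus its first `overlap_len` characters, so
spelling any walk through the graph reconstructs an assembled sequence.
Raw overlap graphs are enormously redundant — at coverage *c* each read
overlaps ~*c* successors — and `olcreduce` shrinks them with the three
classic string-graph reductions, in order:

1. **Transitive Edge Reduction (TER).**  An edge a → c is redundant when
   edges a → b and b → c exist with
   `label(a→b) + label(b→c) ≤ label(a→c) + fuzz`: the two-edge path
   spells the same sequence.  TER deletes every such shortcut using a
   per-vertex marking scan in the style of the linear expected-time
   string-graph algorithm (neighbours visited in increasing label order,
   second-hop scans cut off at the longest out-label).
2. **Dead-End Removal (DER).**  Short spurs — hanging paths of at most
   `max_tip_edges` edges and `max_tip_bp` spelled bases that leave a
   branch vertex and terminate with no continuation — are the signature
   of sequencing errors and chimeric joins; DER clips them (on both the
   sink and the source side by default).
3. **Composite Edge Contraction (CEC).**  Every maximal chain through
   *simple* vertices (in-degree 1, out-degree 1) is replaced by a single
   composite edge carrying the concatenated labels — the unitig step.
   Spelled sequences are unchanged.

The package also bundles a seeded genome/read simulator with ground-truth
layout, and brute-force oracles (all-pairs overlap scan, all-triples
transitive reduction, exhaustive walk-language enumeration) against which
the fast implementations are verified.

Scope ends at the reduced graph and a draft edge-per-contig layout:
consensus polishing, inexact overlaps, and bidirected (strand-aware)
graphs are out of scope.  Both strands can still be represented by
doubling the read set with reverse complements (`--add-rc`).

## Worked example

`examples/assemble_simulated_genome.py` simulates 20× error-free 100 bp
reads of a repeat-free 10 kb genome and runs the full pipeline:

```
stage   edges_before    edges_after     reduction_pct   elapsed_s
TER     19997           1821            90.89           0.132
DER     1821            1821            0.00            0.016
CEC     1821            1               99.95           0.033
final graph: 2 vertices, 1 edge
contig length: 10000 bp; identical to genome: True
reads subsumed by the composite edge: 1822
```

Reading the table: the raw graph holds ~20,000 edges because every read
overlaps about ten successors; TER keeps only the nearest-successor
edges (90.89% removed); nothing dangles, so DER is idle; CEC contracts
the remaining 1,821-edge chain into one composite edge whose spelled
sequence reproduces the genome exactly.

The same run from the shell:

```sh
olcreduce simulate --genome-len 10000 --read-len 100 --coverage 20 \
    --seed 1 --repeat-free-k 40 --out sim
olcreduce pipeline --reads sim.reads.fastq --min-overlap 40 --out run
olcreduce stats run.report.json
```

which writes `run.gfa` (GFA 1.0 graph), `run.contigs.fasta`,
`run.ovl.tsv` (the `#source target overlap_len` overlap list), and
`run.report.json` / `.tsv` (the stage table above).

See also `examples/reduction_stages_walkthrough.py` (each pass acting on
an 11-edge hand-sized graph) and `examples/verify_against_oracles.py`
(oracle cross-checks).

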