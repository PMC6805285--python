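# Methods

## The graph model

Reads are vertices; a directed edge a → b asserts that the suffix of
`seq(a)` of length `overlap_len` equals the prefix of `seq(b)` exactly,
with `overlap_len ≥ min_overlap` and, per ordered pair, *maximal* (the
string-graph convention; it makes the length arithmetic of transitive
reduction consistent).  The edge label — `seq(b)` minus its first
`overlap_len` bases — is the novel sequence appended by traversing the
edge, so the spelled sequence of a walk is
`seq(v₁) + label(e₁) + … + label(eₖ)`.  Every reduction pass is judged
against this spelling semantics: TER and CEC must preserve the set of
spellable strings between anchor vertices, DER deliberately discards the
strings of clipped spurs and nothing else.

The graph is simple and directed.  Reverse-complement overlaps and
bidirected string-graph edges are not modelled; to represent both
strands, the read set can be doubled with reverse complements (ids
suffixed `/rc`), which keeps every algorithm unchanged.  The one
sanctioned self-loop is a *composite* self-loop produced by contracting
a cycle of simple vertices anchored at one junction vertex; atomic
self-loops are forbidden.

Matching is literal character equality over {A,C,G,T,N} (N matches only
N).  Error tolerance belongs to upstream read correction, not to the
overlap step.

### Read filtering

Before graph construction, three classes of reads are excluded and
counted in the run report: reads shorter than `min_overlap`; exact
duplicates (first-seen id kept); and contained reads — whole-read
substrings of another read.  A contained read would produce an edge with
label length ≤ 0, breaking the length bookkeeping of transitive
reduction, and contributes no assembly information; exclusion is
standard string-graph practice.

### Overlap detection

Every read's first `min_overlap` bases are keyed in a hash table.
Sliding a `min_overlap`-wide window across read *a* surfaces every
candidate *b* whose prefix could start at that offset; a full string
comparison verifies the candidate, and scanning offsets left-to-right
yields the maximal overlap per ordered pair first.  Cost is
O(total bases) lookups plus verification of true candidates, against the
quadratic all-pairs scan kept as the oracle.

## Transitive edge reduction

The declarative contract: edge a → c is removed iff the *input* edge set
contains a → b and b → c with
`label(a→b) + label(b→c) ≤ label(a→c) + fuzz`; all decisions are
simultaneous.  The implementation is a per-vertex marking scan in the
style of the linear expected-time string-graph algorithm: out-neighbours
are ranked by (label, id); second-hop scans stop once the path length
exceeds the longest out-label plus fuzz.  Two deliberate choices
strengthen the classical scan:

- every out-neighbour may serve as the middle vertex *b*, even if its
  own edge is also being removed (removal decisions read the original
  edge set), and
- elimination requires the per-edge length inequality above, not merely
  reachability under the length cutoff.

On length-consistent graphs (exact overlaps of reads from a
repeat-free template) the two formulations coincide; on inconsistent
graphs — repeats can make the maximal a → c overlap longer than the
positional offset implies — the per-edge check keeps the pass well
defined and exactly equal to the all-triples oracle.  With fuzz 0 and
exact overlaps, removal implies the shortcut and the two-edge path spell
the identical string, so TER is sequence-preserving; the default fuzz is
therefore 0, with the parameter exposed for graphs whose labels carry
residual inconsistency.

## Dead-end removal

A sink tip is a maximal path v₁ → … → vₖ with vₖ of out-degree 0, every
interior vertex of in/out-degree (1,1), entered from a branch vertex
(out-degree ≥ 2), with at most `max_tip_edges` edges and spelled
extension (sum of tip labels) at most `max_tip_bp`.  Source tips — the
mirror image, anchored at a vertex of in-degree ≥ 2 — are clipped
symmetrically by default (`clip_sources`), since a directed graph of a
linear genome is front/back symmetric; their spelled extension is the
novel prefix each edge's source contributes.  All tips are identified
against the input graph's degrees and clipped simultaneously; a path
that is an entire weakly-connected component has no branch anchor and is
never clipped.  Isolated vertices are retained — they may be singleton
contigs.

Thresholds: tip length criteria only.  `max_tip_edges` defaults to 3 and
`max_tip_bp` to twice the mean read length of the graph (resolved when
the pass runs), standard assembler tip-clipping scale — long enough to
catch error tails, far shorter than any genuine alternative path.  No
coverage test is applied: per-read multiplicity is not available after
deduplication, a known limitation.

One consequence of the anchoring rule worth knowing: a genuine chain
terminus *becomes* a clippable tip if a branch vertex sits within
`max_tip_edges` of it — clipping is a topological judgement, not a truth
judgement.  The planted-spur tests place their spurs accordingly.

## Composite edge contraction

Maximal chains u → r₁ → … → rₖ → w with every rᵢ simple and u, w not
simple are replaced by one composite edge u → w: `members = (r₁…rₖ)`,
`label_seq` the concatenation of the chain's edge labels, `label_len`
their sum; interior vertices are deleted.  Spelled walks are unchanged
by construction.  Contraction composes: a chain whose edges are already
composite merges members and labels transitively, which is what makes
repeated DER → CEC rounds (`der_cec_rounds`) safe.

Two boundary cases are resolved conservatively:

- **All-simple cycles** (an isolated circular chain) have no anchor
  endpoints; they are reported as circular components and left intact
  rather than broken at an arbitrary point.  `emit_contigs` writes one
  full-turn rotation per such cycle, flagged `circular=true`.
- **Collisions**: if the composite u → w would duplicate an existing
  edge (possible when fuzz > 0 leaves a parallel shortcut, or u == w
  twice), the chain is left uncontracted and counted in
  `skipped_contractions`, preserving the one-edge-per-pair invariant.

Anchored cycles (u == w) do contract, into a composite self-loop.

## Pipeline order

TER runs first (it requires an atomic graph and benefits most from full
edge information), then `der_cec_rounds` repetitions of DER followed by
CEC — one round by default; extra rounds let clipping expose new chains.
Marks are pass-local scratch state, reset between stages; each stage
returns a fresh subgraph plus a `StageStats` row (edges before/after,
wall-clock seconds — timing is informational only and never asserted).

## The simulator and what passing tests show

`generate_genome` draws i.i.d. bases with a GC control;
`generate_unique_genome` rescreens (incrementing the seed) until no
exact k-mer repeat exists, giving templates whose overlap graphs are
length-consistent and uniquely assemblable — the regime where "one
composite edge spelling the genome" is the provably right answer.
`sample_reads` draws `ceil(coverage·G/L)` fixed-length reads at seeded
start positions with i.i.d. substitution errors (no indels: overlap
matching is exact and correction is assumed upstream), recording
pre-error truth positions.

For linear genomes the sampler anchors one read at each terminus by
default (`anchor_ends`): under purely uniform starts each genome end is
uncovered with probability ≈ e^(−c/L), and a terminal gap truncates the
reconstruction for a reason that says nothing about the graph
algorithms.  Circular sampling is purely uniform.

The simulator emulates exact-overlap structure only.  Real data bring
indels, coverage bias, chimeras, and genuine repeats longer than
`min_overlap`; passing tests therefore demonstrate the correctness of
the graph transformations, not assembly quality on real libraries.
Repeats are reintroduced deliberately in adversarial fixtures (staggered
tilings, periodic strings) to exercise the inconsistent-label paths.

## Verification strategy

Every fast path has a definitionally independent oracle sharing only the
data types: the all-pairs overlap scan, the all-triples transitive
reduction, exhaustive walk-language enumeration, and a label-guided
matcher deciding whether a given string is spellable between two
vertices (memoised on (vertex, position), so it is exact and linear in
|V|·|string|).  Test problem sizes — 200 random graphs of ≤ 25 vertices
for TER equivalence, 100 read sets of ≤ 30 reads for overlap
equivalence, 50 graphs of ≤ 20 vertices for sequence preservation, a
10 kb genome at 20× for end-to-end recovery — keep brute-force costs
trivial while covering the combinatorial space; each instance is seeded
and reproducible.

## Serialization

GFA 1.0, restricted to S/L lines with single `NM` CIGARs and `+`
orientations.  Composite edges are written as an extra segment holding
the chain's spelled interior sequence, linked to both anchors with the
chain's terminal overlaps — re-reading gives an equivalent atomic graph
with identical spelled walks (exact round-trip for atomic graphs).
Overlap identity is re-verified on read.  All output ordering is
lexicographic, so identical inputs give byte-identical files; report
JSON timing fields are the one nondeterministic exception and are
excluded from determinism checks.

## Known limitations

- No inexact overlaps, no bidirected graphs, no bubble popping or
  coverage-based repeat resolution; contigs are layouts (spelled edges),
  not polished consensus.
- DER has no coverage signal (see above).
- The overlap TSV and GFA dialects are deliberately minimal; PAF/MHAP
  ingestion is out of scope.
- Brute-force oracles and walk enumeration are exponential/quadratic by
  design and must not be pointed at large graphs.
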