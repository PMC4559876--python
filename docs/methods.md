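# Methods

## Model and procedure

`sremine` discovers combinatorial splicing regulatory elements in three
stages over a k-dimensional de Bruijn graph on the DNA alphabet.

**Graph and ranking.**  Vertices are all 4^k k-mers; a directed edge joins
*u* to *v* when they overlap in k−1 nucleotides, so |V| = 4^k and
|E| = 4^(k+1) (each vertex has out-degree exactly 4, counting the self-loop
on each homopolymer).  The graph is never materialised beyond vertex
membership: edges are recomputed from the vertex strings, which makes
vertex-induced subgraphs exact by construction.  Every k-mer gets a rank by
descending enrichment score; k-mers labelled neutral are defined to score
0, and any nonzero score supplied for a neutral row is coerced before
ranking.  Score ties are broken lexicographically (A < C < G < T) — the
evidence does not order tied k-mers, and a deterministic ranking is worth
more than a pretence of resolution.  The top R ranks induce the enhancer
SRE graph, the bottom R the silencer graph; with all scores distinct and
2R ≤ 4^k the two vertex sets are disjoint.

**Occurrence profile.**  Presence of a k-mer in an exon is evaluated on a
fixed window (default: the first 50 nt; the last 50 nt selectable), exact
substring matching, multiplicity discarded.  Windows are uppercased; the
ambiguity code N, or any non-ACGT character, matches nothing — a
conservative choice that cannot invent elements.  Exons shorter than the
window contribute what they have; exons shorter than k remain columns with
empty support.  Sequences are used as given (sense strand); no
reverse-complement scanning, since exonic SREs act on the pre-mRNA sense
sequence.  All reported coordinates are 1-based inclusive.

**Level 1 — maximal α-cohesive subgraphs.**  Vertices whose own support is
below α are pruned up front (sound by anti-monotonicity of T).  From each
surviving vertex, subgraphs grow depth-first through adjacent vertices
while the shared support stays ≥ α; visited vertex sets are memoised by
canonical form (sorted k-mer tuple), so each subgraph expands once.
Adjacency and connectivity are evaluated on the *undirected* graph with
self-loops ignored: element co-occurrence has no direction semantics, and
a self-loop neither connects a vertex to a neighbour nor extends a path.
Maximality is tested against *all* adjacent vertices, not just those ahead
in the traversal — this makes local maximality equivalent to the global
definition, because any cohesive connected supergraph implies a cohesive
one-vertex extension.  Overlapping MCSs sharing vertices are all kept
(partially overlapping subgraphs are distinct elements with common
nucleotides); strict subset pairs cannot both be maximal, so outputs form
an antichain.  IDs are assigned after mining, in canonical vertex-set
order, so downstream enumeration never depends on traversal order.

**Level 2 — MCS collections.**  Enhancer and silencer MCSs are combined
into one table (profiles for both types are built against the same exon
windows, so cross-type intersections are well defined) and re-identified
canonically.  Collections are enumerated over an ordered set-enumeration
tree: a collection extends only by IDs above its current maximum, so every
ID subset arises exactly once, and a branch dies the moment its shared
exon set drops below θ.  The tree is an implementation detail; the output
contract is the exact set { M : |M| ≥ β, |T(M)| ≥ θ }, which the tests
verify against exhaustive subset enumeration.  All qualifying collections
are reported (reported sets are downward-closed above size β); a
`maximal_only` convenience filter is available and off by default.

**Filtering.**  Each member MCS is spelled by depth-first traversal of its
induced subgraph into all maximal simple-path sequences; spellings that
are substrings of another retained spelling are dropped, and a singleton
spells itself.  For each exon shared by a collection, every occurrence of
every spelled sequence is located (all offsets, overlaps allowed — using
all occurrences avoids an arbitrary pick and is reproducible).  Same-type
occurrences overlapping by ≥ 1 nt are merged transitively; the merged
element's sequence is read off the exon itself over the union span
[a, max(b, d)], so chains of m consecutive k-mers yield (m+k−1)-mers and
no re-scoring against the score table is needed or done.  Adjacency
without a shared position does not merge.  Enhancer/silencer overlaps are
never merged.  The exon's resulting element multiset is its candidate SRE
set; identical candidates aggregate across exons, and a candidate is
emitted when it retains ≥ 2 elements and is witnessed by ≥ θ exons — the
same θ that mined the collections.  A layout that collapses into one long
element eliminates that exon's contribution entirely.

Both overlap interpretations are first-class: with merging disabled the
per-exon candidate is the set of distinct spelled sequences present in the
window (so, absent cross-type overlaps, output sets equal the collection's
spelled sequences verbatim).  Candidate identity differs deliberately
between the modes — a multiset of post-merge layout elements in merged
mode (two disjoint copies of one element are a real layout feature), a
presence set in unmerged mode (occurrence counts carry no meaning when
nothing is merged).

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 6 | k-mer length; the graph has 4^k vertices |
| R | 400 | vertices per SRE graph (top/bottom of the ranking) |
| α | 1000 | minimum exons shared by an MCS's vertices |
| θ | 100 | minimum exons shared by a collection, and by a final SRE set |
| β | 2 | minimum MCSs per collection (2 = at least pairs) |
| W | 50 nt | analysis window length |
| window end | first | first or last W nt of each exon |
| merge_same_type | on | merged vs. unmerged overlap interpretation |

The defaults are the reference conditions for genome-scale exon sets
(hundreds of thousands of exons).  α, θ and β are independent thresholds;
α ≥ θ is not required.  On the synthetic study conditions used by the test
suite (thousands of exons), α and θ of 100 play the same role relative to
the background support (≈ n_exons × 45/4096 exons per hexamer).

## Synthetic data

The generator emulates the pipeline's study conditions, not real biology:

* **Score table** — all 4^k rows; 1182 enhancer-labelled and 1090
  silencer-labelled k-mers by default (the scale of published minigene
  hexamer screens), scores uniform in (0.05, 1.5) / (−1.5, −0.05), neutral
  rows 0.  Boost k-mers draw from (1.6, 2.0) / (−2.0, −1.6), strictly
  beyond the background, guaranteeing membership in the top-R/bottom-R
  regions for any R ≥ the boost count.
* **Exons** — fixed-length (default 50 nt, one whole window) uniform
  random sequences (composition configurable); each planted motif set is
  overlaid, non-overlapping, into a consecutive block of exactly
  `co_occurrence_count` exons.  Rejection sampling enforces the exact
  planting contract: a planted exon carries each of its motifs exactly once
  (counting overlapping occurrences) and no other set's full complement; a
  background exon may carry individual planted motifs by chance (that keeps
  their supports realistic) but never a complete set.  Everything is
  reproducible from the seed, and FASTA output is byte-deterministic.

What the generator does *not* emulate: real exon length variation, biased
base composition and codon structure, correlated hexamer occurrences, or
scores estimated with measurement noise.  Passing the planted-recovery and
negative-control tests therefore demonstrates algorithmic correctness and
statistical discrimination under uniform background — not performance on
genomic sequence, where background co-occurrence is structured.

## Numerical and design choices

* Determinism everywhere: explicit canonical sorts before every ID
  assignment and every file write; fixed config + inputs reproduce
  byte-identical outputs, with no timestamps in stage files.
* Degenerate inputs: empty vertex sets give empty profiles; T(∅) is the
  full exon universe (neutral element of intersection); an all-pruned
  graph mines to an empty MCS table; empty tables propagate to header-only
  TSVs that round-trip.
* Duplicate exon IDs, duplicate k-mer rows, non-ACGT k-mers and malformed
  tables fail fast with stage-labelled errors rather than degrading.
* Missing k-mers in a score table may be auto-filled as neutral (on by
  default) since neutral-and-zero is their definition; strict mode is a
  flag away.
* The test suite and acceptance checks run the pipeline at thousands of
  exons with α = θ = 100 — the same geometry as the genome-scale defaults
  (planted support ≈ 1.7 × α, background ≈ 0.2 × α), chosen so every suite
  exercises all pruning paths.

## Known limitations

* Subgraph growth and path spelling are exponential in the worst case;
  they are fast in practice because cohesion keeps MCSs small (real
  elements are 6–7-mers, i.e. 1–2 vertices), but adversarial dense
  subgraphs with huge α would not be.
* Single-process only; no attempt at parallel mining.
* No intronic-flank extraction or annotation handling: the user supplies
  region sequences as FASTA (intronic regions can be analysed simply by
  supplying them).
* No splicing-factor annotation of the output elements; final tables
  report sequences, types, exon support and provenance only.
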