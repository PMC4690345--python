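# Methods

## Model and procedure

`ampliclust` treats a dereplicated amplicon data set as a pool of
(sequence, abundance) pairs and partitions it by iterative single
linkage under a *local* threshold *d*: two amplicons belong to the same
OTU if they are connected by a path whose consecutive steps each differ
by at most *d* unit-cost edit operations (substitution, insertion,
deletion all cost 1). The underlying assumptions are the standard ones
for error-cloud clustering: true biological sequences are locally
abundant, sequencing/PCR errors generate rare variants a small number
of edits away, and error abundance decays with distance from the true
sequence.

### Pool construction

Records are parsed from FASTA with either `_N` or `;size=N` abundance
annotations, uppercased, and restricted to A/C/G/T (hard error
otherwise — silently dropping or recoding records loses data without a
trace). Identical sequences are merged, summing abundances (this *is*
the d=0 mode). The pool is sorted by decreasing abundance with ties
broken by ascending lexicographic sequence order. This tie-break makes
the pool — and therefore every downstream result — a deterministic
function of the record multiset: permuting the input file cannot change
any output byte. (Tools that tie on input order after a stable sort do
not have this property.)

### OTU growth

The highest-ranked unassigned amplicon founds an OTU (generation 0).
Growth is breadth-first: every member of the current generation, taken
in pool order, recruits all still-unassigned amplicons within *d*
differences; recruits are attached in pool order, recording parent,
generation and differences-to-parent. A child reachable from two
same-generation parents therefore attaches to the higher-ranked one —
an arbitrary but deterministic tie-break; the member *sets* are
unaffected by it when chain breaking is off (they are exactly the
connected components of the distance-≤d graph, which the test suite
verifies against a brute-force oracle).

For d=1 the neighbour search enumerates all microvariants of the
member's sequence and probes the pool's hash index — no alignment, and
per-amplicon cost independent of pool size. For general d≥1 a fallback
scans the unassigned pool with banded edlib alignments after a
length-difference prefilter (|ΔL| > d already exceeds the band). Both
paths are exposed and produce identical results at d=1; the generic
path is quadratic and intended for small studies.

### Microvariant counting

For S of length L: 3L distinct substitutions; one distinct deletion per
homopolymer run (deleting any base of a run gives the same string);
and 3L+4 distinct insertions (inserting base c into the L+1 gaps
collides once per occurrence of c, so 4(L+1) − L survive). The total is
6L + 4 + r with r the number of runs, bounded by 6L+5 (r=1, pure
homopolymer) and 7L+4 (r=L, no two adjacent bases equal). The closed
form is implemented alongside the enumeration and the two are asserted
equal; the deletion from a length-1 sequence legitimately yields the
empty string and is kept in the set (pool sequences are non-empty, so
it can never produce a spurious hit).

### Chain breaking

With breaking on (the default), an attachment is refused when the
child's abundance exceeds the parent's: abundance may never increase
along a continuous path from the seed. Equality is allowed — only a
strict increase is forbidden. The gate is per-edge, not per-amplicon: a
refused child may still be reached later through another, lower-abundance
path in the same OTU, or found its own OTU. Refused edges are recorded
(`cut_edges`) so that network exports can draw them — typically two
abundant OTUs joined through a rare amplicon, with the cut shown in
red. The gate also applies at generation 1, where it can never fire
(no pool member out-ranks the seed of its OTU, by pool ordering).

### Fastidious grafting

After clustering, OTUs with total abundance below the boundary
(default 3: singletons and doubletons; boundary < 2 would select
nothing and is rejected) are *light*; the rest are *heavy*. A light
OTU may graft onto a heavy OTU iff some light member is within two
edits of some heavy member — equivalently, iff a virtual intermediate
amplicon exists at one edit from each side. The equivalence holds
because over a ≥3-letter alphabet any two strings at distance 1 or 2
share a one-edit intermediate: at distance 2, applying the first
operation of an optimal two-operation script gives one; at distance 1,
substituting the differing position with a third base (or, for an
indel, editing at the indel site) gives one.

The search follows the intermediate picture: all microvariants of all
light amplicons are inserted into a Bloom filter (blake2b double
hashing; sized from a target false-positive rate, default 1%, or an
explicit bits-per-entry budget); microvariants of heavy amplicons are
probed against it. The filter has no false negatives, so no graftable
pair can be missed; a positive probe is confirmed against an exact
dictionary of light microvariants, built lazily on the first hit, so a
false positive can never cause a graft. A heavy microvariant that is
itself a light pool sequence is a distance-1 link (possible only across
a breaking cut) and is accepted directly. Decisions use pre-graft
abundances throughout: light-to-light grafts and graft chains are
structurally impossible, each light OTU joins at most one heavy OTU —
the one with the largest pre-graft total abundance, ties to the lower
OTU index — and the outcome is independent of processing order. The
filter is an engineering device only; correctness is defined by the
two-edit reachability contract, which a brute-force oracle
(`graft_oracle`) re-derives independently in the tests. Only d=1 is
supported: the k-edit neighbourhood grows as ~(7L)^k.

Grafted members join the heavy OTU after its own members, keeping their
internal tree and generation numbers; the graft edge (heavy anchor —
light anchor, 1 or 2 differences) is added to the internal structure
with generation anchor+1, and the merged OTU's maximum generation is
taken over both trees joined at the anchor. Surviving OTUs are
renumbered consecutively in seed order.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d` | 1 | local threshold, in edit operations; 0 = dereplicate only |
| `break_chains` | true | refuse abundance increases along paths |
| `fastidious` | false | graft light OTUs after clustering (d=1 only) |
| `boundary` | 3 | OTUs with total abundance < boundary are light |
| filter `fp_rate` | 0.01 | Bloom false-positive target (correctness-neutral) |
| filter `bits_per_entry` | unset | explicit memory/size trade-off override |

The d=1 default reflects the method's premise that most error variants
sit one edit from their source; the boundary of 3 targets singletons
and doubletons, the classes usually discarded as noise.

## Synthetic communities

The generator plants `n_true_otus` random seed sequences (default
length 130 nt, the typical high-throughput 16S read length; default
abundance 100) and surrounds each with satellites at exactly
`max_edits` edits (1 or 2), with geometrically decaying abundances
(ratio 0.5) or a fixed satellite abundance. Seeds are kept at pairwise
distance ≥ 2·max_edits + 3, which by the triangle inequality puts every
cross-OTU amplicon pair at distance ≥ 3: unreachable at d=1 and
ungraftable at two edits. At max_edits=2, satellites are additionally
kept at distance ≥ 2 from each other so plain d=1 cannot link them.
Consequently the ground truth is recovered *by construction*: exactly
at d=1 for one-edit satellites, and exactly after grafting for
two-edit low-abundance satellites. Geometric decay keeps abundances
monotone inside true OTUs, so chain breaking never fires there and each
feature is tested in isolation.

What the generator does *not* emulate: chimeras, length-heterogeneous
communities, abundance-dependent error rates, overlapping error clouds
between closely related taxa, and quality information. Passing tests
therefore demonstrate algorithmic correctness under the stated
separation assumptions, not ecological accuracy on real data where
clouds do overlap — there, chain breaking and grafting change results
in ways no synthetic ground truth here can arbitrate.

## Numerical and design choices

* Distances are unit-cost Levenshtein everywhere (edlib, banded at k=d
  for the generic scan). Tools that count differences from a scored
  alignment can differ on rare alignment ties for d ≥ 2.
* All tie-breaks (pool order, parent choice, graft winner, graft anchor
  pair) are total orders, so every output is byte-deterministic;
  `--threads` is accepted for interface compatibility and is a no-op.
* Degenerate inputs: empty record lists yield empty pools and zero
  OTUs; duplicate sequences under `assume_dereplicated` are an error
  naming both records; empty sequences, non-ACGT characters, and
  non-positive abundances are errors at parse time.
* Bloom sizing: bits = ⌈−n·ln p / (ln 2)²⌉, k = round(bits/n·ln 2),
  floored at 8 bits and one hash; an undersized filter only raises the
  confirmed-candidate rate, never changes decisions (tested with
  2 bits/entry).
* Network rendering is best effort: spring layout with a fixed seed,
  node area and colour mapped to abundance, labels for abundance ≥ 10,
  cut edges red, graft edges dashed. Edge length carries no
  information. Only the exported graph structure (GraphML/DOT/TSV) is
  under test.

## Test problem sizes

Brute-force oracle comparisons run on 50 random communities of up to
200 amplicons (lengths 20–60 nt); formula verification covers all 5,460
DNA sequences of length ≤ 6 against an exhaustive candidate scan over
lengths L−1, L, L+1; bound checks sample 1,000 random sequences of
lengths 1–200. These sizes make the full suite run in well under a
minute while keeping every check exact rather than sampled where
exhaustiveness is feasible.

## Known limitations

* d ≥ 2 clustering is quadratic; the linear fast path exists only for
  d = 1, and fastidious grafting only composes two one-edit steps.
* Memory capping of the fastidious phase is limited to the filter
  sizing knobs; `-c/--ceiling` is accepted but not enforced.
* No FASTQ input, quality filtering, primer handling, chimera
  detection, or taxonomic assignment — upstream and downstream tools
  own those steps.
* Ambiguous bases are rejected rather than matched permissively; data
  containing N must be filtered first.
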