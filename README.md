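# ampliclust

De novo clustering of marker-gene amplicons (16S/18S rRNA and similar)
into fine-scale molecular OTUs, for microbial ecologists who want
clusters free of arbitrary global similarity thresholds and of
input-order dependence.

## The method

Amplicon surveys dereplicate their reads into unique sequences, each
carrying an abundance (read count). Classic OTU pickers draw a fixed
global radius (e.g. 97% similarity) around centroid sequences; the
radius is arbitrary and the result depends on input order. `ampliclust`
instead grows clusters by **iterative single linkage with a small local
threshold _d_**: the most abundant unassigned amplicon founds an OTU,
and the cluster repeatedly recruits every remaining amplicon within _d_
differences (unit-cost edit operations) of *any current member*, until
it reaches its natural limits.

Three ideas make this practical and sharp:

* **Linear-time d=1 search.** A *microvariant* of a sequence S of
  length L is any string at edit distance exactly 1. Counting distinct
  outcomes — 3L substitutions, one deletion per homopolymer run,
  3L + 4 distinct insertions — gives between 6L + 5 (homopolymer) and
  7L + 4 (no two adjacent bases equal) microvariants; a 130-nt read has
  785–914. Instead of aligning an amplicon against the whole pool,
  the engine enumerates its microvariants and looks each one up in a
  hash index of the pool. The cost per amplicon is O(L), independent of
  pool size, so clustering scales as n·L rather than n².
* **Chain breaking.** Sequencing-error clouds decay in abundance away
  from the true sequence. Attachments that would *increase* abundance
  along a seed-to-member path (child more abundant than its parent) are
  refused, splitting chained clusters at abundance valleys. Refused
  edges are kept and can be displayed in network exports.
* **Fastidious grafting.** Leftover low-abundance OTUs (total abundance
  below a boundary, default 3 — singletons and doubletons) are grafted
  onto a larger OTU whenever a *virtual linking amplicon* could join
  them: some member of each lies within two edits of the other side.
  The search inserts all microvariants of light-OTU amplicons into a
  Bloom filter, probes microvariants of heavy-OTU amplicons against it,
  and confirms every hit exactly. Each light OTU joins at most one
  heavy OTU (largest pre-graft abundance wins).

d=0 performs pure dereplication; d≥2 is supported through a generic
banded-alignment scan (quadratic, for small studies only). The
fastidious phase requires d=1.

Sequences must be uppercase-able A/C/G/T. Ambiguous bases (`N`) and
RNA-style `U` are hard errors, never silently skipped or converted —
filter or convert beforehand.

## Worked example

Generate a small synthetic community — two "true" sequences of
abundance 100, each with two singleton error variants two edits away —
and cluster it with the fastidious option:

```sh
python - <<'EOF'
from ampliclust import CommunitySpec, generate_community, write_fasta
records, truth = generate_community(CommunitySpec(
    n_true_otus=2, seed_length=40, satellites_per_otu=2,
    max_edits=2, satellite_abundance=1, rng_seed=5))
write_fasta(records, "community.fasta")
EOF
ampliclust community.fasta -d 1 -f -o otus.txt -w reps.fasta -s stats.tsv
```

```
INFO: pool: 6 unique amplicons, 204 reads
INFO: clustering (d=1): 6 OTUs
INFO: fastidious grafting: 2 OTUs (66.7% fewer)
```

Plain d=1 clustering leaves each two-edit singleton as its own OTU
(6 in total); grafting recovers the two planted OTUs. `otus.txt` holds
one OTU per line (seed first, grafted members last):

```
otu2-seed_100 otu2-sat2_1 otu2-sat1_1
otu1-seed_100 otu1-sat1_1 otu1-sat2_1
```

`reps.fasta` contains each OTU's representative — its most abundant
amplicon, with the abundance annotation updated to the OTU total
(100 + 1 + 1):

```
>otu2-seed_102
AGTCCGAGGAGAGGGTGCTTCAGAGTATGTATACCACTGG
...
```

and `stats.tsv` one row per OTU (amplicons, total abundance, seed id,
seed abundance, singleton members, max generation, grafted members):

```
3	102	otu2-seed	100	2	1	2
3	102	otu1-seed	100	2	1	2
```

Useful flags: `-n` disables chain breaking, `-b N` moves the fastidious
boundary, `-z` switches to `;size=N` abundance annotations,
`-i FILE` writes the attachment edges, `-d 0` dereplicates only.
`-t/--threads` and `-c/--ceiling` are accepted for compatibility;
results never depend on them. Individual OTUs can be exported as
GraphML/DOT/TSV networks or rendered as images via
`ampliclust.build_network`, `export_network` and `render_network`.

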