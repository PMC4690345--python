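"""Synthetic amplicon communities with known ground-truth OTU structure.

Real amplicon data is dominated by a few abundant "true" sequences, each
surrounded by a cloud of rare error variants a handful of edits away.
The generator emulates exactly that: ``n_true_otus`` random seed
sequences, placed far enough apart that their clouds can never touch,
each with geometrically decaying satellite amplicons at a fixed edit
distance.  Because the structure is known, every clustering feature can
be validated without external data:

* satellites at one edit (``max_edits=1``) are recovered exactly by
  plain d=1 clustering;
* satellites at exactly two edits with abundance below the fastidious
  boundary become their own tiny OTUs under plain d=1 and are recovered
  only by the fastidious phase.

Seeds are kept at pairwise distance >= 2·max_edits + 3, so every
cross-OTU amplicon pair is at distance >= 3: unreachable at d=1 and
ungraftable at two edits.  Output is fully deterministic given
``rng_seed``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import edlib

from ampliclust.microvariants import ALPHABET

_MAX_TRIES = 1000


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community.

    n_true_otus
        Number of ground-truth OTUs (seed sequences).
    seed_length
        Length of each seed sequence in nucleotides; 130 mirrors typical
        high-throughput 16S rRNA reads.
    satellites_per_otu
        Error variants generated around each seed.
    max_edits
        Edit distance of every satellite to its seed (1 or 2).
    seed_abundance, abundance_ratio
        Geometric abundance decay: satellite k of an OTU has abundance
        max(1, floor(seed_abundance · abundance_ratio^k)), always below
        the seed — so chain breaking stays inactive inside true OTUs.
    satellite_abundance
        If set, overrides the decay and gives every satellite this
        abundance (e.g. 1 to produce singleton satellites).
    rng_seed
        Seed for the pseudo-random generator; output is byte-identical
        for identical specs.
    """

    n_true_otus: int = 5
    seed_length: int = 130
    satellites_per_otu: int = 5
    max_edits: int = 1
    seed_abundance: int = 100
    abundance_ratio: float = 0.5
    satellite_abundance: int | None = None
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_true_otus < 1 or self.seed_length < 1:
            raise ValueError("need at least one OTU and a positive seed length")
        if self.max_edits not in (1, 2):
            raise ValueError("max_edits must be 1 or 2")
        if self.satellites_per_otu < 0:
            raise ValueError("satellites_per_otu must be >= 0")
        if self.seed_abundance < 1:
            raise ValueError("seed_abundance must be >= 1")
        if not 0.0 < self.abundance_ratio < 1.0:
            raise ValueError("abundance_ratio must be in (0, 1)")
        if self.satellite_abundance is not None and not (
            0 < self.satellite_abundance < self.seed_abundance
        ):
            raise ValueError("satellite_abundance must be in [1, seed_abundance)")


def _distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _mutate(sequence: str, rng: random.Random) -> str:
    """Apply one random edit (substitution, insertion or deletion)."""
    op = rng.choice("SID" if len(sequence) > 1 else "SI")
    if op == "S":
        i = rng.randrange(len(sequence))
        b = rng.choice([c for c in ALPHABET if c != sequence[i]])
        return sequence[:i] + b + sequence[i + 1 :]
    if op == "I":
        i = rng.randrange(len(sequence) + 1)
        return sequence[:i] + rng.choice(ALPHABET) + sequence[i:]
    i = rng.randrange(len(sequence))
    return sequence[:i] + sequence[i + 1 :]


def generate_community(
    spec: CommunitySpec,
) -> tuple[list[tuple[str, str, int]], list[frozenset[str]]]:
    """Generate (records, ground_truth).

    ``records`` are FASTA-ready (id, sequence, abundance) triples, seeds
    first within each OTU; ``ground_truth`` is the true partition as a
    list of frozensets of record ids, one per OTU.  Raises ``ValueError``
    if the spec is infeasible (seeds cannot be placed far enough apart
    within a bounded number of retries).
    """
    rng = random.Random(spec.rng_seed)
    min_seed_dist = 2 * spec.max_edits + 3

    seeds: list[str] = []
    for _ in range(spec.n_true_otus):
        for _try in range(_MAX_TRIES):
            cand = "".join(rng.choice(ALPHABET) for _ in range(spec.seed_length))
            if all(_distance(cand, s) >= min_seed_dist for s in seeds):
                seeds.append(cand)
                break
        else:
            raise ValueError(
                f"could not place {spec.n_true_otus} seeds of length "
                f"{spec.seed_length} at pairwise distance >= {min_seed_dist}"
            )

    records: list[tuple[str, str, int]] = []
    ground_truth: list[frozenset[str]] = []
    community: set[str] = set(seeds)
    for k, seed_seq in enumerate(seeds, start=1):
        otu_ids = [f"otu{k}-seed"]
        records.append((f"otu{k}-seed", seed_seq, spec.seed_abundance))
        sats: list[str] = []
        for j in range(1, spec.satellites_per_otu + 1):
            for _try in range(_MAX_TRIES):
                cand = seed_seq
                for _ in range(spec.max_edits):
                    cand = _mutate(cand, rng)
                if not cand or cand in community:
                    continue
                if _distance(cand, seed_seq) != spec.max_edits:
                    continue
                # at max_edits=2, satellites must not link to each other
                # at d=1, or plain clustering would partially recover them
                if spec.max_edits == 2 and any(
                    _distance(cand, s) < 2 for s in sats
                ):
                    continue
                break
            else:
                raise ValueError(
                    f"could not place satellite {j} of OTU {k} "
                    f"(length {spec.seed_length}, {spec.max_edits} edits)"
                )
            if spec.satellite_abundance is not None:
                abundance = spec.satellite_abundance
            else:
                abundance = max(
                    1, int(spec.seed_abundance * spec.abundance_ratio**j)
                )
            sat_id = f"otu{k}-sat{j}"
            records.append((sat_id, cand, abundance))
            otu_ids.append(sat_id)
            sats.append(cand)
            community.add(cand)
        ground_truth.append(frozenset(otu_ids))
    return records, ground_truth
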