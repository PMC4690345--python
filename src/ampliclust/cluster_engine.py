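"""Iterative single-linkage OTU growth with a local threshold and chain breaking.

OTUs are grown greedily: the highest-ranked unassigned amplicon founds a
new OTU (generation 0) and the cluster expands breadth-first — every
member of the current generation recruits all still-unassigned amplicons
within *d* differences of itself.  The threshold is *local* (between an
amplicon and the member it attaches to, never the seed), so OTUs grow to
their natural limits instead of being bounded by a global radius.

Two neighbour searches back the growth.  For d=1 every microvariant of
the current member is generated and looked up in the pool's hash index —
cost independent of pool size, hence overall linear scaling.  For any
d ≥ 1 a generic scan computes unit-cost Levenshtein distances against the
remaining pool (with a length-difference prefilter); for d=1 both paths
return identical neighbour sets and identical cluster results.

Chain breaking (on by default) refuses any attachment whose child would
be more abundant than its parent, preventing any increase in abundance
along a continuous amplicon path.  Refused edges are recorded so network
exports can display them (the classic red "cut" edges between two
abundant clusters joined through a rare intermediate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from ampliclust.amplicon_io import AmpliconPool
from ampliclust.microvariants import iter_microvariants


@dataclass(frozen=True)
class Parameters:
    """Clustering parameters.

    d
        Local threshold: maximum number of differences (unit-cost edit
        operations) between an amplicon and the member it attaches to.
        d=0 means dereplication only. Default 1.
    break_chains
        Refuse attachments that would increase abundance along a path.
    fastidious
        Graft low-abundance OTUs onto larger ones afterwards (d=1 only).
    boundary
        An OTU with total abundance below this is "low-abundance" for
        the fastidious phase; default 3 selects singletons + doubletons.
    engine
        "auto" uses the hash/microvariant path for d=1 and the generic
        scan otherwise; "hash" / "generic" force a path (testing hook).
    """

    d: int = 1
    break_chains: bool = True
    fastidious: bool = False
    boundary: int = 3
    engine: str = "auto"

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be a non-negative integer")
        if self.fastidious and self.d != 1:
            raise ValueError("the fastidious option can only be used with d = 1")
        if self.boundary < 2:
            raise ValueError("boundary must be >= 2")
        if self.engine not in ("auto", "hash", "generic"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.engine == "hash" and self.d > 1:
            raise ValueError("the hash engine only supports d = 1")


@dataclass(frozen=True)
class OtuMember:
    position: int  # pool position
    generation: int  # 0 for the seed
    parent: int | None  # pool position of the member it attached to
    differences_to_parent: int | None


@dataclass
class OTU:
    otu_index: int  # 1-based, in seed order
    seed: int
    members: list[OtuMember]
    total_abundance: int
    max_generation: int
    n_grafted: int = 0


@dataclass(frozen=True)
class InternalEdge:
    parent: int
    child: int
    differences: int
    otu_index: int
    generation: int
    is_graft: bool = False


@dataclass
class ClusterResult:
    """A partition of the pool into OTUs plus the edges that built it."""

    otus: list[OTU]
    internal_edges: list[InternalEdge]
    cut_edges: list[tuple[int, int, int]]  # (parent, child, differences) refusals
    grafts: list = field(default_factory=list)  # GraftRecord, fastidious phase

    def otu_of(self) -> dict[int, int]:
        """Map pool position -> 1-based otu_index."""
        return {
            m.position: otu.otu_index for otu in self.otus for m in otu.members
        }


def breaking_gate(parent: int, child: int, pool: AmpliconPool, params: Parameters) -> bool:
    """True iff the child may attach under the parent.

    With chain breaking on, only a non-increase in abundance passes
    (equality allowed); with it off, every candidate attaches.
    """
    if not params.break_chains:
        return True
    return pool[child].abundance <= pool[parent].abundance


def neighbors_d1(
    amplicon: int, pool: AmpliconPool, assigned: list[bool]
) -> list[int]:
    """Unassigned pool positions at exactly one edit, via exact-string lookup.

    Enumerates the amplicon's microvariants and probes the pool's hash
    index; never performs a pairwise alignment.  Sorted by pool order.
    """
    index = pool.index
    hits = {
        pos
        for v in iter_microvariants(pool[amplicon].sequence)
        if (pos := index.get(v)) is not None and not assigned[pos]
    }
    return sorted(hits)


def _edit_distance_at_most(a: str, b: str, k: int) -> int | None:
    """Unit-cost Levenshtein distance if <= k, else None (banded edlib)."""
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    return None if d == -1 else d


def neighbors_generic(
    amplicon: int, pool: AmpliconPool, assigned: list[bool], d: int
) -> list[tuple[int, int]]:
    """Unassigned pool positions within d edits, by scanning the pool.

    Returns (position, distance) pairs sorted by pool order.  A
    length-difference > d candidate is skipped before any alignment
    (the length gap lower-bounds the edit distance).
    """
    if d < 1:
        raise ValueError("neighbors_generic requires d >= 1")
    seq = pool[amplicon].sequence
    out: list[tuple[int, int]] = []
    for pos in range(len(pool)):
        if assigned[pos] or pos == amplicon:
            continue
        cand = pool[pos].sequence
        if abs(len(cand) - len(seq)) > d:
            continue
        dist = _edit_distance_at_most(seq, cand, d)
        if dist is not None and dist >= 1:
            out.append((pos, dist))
    return out


def cluster(pool: AmpliconPool, params: Parameters | None = None) -> ClusterResult:
    """Partition the pool into OTUs.

    Growth is breadth-first by generation; within a generation parents
    are processed in pool order and children attached in pool order, so
    a child reachable from two same-generation parents attaches to the
    higher-ranked one.  A child refused by the breaking gate stays
    unassigned: it may be reached later through another (lower-abundance)
    path in the same OTU, or found its own OTU.  For d=0 the (already
    dereplicated) pool yields one OTU per amplicon.
    """
    params = params or Parameters()
    n = len(pool)
    if params.d == 0:
        otus = [
            OTU(i + 1, i, [OtuMember(i, 0, None, None)], pool[i].abundance, 0)
            for i in range(n)
        ]
        return ClusterResult(otus, [], [])

    use_hash = params.engine == "hash" or (params.engine == "auto" and params.d == 1)
    assigned = [False] * n
    otus: list[OTU] = []
    edges: list[InternalEdge] = []
    cut_edges: list[tuple[int, int, int]] = []
    seen_cuts: set[tuple[int, int]] = set()

    for seed in range(n):
        if assigned[seed]:
            continue
        otu_index = len(otus) + 1
        assigned[seed] = True
        members = [OtuMember(seed, 0, None, None)]
        frontier = [seed]
        generation = 0
        while frontier:
            generation += 1
            recruits: list[int] = []
            for parent in frontier:
                if use_hash:
                    candidates = [
                        (c, 1) for c in neighbors_d1(parent, pool, assigned)
                    ]
                else:
                    candidates = neighbors_generic(parent, pool, assigned, params.d)
                for child, diff in candidates:
                    if assigned[child]:
                        continue
                    if breaking_gate(parent, child, pool, params):
                        assigned[child] = True
                        members.append(OtuMember(child, generation, parent, diff))
                        edges.append(
                            InternalEdge(parent, child, diff, otu_index, generation)
                        )
                        recruits.append(child)
                    elif (parent, child) not in seen_cuts:
                        seen_cuts.add((parent, child))
                        cut_edges.append((parent, child, diff))
            frontier = sorted(recruits)
        otus.append(
            OTU(
                otu_index,
                seed,
                members,
                sum(pool[m.position].abundance for m in members),
                members[-1].generation if members else 0,
            )
        )
    return ClusterResult(otus, edges, cut_edges)
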