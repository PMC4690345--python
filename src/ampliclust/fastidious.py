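"""Fastidious grafting of low-abundance OTUs through virtual linking amplicons.

Even with chain breaking, d=1 clustering leaves many tiny OTUs —
singletons and doubletons that are mostly sequencing errors sitting two
edits away from an abundant sequence.  The fastidious phase rescues them:
a light OTU (total abundance below a boundary, default 3) is grafted onto
a heavy OTU whenever some light amplicon lies within two edits of some
heavy amplicon, i.e. whenever a *virtual* intermediate amplicon at one
edit from each side could link them.

The search follows the virtual-amplicon picture literally: every
microvariant of every light amplicon is inserted into a Bloom filter;
microvariants of heavy amplicons are then probed against it.  Over a
four-letter alphabet two sequences at distance 1 or 2 always share a
one-edit intermediate, so the intersection test is exactly the
two-edit reachability contract.  A Bloom hit is only a candidate — an
exact dictionary of light microvariants (built lazily on the first hit)
confirms it, so false positives never cause a graft and false negatives
cannot occur.

All decisions use PRE-graft abundances: light-to-light grafts and graft
chains are impossible, each light OTU grafts onto at most one heavy OTU
(largest pre-graft abundance wins, ties to the lower OTU index), and the
outcome is independent of processing order.  Only d=1 is supported; the
neighbourhood enumeration grows too fast for larger d.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import edlib

from ampliclust.amplicon_io import AmpliconPool
from ampliclust.cluster_engine import (
    OTU,
    ClusterResult,
    InternalEdge,
    OtuMember,
    Parameters,
)
from ampliclust.microvariants import iter_microvariants


@dataclass(frozen=True)
class GraftRecord:
    """One accepted graft: which light OTU joined which heavy OTU, and where."""

    light_otu: int  # pre-graft otu_index
    heavy_otu: int  # pre-graft otu_index
    light_anchor: int  # pool position of the light-side amplicon
    heavy_anchor: int  # pool position of the heavy-side amplicon
    differences: int  # edit distance between the anchors (1 or 2)


class MembershipFilter:
    """A Bloom filter: approximate set membership with no false negatives.

    Sized from an expected item count and a target false-positive rate
    (or an explicit bits-per-entry budget).  Hashing is blake2b-based and
    fully deterministic across processes.  A positive test is only a
    candidate; callers must confirm exactly before acting on it.
    """

    def __init__(
        self,
        capacity: int,
        fp_rate: float = 0.01,
        bits_per_entry: float | None = None,
    ):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if not 0.0 < fp_rate < 1.0:
            raise ValueError("fp_rate must be in (0, 1)")
        if bits_per_entry is not None:
            self.n_bits = max(8, math.ceil(capacity * bits_per_entry))
        else:
            self.n_bits = max(8, math.ceil(-capacity * math.log(fp_rate) / math.log(2) ** 2))
        self.n_hashes = max(1, round(self.n_bits / capacity * math.log(2)))
        self._bits = bytearray((self.n_bits + 7) // 8)

    def _positions(self, item: str):
        digest = hashlib.blake2b(item.encode(), digest_size=16).digest()
        h1 = int.from_bytes(digest[:8], "little")
        h2 = int.from_bytes(digest[8:], "little") | 1
        for i in range(self.n_hashes):
            yield (h1 + i * h2) % self.n_bits

    def add(self, item: str) -> None:
        for pos in self._positions(item):
            self._bits[pos >> 3] |= 1 << (pos & 7)

    def __contains__(self, item: str) -> bool:
        return all(
            self._bits[pos >> 3] & (1 << (pos & 7)) for pos in self._positions(item)
        )


def partition_otus(
    result: ClusterResult, boundary: int
) -> tuple[list[int], list[int]]:
    """Split OTU indices into (light, heavy) by total abundance.

    Light OTUs have total abundance < boundary; with the default boundary
    of 3 that is exactly the singletons and doubletons.  A boundary below
    2 selects nothing and is rejected as a user mistake.
    """
    if boundary < 2:
        raise ValueError("boundary must be >= 2")
    light = [o.otu_index for o in result.otus if o.total_abundance < boundary]
    heavy = [o.otu_index for o in result.otus if o.total_abundance >= boundary]
    return light, heavy


def _find_grafts(
    result: ClusterResult,
    pool: AmpliconPool,
    boundary: int,
    fp_rate: float = 0.01,
    bits_per_entry: float | None = None,
) -> list[GraftRecord]:
    """Decide grafts via the Bloom-filter search with exact confirmation."""
    light, heavy = partition_otus(result, boundary)
    if not light or not heavy:
        return []
    by_index = {o.otu_index: o for o in result.otus}
    light_set = set(light)
    light_positions = {
        m.position: o for o in light for m in by_index[o].members
    }

    # Phase 1: all microvariants of light amplicons go into the filter.
    capacity = sum(
        7 * len(pool[p].sequence) + 4 for p in light_positions
    )
    bloom = MembershipFilter(capacity, fp_rate=fp_rate, bits_per_entry=bits_per_entry)
    for pos in light_positions:
        for v in iter_microvariants(pool[pos].sequence):
            bloom.add(v)

    # candidates[light_otu][heavy_otu] -> best (distance, heavy_pos, light_pos)
    candidates: dict[int, dict[int, tuple[int, int, int]]] = {}
    exact: dict[str, list[tuple[int, int]]] | None = None  # variant -> (otu, pos)

    def record(lotu: int, hotu: int, dist: int, hpos: int, lpos: int) -> None:
        best = candidates.setdefault(lotu, {}).get(hotu)
        key = (dist, hpos, lpos)
        if best is None or key < best:
            candidates[lotu][hotu] = key

    # Phase 2: probe microvariants of heavy amplicons against the filter.
    for hotu in heavy:
        for member in by_index[hotu].members:
            hpos = member.position
            seen: set[str] = set()
            for v in iter_microvariants(pool[hpos].sequence):
                if v in seen:
                    continue
                seen.add(v)
                # a microvariant that IS a light amplicon: distance 1
                direct = pool.index.get(v)
                if direct is not None and direct in light_positions:
                    record(light_positions[direct], hotu, 1, hpos, direct)
                if v in bloom:
                    if exact is None:  # lazy confirmation dictionary
                        exact = {}
                        for lpos, lotu in light_positions.items():
                            for lv in iter_microvariants(pool[lpos].sequence):
                                exact.setdefault(lv, []).append((lotu, lpos))
                    for lotu, lpos in exact.get(v, ()):
                        record(lotu, hotu, 2, hpos, lpos)

    grafts: list[GraftRecord] = []
    for lotu in sorted(candidates):
        if lotu not in light_set:
            continue
        # winner: largest pre-graft heavy abundance, then lowest otu_index
        winner = min(
            candidates[lotu],
            key=lambda h: (-by_index[h].total_abundance, h),
        )
        dist, hpos, lpos = candidates[lotu][winner]
        grafts.append(GraftRecord(lotu, winner, lpos, hpos, dist))
    return grafts


def fastidious_graft(
    result: ClusterResult,
    pool: AmpliconPool,
    params: Parameters,
    fp_rate: float = 0.01,
    bits_per_entry: float | None = None,
) -> ClusterResult:
    """Graft light OTUs onto heavy ones and rebuild the result.

    Grafted members join the winning heavy OTU after its own members,
    keeping their internal structure and generation numbers; a graft edge
    (heavy anchor — light anchor) is added to the internal edges.  OTUs
    are renumbered consecutively in original seed order.  Total abundance
    is conserved and the OTU count never increases.
    """
    if not params.fastidious:
        raise ValueError("fastidious_graft called but params.fastidious is not set")
    if params.d != 1:
        raise ValueError("the fastidious option can only be used with d = 1")
    grafts = _find_grafts(
        result, pool, params.boundary, fp_rate=fp_rate, bits_per_entry=bits_per_entry
    )
    by_index = {o.otu_index: o for o in result.otus}
    grafted_onto: dict[int, list[GraftRecord]] = {}
    for g in grafts:
        grafted_onto.setdefault(g.heavy_otu, []).append(g)
    absorbed = {g.light_otu for g in grafts}

    new_otus: list[OTU] = []
    renumber: dict[int, int] = {}
    for otu in result.otus:
        if otu.otu_index in absorbed:
            continue
        new_index = len(new_otus) + 1
        renumber[otu.otu_index] = new_index
        members = list(otu.members)
        total = otu.total_abundance
        max_gen = otu.max_generation
        n_grafted = otu.n_grafted
        for g in sorted(grafted_onto.get(otu.otu_index, []), key=lambda g: g.light_otu):
            light = by_index[g.light_otu]
            renumber[g.light_otu] = new_index
            members.extend(light.members)
            total += light.total_abundance
            n_grafted += len(light.members)
            anchor_gen = _generation_of(otu, g.heavy_anchor)
            max_gen = max(max_gen, anchor_gen + 1 + light.max_generation)
        new_otus.append(
            OTU(new_index, otu.seed, members, total, max_gen, n_grafted)
        )

    new_edges = [
        replace(e, otu_index=renumber[e.otu_index]) for e in result.internal_edges
    ]
    for g in grafts:
        heavy = by_index[g.heavy_otu]
        anchor_gen = _generation_of(heavy, g.heavy_anchor)
        new_edges.append(
            InternalEdge(
                g.heavy_anchor,
                g.light_anchor,
                g.differences,
                renumber[g.heavy_otu],
                anchor_gen + 1,
                is_graft=True,
            )
        )
    return ClusterResult(new_otus, new_edges, list(result.cut_edges), list(grafts))


def _generation_of(otu: OTU, position: int) -> int:
    for m in otu.members:
        if m.position == position:
            return m.generation
    raise ValueError(f"position {position} is not a member of OTU {otu.otu_index}")


def graft_oracle(
    result: ClusterResult, pool: AmpliconPool, boundary: int
) -> set[tuple[int, int]]:
    """Brute-force graft decisions: the definition the filter path must match.

    A light OTU is graftable onto a heavy OTU iff some member pair is
    within two edits (unit-cost Levenshtein, computed independently of
    the microvariant machinery); the same winner rule is applied.
    Intended for small pools only.
    """
    light, heavy = partition_otus(result, boundary)
    by_index = {o.otu_index: o for o in result.otus}
    decisions: set[tuple[int, int]] = set()
    for lotu in light:
        reachable = []
        for hotu in heavy:
            linked = any(
                edlib.align(
                    pool[lm.position].sequence,
                    pool[hm.position].sequence,
                    mode="NW",
                    task="distance",
                    k=2,
                )["editDistance"]
                != -1
                for lm in by_index[lotu].members
                for hm in by_index[hotu].members
            )
            if linked:
                reachable.append(hotu)
        if reachable:
            winner = min(reachable, key=lambda h: (-by_index[h].total_abundance, h))
            decisions.add((lotu, winner))
    return decisions
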