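"""Shared helpers: an independent edit-distance oracle and community factories."""

from __future__ import annotations

import random

import edlib
import pytest

from ampliclust.amplicon_io import AmpliconPool, build_pool
from ampliclust.microvariants import ALPHABET


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance via edlib (independent of the microvariant code)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(length))


def mutate_once(rng: random.Random, seq: str) -> str:
    """One random substitution, insertion, or deletion."""
    ops = ["S", "I"] + (["D"] if len(seq) > 1 else [])
    op = rng.choice(ops)
    if op == "S":
        i = rng.randrange(len(seq))
        return seq[:i] + rng.choice([c for c in ALPHABET if c != seq[i]]) + seq[i + 1 :]
    if op == "I":
        i = rng.randrange(len(seq) + 1)
        return seq[:i] + rng.choice(ALPHABET) + seq[i:]
    i = rng.randrange(len(seq))
    return seq[:i] + seq[i + 1 :]


def random_community_records(
    rng: random.Random,
    n_seeds: int = 5,
    n_satellites: int = 20,
    length_range: tuple[int, int] = (20, 60),
    max_edits: int = 2,
) -> list[tuple[str, str, int]]:
    """Clustered records: abundant seeds plus rare nearby mutants.

    Unlike the package's own generator this makes no separation
    guarantees, so clusters can touch and chain — which is exactly what
    the brute-force oracle comparisons want to exercise.
    """
    records: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    seeds: list[str] = []
    for i in range(n_seeds):
        seq = random_sequence(rng, rng.randint(*length_range))
        if seq in seen:
            continue
        seen.add(seq)
        seeds.append(seq)
        records.append((f"seed{i}", seq, rng.randint(10, 200)))
    for j in range(n_satellites):
        base = rng.choice(seeds)
        seq = base
        for _ in range(rng.randint(1, max_edits)):
            seq = mutate_once(rng, seq)
        if not seq or seq in seen:
            continue
        seen.add(seq)
        records.append((f"sat{j}", seq, rng.randint(1, 9)))
    return records


@pytest.fixture
def chain_pool() -> AmpliconPool:
    """The classic three-amplicon chain with an abundance valley:
    AAAA(10) - AAAT(1) - AATT(8), each link one substitution."""
    return build_pool([("A", "AAAA", 10), ("B", "AAAT", 1), ("C", "AATT", 8)])


@pytest.fixture
def graft_pool() -> AmpliconPool:
    """An abundant amplicon and a singleton two substitutions away."""
    return build_pool([("X", "AAAAAAAA", 50), ("Y", "AATTAAAA", 1)])
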