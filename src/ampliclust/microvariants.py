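"""One-edit neighbourhood ("microvariant") enumeration.

A microvariant of a DNA sequence S of length L is any distinct string at
unit-cost edit distance exactly 1: a substitution (3 per position), a
deletion (1 per position), or an insertion (4 per gap, L+1 gaps).  After
deduplication the count is 6L+4+r where r is the number of homopolymer
runs in S: substitutions always contribute 3L distinct strings, deletions
one distinct string per run, and insertions always 3L+4 (inserting base c
left or right of an existing c collides).  The count therefore ranges
from 6L+5 (a pure homopolymer, r=1) up to 7L+4 (no two adjacent bases
equal, r=L) — small enough that exhaustive enumeration plus an exact
hash lookup replaces pairwise alignment entirely for d=1 clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

ALPHABET = "ACGT"


@dataclass(frozen=True)
class MicrovariantSet:
    origin: str
    variants: frozenset[str]

    def __len__(self) -> int:
        return len(self.variants)


def enumerate_microvariants(sequence: str) -> MicrovariantSet:
    """All distinct strings at edit distance exactly 1 from ``sequence``.

    The empty string (deletion from a length-1 input) is a legitimate
    variant and is included.  Raises ``ValueError`` on empty input.
    """
    if not sequence:
        raise ValueError("cannot enumerate microvariants of an empty sequence")
    variants: set[str] = set()
    L = len(sequence)
    for i in range(L):
        head, base, tail = sequence[:i], sequence[i], sequence[i + 1 :]
        for b in ALPHABET:
            if b != base:
                variants.add(head + b + tail)  # substitution
        variants.add(head + tail)  # deletion
    for i in range(L + 1):
        head, tail = sequence[:i], sequence[i:]
        for b in ALPHABET:
            variants.add(head + b + tail)  # insertion
    # no edit class can recreate the origin (substitutions exclude the
    # original base; indels change the length), so no discard is needed
    return MicrovariantSet(sequence, frozenset(variants))


def iter_microvariants(sequence: str):
    """Yield microvariants lazily, possibly with repeats.

    Generation-order duplicates are the caller's concern; the d=1 engine
    tolerates them because pool lookups are idempotent.
    """
    if not sequence:
        raise ValueError("cannot enumerate microvariants of an empty sequence")
    L = len(sequence)
    for i in range(L):
        head, base, tail = sequence[:i], sequence[i], sequence[i + 1 :]
        for b in ALPHABET:
            if b != base:
                yield head + b + tail
        yield head + tail
    for i in range(L + 1):
        head, tail = sequence[:i], sequence[i:]
        for b in ALPHABET:
            yield head + b + tail


def count_bounds(length: int) -> tuple[int, int]:
    """(minimum, maximum) number of distinct microvariants for a length.

    6L+5 for a pure homopolymer, 7L+4 when no two adjacent bases match.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    return 6 * length + 5, 7 * length + 4


def microvariant_count(sequence: str) -> int:
    """Number of distinct microvariants, by closed form.

    6L + 4 + r with r the number of homopolymer runs; cross-checked
    against full enumeration in the test suite.
    """
    if not sequence:
        raise ValueError("cannot count microvariants of an empty sequence")
    runs = 1 + sum(
        1 for a, b in zip(sequence, sequence[1:]) if a != b
    )
    return 6 * len(sequence) + 4 + runs
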