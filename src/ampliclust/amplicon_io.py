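"""FASTA input/output with abundance annotations and d=0 dereplication.

Amplicon pipelines carry a read count ("abundance") on every dereplicated
sequence, encoded in the FASTA identifier.  Two dialects are common: a
trailing ``_N`` suffix (``>seq1_1234``) and the usearch-style
``;size=N`` annotation (``>seq1;size=1234``).  This module parses both,
merges strictly identical sequences (dereplication — exactly the d=0
clustering mode), and builds the sorted, indexed amplicon pool that the
clustering engine consumes.

Sequences must be plain A/C/G/T after uppercasing.  Ambiguous bases (N)
and RNA-style U are rejected outright rather than silently skipped or
converted; see the README.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

from Bio import SeqIO

_VALID_SEQ = re.compile(r"^[ACGT]+$")
_SIZE_ANNOT = re.compile(r";size=(\d+);?")
_UNDERSCORE_ANNOT = re.compile(r"^(.*)_(\d+)$")


@dataclass(frozen=True)
class Amplicon:
    """A dereplicated sequence: identifier, DNA string, read count."""

    id: str
    sequence: str
    abundance: int

    def __post_init__(self) -> None:
        if not self.sequence or not _VALID_SEQ.match(self.sequence):
            raise ValueError(
                f"amplicon {self.id!r}: sequence must be non-empty and over A/C/G/T"
            )
        if self.abundance < 1:
            raise ValueError(f"amplicon {self.id!r}: abundance must be >= 1")


@dataclass(frozen=True)
class AbundanceDialect:
    """How abundances are encoded in FASTA identifiers.

    style
        ``"underscore"`` for a trailing ``_N`` suffix, ``"size_annotation"``
        for usearch-style ``;size=N``.
    default_abundance
        Used when a record carries no annotation; if unset, a missing
        annotation is a hard error.
    """

    style: str = "underscore"
    default_abundance: int | None = None

    def __post_init__(self) -> None:
        if self.style not in ("underscore", "size_annotation"):
            raise ValueError(f"unknown abundance dialect style {self.style!r}")
        if self.default_abundance is not None and self.default_abundance < 1:
            raise ValueError("default_abundance must be a positive integer")

    def parse_id(self, raw_id: str) -> tuple[str, int | None]:
        """Split a FASTA identifier into (bare id, abundance or None)."""
        if self.style == "underscore":
            m = _UNDERSCORE_ANNOT.match(raw_id)
            if m:
                return m.group(1), int(m.group(2))
            return raw_id, None
        m = _SIZE_ANNOT.search(raw_id)
        if m:
            return _SIZE_ANNOT.sub("", raw_id, count=1).rstrip(";"), int(m.group(1))
        return raw_id, None

    def format_id(self, bare_id: str, abundance: int) -> str:
        """Annotate a bare identifier with an abundance."""
        if self.style == "underscore":
            return f"{bare_id}_{abundance}"
        return f"{bare_id};size={abundance}"


class AmpliconPool:
    """The sorted, dereplicated amplicon collection clustering operates on.

    Order is strictly non-increasing abundance, ties broken by ascending
    lexicographic sequence order — a deterministic function of the record
    multiset, so clustering output never depends on input order.  A
    sequence → position hash index supports the exact-string microvariant
    lookups of the d=1 engine.
    """

    def __init__(self, amplicons: Sequence[Amplicon]):
        order = sorted(amplicons, key=lambda a: (-a.abundance, a.sequence))
        self.amplicons: list[Amplicon] = list(order)
        self.index: dict[str, int] = {a.sequence: i for i, a in enumerate(order)}
        if len(self.index) != len(self.amplicons):
            raise ValueError("pool must be dereplicated: duplicate sequences present")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, position: int) -> Amplicon:
        return self.amplicons[position]

    def __iter__(self):
        return iter(self.amplicons)

    @property
    def total_abundance(self) -> int:
        return sum(a.abundance for a in self.amplicons)


def parse_fasta(
    path: str | PathLike, dialect: AbundanceDialect | None = None
) -> list[tuple[str, str, int]]:
    """Read a FASTA file into (id, SEQUENCE, abundance) triples.

    Sequences are uppercased; the abundance annotation is stripped from
    the returned identifier.  Input order is preserved.  Raises
    ``ValueError`` naming the offending record on any non-ACGT character,
    empty sequence, or missing/invalid abundance annotation.
    """
    dialect = dialect or AbundanceDialect()
    records: list[tuple[str, str, int]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(
                f"record {rec.id!r}: invalid characters {bad} (only A/C/G/T accepted)"
            )
        bare_id, abundance = dialect.parse_id(rec.id)
        if abundance is None:
            if dialect.default_abundance is None:
                raise ValueError(
                    f"record {rec.id!r}: no abundance annotation and no default set"
                )
            abundance = dialect.default_abundance
        if abundance < 1:
            raise ValueError(f"record {rec.id!r}: abundance must be >= 1")
        records.append((bare_id, seq, abundance))
    return records


def dereplicate(records: Iterable[tuple[str, str, int]]) -> AmpliconPool:
    """Merge strictly identical sequences into one amplicon each (d=0 mode).

    Merged abundance is the sum over members; the merged identifier is
    that of the highest-abundance member (ties: first occurrence).
    """
    by_seq: dict[str, list[tuple[str, int]]] = {}
    for rec_id, seq, abundance in records:
        by_seq.setdefault(seq, []).append((rec_id, abundance))
    merged = []
    for seq, members in by_seq.items():
        total = sum(ab for _, ab in members)
        best_id = max(members, key=lambda m: m[1])[0]  # max() keeps first on ties
        merged.append(Amplicon(best_id, seq, total))
    return AmpliconPool(merged)


def build_pool(
    records: Iterable[tuple[str, str, int]], assume_dereplicated: bool = False
) -> AmpliconPool:
    """Build the sorted pool, dereplicating unless the input claims to be.

    With ``assume_dereplicated`` a duplicate sequence is a contract
    violation and raises ``ValueError`` naming both records.
    """
    records = list(records)
    if assume_dereplicated:
        seen: dict[str, str] = {}
        for rec_id, seq, _ in records:
            if seq in seen:
                raise ValueError(
                    f"input declared dereplicated but records {seen[seq]!r} "
                    f"and {rec_id!r} share a sequence"
                )
            seen[seq] = rec_id
        return AmpliconPool([Amplicon(i, s, a) for i, s, a in records])
    return dereplicate(records)


def write_fasta(
    amplicons: Iterable[tuple[str, str, int]],
    path: str | PathLike,
    dialect: AbundanceDialect | None = None,
) -> None:
    """Write (id, sequence, abundance) triples as single-line FASTA."""
    dialect = dialect or AbundanceDialect()
    with open(path, "w") as fh:
        for rec_id, seq, abundance in amplicons:
            fh.write(f">{dialect.format_id(rec_id, abundance)}\n{seq}\n")
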