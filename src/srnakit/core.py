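"""Core read and alignment containers shared by all pipeline stages.

Coordinates are 0-based, half-open throughout.  The 5' end of a minus-strand
alignment is ``end - 1``; plus-strand 5' is ``start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse-complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Read(NamedTuple):
    """A (possibly collapsed) sequencing read."""

    id: str
    seq: str
    count: int = 1


@dataclass
class ReadSet:
    """A small-RNA library: reads with multiplicities plus a library id."""

    library_id: str
    reads: list[Read]

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def validate(self) -> None:
        seen: set[str] = set()
        for r in self.reads:
            if not r.seq:
                raise ValueError(f"empty sequence for read {r.id!r}")
            if not set(r.seq) <= VALID_BASES:
                raise ValueError(f"non-ACGTN characters in read {r.id!r}")
            if r.count < 1:
                raise ValueError(f"multiplicity < 1 for read {r.id!r}")
            if r.id in seen:
                raise ValueError(f"duplicate read id {r.id!r}")
            seen.add(r.id)

    def select_sizes(self, min_len: int, max_len: int) -> "ReadSet":
        """Reads whose length is within [min_len, max_len]."""
        if min_len > max_len:
            raise ValueError("min_len must be <= max_len")
        kept = [r for r in self.reads if min_len <= len(r.seq) <= max_len]
        return ReadSet(self.library_id, kept)


class Mismatch(NamedTuple):
    """A single substitution, in forward-reference space.

    ``ref_pos`` is the absolute 0-based position on the reference;
    ``read_base`` is the base the read presents on the forward reference
    strand (i.e. already complemented for minus-strand alignments).
    """

    ref_pos: int
    ref_base: str
    read_base: str


class Alignment(NamedTuple):
    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: tuple[Mismatch, ...]
    count: int  # read multiplicity
    n_best: int  # equally good placements in the best stratum

    @property
    def read_length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class AlignmentSet:
    """Placements of a library's reads on a reference set."""

    library_id: str
    alignments: list[Alignment]
    ref_lengths: dict[str, int]
    n_reads_input: int = 0
    n_reads_aligned: int = 0

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self) -> Iterator[Alignment]:
        return iter(self.alignments)

    def validate(self) -> None:
        for a in self.alignments:
            rlen = self.ref_lengths[a.ref_id]
            if not (0 <= a.start < a.end <= rlen):
                raise ValueError(f"out-of-bounds alignment for read {a.read_id!r}")
            if a.strand not in "+-":
                raise ValueError(f"bad strand {a.strand!r}")

    def aligned_read_ids(self) -> set[str]:
        return {a.read_id for a in self.alignments}
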