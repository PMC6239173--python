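"""Substitution-type spectrum of 21-nt TE-aligned reads (A->G editing readout).

Counts, for each of the 12 ordered substitution types, the fraction of
aligned 21-nt reads carrying that mismatch.  Mismatches on antisense
placements are complemented so that A->G always refers to the transcribed
sense base — deamination on the transcript reads as A->G regardless of the
strand the read aligned to.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import pandas as pd

from .core import AlignmentSet

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_TYPES = [(r, q) for r, q in permutations("ACGT", 2)]


@dataclass
class MismatchSpectrum:
    """Counts and fractions of the 12 substitution types for one library."""

    library_id: str
    counts: dict[tuple[str, str], int]
    total_aligned: int

    @property
    def fractions(self) -> dict[tuple[str, str], float]:
        return {t: c / self.total_aligned for t, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r, q, self.counts[(r, q)], self.counts[(r, q)] / self.total_aligned)
            for r, q in SUBSTITUTION_TYPES
        ]
        return pd.DataFrame(rows, columns=["ref_base", "read_base", "count", "fraction"])


def mismatch_spectrum(aln: AlignmentSet, read_length: int = 21) -> MismatchSpectrum:
    """Substitution-type spectrum from single-placement alignments.

    Expects one placement per read (unique or seeded random-one mode);
    raises if a read has several placements.  The denominator counts every
    aligned read of the requested length exactly once, mismatch or not.
    """
    seen: set[str] = set()
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    total = 0
    for a in aln:
        if a.read_length != read_length:
            continue
        if a.read_id in seen:
            raise ValueError(
                f"read {a.read_id!r} has multiple placements; "
                "run the aligner in unique or random_one mode first"
            )
        seen.add(a.read_id)
        total += a.count
        for mm in a.mismatches:
            ref_b, read_b = mm.ref_base, mm.read_base
            if a.strand == "-":
                ref_b, read_b = _COMP[ref_b], _COMP[read_b]
            if (ref_b, read_b) in counts:
                counts[(ref_b, read_b)] += a.count
    if total == 0:
        raise ValueError("no aligned reads of the requested length")
    return MismatchSpectrum(aln.library_id, counts, total)


def ag_excess(spectrum: MismatchSpectrum) -> float:
    """A->G fraction minus the mean of the other 11 substitution fractions."""
    fr = spectrum.fractions
    ag = fr[("A", "G")]
    others = [v for t, v in fr.items() if t != ("A", "G")]
    return ag - sum(others) / len(others)
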