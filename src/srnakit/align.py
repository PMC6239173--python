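"""Short-read alignment with at most one mismatch.

The contract mirrors classic seed-free small-RNA alignment: report every
placement in the best mismatch stratum (an exact hit for a read suppresses
its one-mismatch hits), on either strand.  Three reporting modes are
supported: ``all`` placements, ``unique`` (reads with exactly one
best-stratum placement), and ``random_one`` (one placement per read chosen
uniformly at random, seeded).

Implementation: an exact-substring dictionary over the reference, queried
with the read and, when needed, with each of its 3L single-substitution
variants.  This is exact (the placement set is identical to a brute-force
sliding-window scan) and fast for the short references used here.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np

from .core import Alignment, AlignmentSet, Mismatch, Read, ReadSet, revcomp

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def build_index(refs: Mapping[str, str], lengths: Sequence[int]) -> dict[str, list[tuple[str, int]]]:
    """Map every reference substring of the given lengths to its placements."""
    index: dict[str, list[tuple[str, int]]] = {}
    for rid, seq in refs.items():
        n = len(seq)
        for length in set(lengths):
            for i in range(n - length + 1):
                key = seq[i : i + length]
                if key in index:
                    index[key].append((rid, i))
                else:
                    index[key] = [(rid, i)]
    return index


def _query(seq: str, index: dict, max_mm: int) -> list[tuple[str, int, str, tuple[Mismatch, ...]]]:
    """Best-stratum placements of one read sequence: (ref, start, strand, mismatches)."""
    hits: list[tuple[str, int, str, tuple[Mismatch, ...]]] = []
    rc = revcomp(seq)
    for rid, st in index.get(seq, ()):
        hits.append((rid, st, "+", ()))
    for rid, st in index.get(rc, ()):
        hits.append((rid, st, "-", ()))
    if hits or max_mm == 0:
        return hits
    # one-mismatch stratum: substitute each position in turn
    for i, base in enumerate(seq):
        prefix, suffix = seq[:i], seq[i + 1 :]
        for b in _BASES:
            if b == base:
                continue
            for rid, st in index.get(prefix + b + suffix, ()):
                hits.append((rid, st, "+", (Mismatch(st + i, b, base),)))
    for j, base in enumerate(rc):
        prefix, suffix = rc[:j], rc[j + 1 :]
        for b in _BASES:
            if b == base:
                continue
            for rid, st in index.get(prefix + b + suffix, ()):
                # read presents rc[j] on the forward reference strand
                hits.append((rid, st, "-", (Mismatch(st + j, b, base),)))
    return hits


def align(
    reads: ReadSet,
    refs: Mapping[str, str],
    max_mm: int = 1,
    mode: str = "all",
    seed: int | None = None,
    strands: str = "both",
) -> AlignmentSet:
    """Align a ReadSet against a set of reference sequences.

    Parameters
    ----------
    max_mm : 0 or 1
        Maximum mismatches; an exact hit always suppresses one-mismatch hits.
    mode : {'all', 'unique', 'random_one'}
        Placement reporting mode.
    seed : int, optional
        Required for mode='random_one'.
    strands : {'both', 'fwd'}
        'fwd' restricts to sense placements (used for precursor matching).
    """
    if not refs or all(len(s) == 0 for s in refs.values()):
        raise ValueError("reference set is empty")
    if max_mm not in (0, 1):
        raise ValueError("max_mm must be 0 or 1")
    if mode not in ("all", "unique", "random_one"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "random_one" and seed is None:
        raise ValueError("mode='random_one' requires a seed")
    if strands not in ("both", "fwd"):
        raise ValueError(f"unknown strands {strands!r}")

    groups: dict[str, list[Read]] = defaultdict(list)
    for r in reads:
        groups[r.seq].append(r)
    lengths = {len(s) for s in groups}
    index = build_index(refs, sorted(lengths))

    rng = np.random.default_rng(seed) if mode == "random_one" else None
    out: list[Alignment] = []
    aligned_count = 0
    for seq in groups:
        hits = _query(seq, index, max_mm)
        if strands == "fwd":
            hits = [h for h in hits if h[2] == "+"]
        if not hits:
            continue
        n_best = len(hits)
        length = len(seq)
        for r in groups[seq]:
            if mode == "unique":
                if n_best != 1:
                    continue
                chosen = hits
            elif mode == "random_one":
                chosen = [hits[int(rng.integers(n_best))]] if n_best > 1 else hits
            else:
                chosen = hits
            aligned_count += r.count
            for rid, st, strand, mms in chosen:
                out.append(Alignment(r.id, rid, st, st + length, strand, mms, r.count, n_best))

    return AlignmentSet(
        library_id=reads.library_id,
        alignments=out,
        ref_lengths={rid: len(s) for rid, s in refs.items()},
        n_reads_input=reads.total_count,
        n_reads_aligned=aligned_count,
    )


def size_select(aln: AlignmentSet, min_len: int, max_len: int) -> AlignmentSet:
    """Retain alignments whose read length lies within [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = [a for a in aln.alignments if min_len <= a.read_length <= max_len]
    aligned = sum({a.read_id: a.count for a in kept}.values())
    return AlignmentSet(aln.library_id, kept, aln.ref_lengths, aln.n_reads_input, aligned)


def filter_blocklist(reads: ReadSet, blocklist: Mapping[str, str], max_mm: int = 1) -> ReadSet:
    """Drop reads that align (<= max_mm mismatches, either strand) to any blocklist sequence.

    An empty blocklist is the identity.
    """
    if not blocklist:
        return ReadSet(reads.library_id, list(reads.reads))
    lengths = {len(r.seq) for r in reads}
    index = build_index(blocklist, sorted(lengths))
    kept = []
    checked: dict[str, bool] = {}
    for r in reads:
        blocked = checked.get(r.seq)
        if blocked is None:
            blocked = bool(_query(r.seq, index, max_mm))
            checked[r.seq] = blocked
        if not blocked:
            kept.append(r)
    return ReadSet(reads.library_id, kept)
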