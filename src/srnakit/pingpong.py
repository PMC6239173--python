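"""Five-prime overlap ("ping-pong") signature scoring and library classification.

The signature counts sense/antisense read pairs whose 5' ends overlap by
d nucleotides for d in a window (default 5..15), converts the counts into
z-scores over the window, and calls a library positive, negative, or
intermediate based on the z-score and pair count at d = 10.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import AlignmentSet

D_MIN_DEFAULT = 5
D_MAX_DEFAULT = 15

Z_POSITIVE_THRESHOLD = 2.0
PAIRS_POSITIVE_THRESHOLD = 20  # strict: pairs must exceed this


@dataclass
class FivePrimeProfile:
    """Per (reference, strand) map of 5'-end coordinate -> summed multiplicity."""

    sense: dict[str, dict[int, int]]
    antisense: dict[str, dict[int, int]]
    size_range: tuple[int, int] | None = None


@dataclass
class OverlapSignature:
    d_min: int
    d_max: int
    counts: np.ndarray  # pair counts, one per overlap d
    z: np.ndarray
    call: str = "intermediate"

    @property
    def overlaps(self) -> np.ndarray:
        return np.arange(self.d_min, self.d_max + 1)

    def count_at(self, d: int) -> float:
        return float(self.counts[d - self.d_min])

    def z_at(self, d: int) -> float:
        return float(self.z[d - self.d_min])

    @property
    def n_pairs_10(self) -> float:
        return self.count_at(10)

    @property
    def z_10(self) -> float:
        return self.z_at(10)


def fiveprime_profile(
    aln: AlignmentSet, size_range: tuple[int, int] | None = None
) -> FivePrimeProfile:
    """Collapse alignments to 5'-end coordinate profiles per reference and strand.

    Sense 5' is the alignment start; antisense 5' is end - 1.  Multiplicities
    are summed per coordinate.  ``size_range`` optionally restricts read lengths
    (inclusive bounds), e.g. (24, 28).
    """
    sense: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    anti: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    lo, hi = size_range if size_range is not None else (0, 10**9)
    for a in aln:
        if not (lo <= a.read_length <= hi):
            continue
        if a.strand == "+":
            sense[a.ref_id][a.start] += a.count
        else:
            anti[a.ref_id][a.end - 1] += a.count
    return FivePrimeProfile(
        sense={k: dict(v) for k, v in sense.items()},
        antisense={k: dict(v) for k, v in anti.items()},
        size_range=size_range,
    )


def overlap_counts(
    profile: FivePrimeProfile,
    d_min: int = D_MIN_DEFAULT,
    d_max: int = D_MAX_DEFAULT,
    pair_mode: str = "product",
) -> np.ndarray:
    """Pair counts for each 5'-overlap d in [d_min, d_max], summed over references.

    Overlap d means the sense and antisense 5' ends span d reverse-complementary
    bases: d = antisense5' - sense5' + 1 on reference coordinates.  With
    pair_mode='product' each coordinate pair contributes the product of read
    multiplicities; 'unique' counts each occupied coordinate pair once.
    """
    if pair_mode not in ("product", "unique"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    n = d_max - d_min + 1
    counts = np.zeros(n, dtype=np.int64)
    for ref, s_map in profile.sense.items():
        a_map = profile.antisense.get(ref)
        if not a_map:
            continue
        for i, d in enumerate(range(d_min, d_max + 1)):
            shift = d - 1
            total = 0
            for p, ns in s_map.items():
                na = a_map.get(p + shift)
                if na:
                    total += ns * na if pair_mode == "product" else 1
            counts[i] += total
    return counts


def signature(
    counts: np.ndarray, d_min: int = D_MIN_DEFAULT, d_max: int = D_MAX_DEFAULT
) -> OverlapSignature:
    """z-transform pair counts over the overlap window.

    Each count has the window mean subtracted and is divided by the
    population (divide-by-n) standard deviation; if the standard deviation
    is zero all z-scores are zero.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (d_max - d_min + 1,):
        raise ValueError(f"expected {d_max - d_min + 1} counts, got {counts.shape}")
    sd = counts.std()  # population sd
    z = (counts - counts.mean()) / sd if sd > 0 else np.zeros_like(counts)
    sig = OverlapSignature(d_min=d_min, d_max=d_max, counts=counts, z=z)
    sig.call = classify(sig)
    return sig


def classify(sig: OverlapSignature) -> str:
    """Classify a library from its overlap signature.

    positive: z at 10 >= 2 and more than 20 pairs at 10-nt overlap;
    negative: z at 10 < 0; otherwise intermediate.
    """
    z10 = sig.z_10
    if z10 >= Z_POSITIVE_THRESHOLD and sig.n_pairs_10 > PAIRS_POSITIVE_THRESHOLD:
        return "positive"
    if z10 < 0:
        return "negative"
    return "intermediate"


def per_reference_signatures(
    profile: FivePrimeProfile,
    d_min: int = D_MIN_DEFAULT,
    d_max: int = D_MAX_DEFAULT,
    pair_mode: str = "product",
) -> dict[str, OverlapSignature]:
    """Diagnostic per-reference signatures (the library call aggregates refs)."""
    out = {}
    for ref in set(profile.sense) | set(profile.antisense):
        single = FivePrimeProfile(
            sense={ref: profile.sense.get(ref, {})},
            antisense={ref: profile.antisense.get(ref, {})},
            size_range=profile.size_range,
        )
        counts = overlap_counts(single, d_min=d_min, d_max=d_max, pair_mode=pair_mode)
        out[ref] = signature(counts, d_min=d_min, d_max=d_max)
    return out


def signature_from_alignments(
    aln: AlignmentSet,
    size_range: tuple[int, int] = (24, 28),
    d_min: int = D_MIN_DEFAULT,
    d_max: int = D_MAX_DEFAULT,
    pair_mode: str = "product",
) -> OverlapSignature:
    """Convenience pipeline: profile -> pair counts -> z-scores -> call."""
    profile = fiveprime_profile(aln, size_range=size_range)
    counts = overlap_counts(profile, d_min=d_min, d_max=d_max, pair_mode=pair_mode)
    return signature(counts, d_min=d_min, d_max=d_max)
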