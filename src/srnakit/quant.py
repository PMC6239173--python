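"""Strand/size-resolved TE small-RNA quantification.

Covers: per-library size/strand profiles in counts per 10 million mapped
reads (cp10m), 21-nt antisense per-family counts from unique alignments,
miRNA-anchored median-of-ratios size factors, abundance filters, log2
fold changes with Mann-Whitney comparison of their distributions, and
piRNA-cluster-exclusive read partitioning.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignmentSet

CP10M_SCALE = 1e7


@dataclass
class SizeProfile:
    """Counts by (read length, strand) with a cp10m normalization constant."""

    library_id: str
    table: pd.DataFrame  # columns: length, strand, raw, cp10m
    denominator: int


def size_profile(
    aln: AlignmentSet,
    denominator: int,
    len_range: tuple[int, int] = (18, 30),
) -> SizeProfile:
    """Per-length, per-strand read counts, raw and per 10 million mapped reads.

    Multi-placement reads count once (their first placement's strand is used,
    which is exact for unique/random-one input).
    """
    if denominator <= 0:
        raise ValueError("cp10m denominator must be > 0")
    seen: dict[str, tuple[int, str, int]] = {}
    for a in aln:
        if a.read_id not in seen:
            seen[a.read_id] = (a.read_length, a.strand, a.count)
    lo, hi = len_range
    rows = []
    agg: dict[tuple[int, str], int] = {}
    for length, strand, count in seen.values():
        if lo <= length <= hi:
            agg[(length, strand)] = agg.get((length, strand), 0) + count
    for length in range(lo, hi + 1):
        for strand in "+-":
            raw = agg.get((length, strand), 0)
            rows.append((length, strand, raw, raw * CP10M_SCALE / denominator))
    table = pd.DataFrame(rows, columns=["length", "strand", "raw", "cp10m"])
    return SizeProfile(aln.library_id, table, denominator)


def family_counts_21as(aln: AlignmentSet) -> pd.Series:
    """Per-family antisense read counts from 21-nt unique alignments.

    Expects alignments produced with mode='unique', max_mm<=1, and reads
    size-selected to 21 nt; only antisense placements are counted.
    """
    counts: dict[str, int] = {rid: 0 for rid in aln.ref_lengths}
    for a in aln:
        if a.read_length != 21:
            continue
        if a.strand == "-":
            counts[a.ref_id] = counts.get(a.ref_id, 0) + a.count
    return pd.Series(counts, dtype=int).sort_index()


@dataclass
class CountMatrix:
    """Features x libraries raw counts with per-feature roles and size factors."""

    counts: pd.DataFrame
    roles: pd.Series  # per-feature: 'te_family' or 'mirna'
    size_factors: pd.Series | None = None

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed yet")
        return self.counts / self.size_factors


def build_count_matrix(
    family_counts: dict[str, pd.Series], mirna_counts: pd.DataFrame
) -> CountMatrix:
    """Pool per-library 21-nt antisense family counts with miRNA counts.

    miRNA features anchor the normalization and are role-tagged so they can
    be excluded from fold-change reporting.
    """
    fam = pd.DataFrame(family_counts).fillna(0).astype(int)
    mirna = mirna_counts[fam.columns].astype(int)
    counts = pd.concat([fam, mirna])
    roles = pd.Series(
        ["te_family"] * len(fam) + ["mirna"] * len(mirna), index=counts.index
    )
    return CountMatrix(counts=counts, roles=roles)


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over features f (restricted to features with a
    positive geometric mean across libraries, i.e. nonzero everywhere) of
    count_fj / geomean_f.
    """
    counts = m.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("size factors require >= 2 libraries")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has nonzero counts in every library")
    sub = counts[positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    sf = pd.Series(factors, index=m.counts.columns)
    m.size_factors = sf
    return sf


def filter_families(values: pd.DataFrame, rule: str) -> list[str]:
    """Select features whose across-library mean passes an abundance filter.

    rule='cp10m_gt20'   : mean cp10m strictly greater than 20;
    rule='norm21as_ge5' : mean normalized 21-nt antisense count >= 5.
    ``values`` holds already-normalized per-library values, features x libraries.
    """
    means = values.mean(axis=1)
    if rule == "cp10m_gt20":
        kept = means[means > 20]
    elif rule == "norm21as_ge5":
        kept = means[means >= 5]
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    return list(kept.index)


@dataclass
class FoldChangeTable:
    """Per-family log2 fold change of normalized 21-nt antisense counts."""

    values: pd.Series  # finite log2 fold changes
    negative_infinite: list[str] = field(default_factory=list)


def log2fc(
    m: CountMatrix,
    mutant: list[str],
    control: list[str],
    families: list[str],
) -> FoldChangeTable:
    """log2(mean normalized mutant / mean normalized control) per kept family.

    No pseudocount: the abundance filter guarantees positive control means;
    a zero mutant mean yields -inf, which is flagged and excluded from
    distribution tests.
    """
    norm = m.normalized.loc[families]
    mut = norm[mutant].mean(axis=1)
    ctl = norm[control].mean(axis=1)
    if (ctl <= 0).any():
        bad = list(ctl[ctl <= 0].index)
        raise ValueError(f"non-positive control mean for families {bad}; apply the filter first")
    with np.errstate(divide="ignore"):
        lfc = np.log2(mut / ctl)
    neg_inf = list(lfc[np.isneginf(lfc)].index)
    return FoldChangeTable(values=lfc[np.isfinite(lfc)], negative_infinite=neg_inf)


def _mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    Enumerates all C(n1+n2, n1) assignments of the pooled observed values
    and counts those at least as extreme (|U - n1*n2/2|) as observed.
    Valid with ties.
    """
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(pooled)
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    obs_dev = abs(obs_u - center)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= obs_dev - 1e-12:
            extreme += 1
    return float(obs_u), extreme / total


def compare_fc_distributions(
    a: FoldChangeTable | np.ndarray, b: FoldChangeTable | np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two fold-change distributions.

    Exact enumeration when both sides have n <= 8; tie-corrected normal
    approximation (with continuity correction) otherwise.  Degenerate
    all-tied input gives p = 1.
    """
    x = np.asarray(a.values if isinstance(a, FoldChangeTable) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, FoldChangeTable) else b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must contain at least one finite value")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2, 1.0
    if len(x) <= 8 and len(y) <= 8:
        return _mannwhitney_exact(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cluster_exclusive_quant(
    aln_all: AlignmentSet,
    clusters: list[tuple[int, int]],
    insertions: list[tuple[int, int]],
    genome_id: str | None = None,
) -> dict:
    """Partition reads into piRNA-cluster-exclusive vs shared with insertions.

    A read is cluster-exclusive iff every best-stratum placement lies fully
    within a cluster interval and none overlaps a TE insertion interval.
    Requires alignments produced with mode='all' against the genome.
    Returns sense/antisense exclusive counts and the fraction of all aligned
    reads (the TE-matched denominator).
    """
    for cs, ce in clusters:
        for is_, ie in insertions:
            if cs < ie and is_ < ce:
                warnings.warn(
                    "cluster and insertion annotations overlap; "
                    "exclusivity rule resolves the conflict",
                    stacklevel=2,
                )

    per_read: dict[str, list] = {}
    for a in aln_all:
        if genome_id is not None and a.ref_id != genome_id:
            continue
        per_read.setdefault(a.read_id, []).append(a)

    n_total = 0
    sense = antisense = 0
    for rid, placements in per_read.items():
        count = placements[0].count
        n_total += count
        exclusive = True
        for a in placements:
            in_cluster = any(cs <= a.start and a.end <= ce for cs, ce in clusters)
            hits_insertion = any(a.start < ie and is_ < a.end for is_, ie in insertions)
            if not in_cluster or hits_insertion:
                exclusive = False
                break
        if exclusive:
            if placements[0].strand == "+":
                sense += count
            else:
                antisense += count

    n_exclusive = sense + antisense
    return {
        "sense": sense,
        "antisense": antisense,
        "exclusive": n_exclusive,
        "total_aligned": n_total,
        "fraction": n_exclusive / n_total if n_total else 0.0,
    }
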