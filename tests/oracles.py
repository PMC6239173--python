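"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with srnakit's implementations: the
aligner oracle is a sliding-window scan, the pair-count oracle enumerates
all sense/antisense alignment pairs, the BH oracle is a literal step-up
enumeration, and the size-factor oracle recomputes median-of-ratios from
its definition.
"""

from __future__ import annotations

import numpy as np

_CODE = {c: i for i, c in enumerate("ACGT")}
_RC = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def oracle_align_all(
    read_seq: str, refs: dict[str, str], max_mm: int
) -> set[tuple[str, int, str, int]]:
    """All best-stratum placements of one read: {(ref_id, start, strand, n_mm)}.

    O(N*M) sliding-window scan with <= max_mm mismatches on both strands;
    the best stratum (minimum mismatch count observed anywhere) suppresses
    worse placements.
    """
    hits: list[tuple[str, int, str, int]] = []
    queries = [(read_seq, "+"), (read_seq.translate(_RC)[::-1], "-")]
    L = len(read_seq)
    for rid, ref in refs.items():
        if len(ref) < L:
            continue
        enc_ref = _encode(ref)
        windows = np.lib.stride_tricks.sliding_window_view(enc_ref, L)
        for q, strand in queries:
            mm = (windows != _encode(q)).sum(axis=1)
            for start in np.nonzero(mm <= max_mm)[0]:
                hits.append((rid, int(start), strand, int(mm[start])))
    if not hits:
        return set()
    best = min(h[3] for h in hits)
    return {h for h in hits if h[3] == best}


def oracle_align_batch(
    read_seqs: list[str], ref: str, max_mm: int
) -> list[set[tuple[int, str, int]]]:
    """Best-stratum placements for many reads on one reference sequence.

    Vectorized sliding-window scan over all reads of each length at once;
    returns, per read, {(start, strand, n_mm)}.
    """
    enc_ref = _encode(ref)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(read_seqs):
        by_len.setdefault(len(s), []).append(i)
    out: list[list[tuple[int, str, int]]] = [[] for _ in read_seqs]
    for L, idxs in by_len.items():
        if len(ref) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc_ref, L)
        for strand in "+-":
            if strand == "+":
                mats = np.stack([_encode(read_seqs[i]) for i in idxs])
            else:
                mats = np.stack(
                    [_encode(read_seqs[i].translate(_RC)[::-1]) for i in idxs]
                )
            mm = np.zeros((len(idxs), windows.shape[0]), dtype=np.uint8)
            for j in range(L):
                mm += mats[:, j][:, None] != windows[:, j][None, :]
            rows, cols = np.nonzero(mm <= max_mm)
            for r, c in zip(rows, cols):
                out[idxs[int(r)]].append((int(c), strand, int(mm[r, c])))
    final = []
    for hits in out:
        if not hits:
            final.append(set())
            continue
        best = min(h[2] for h in hits)
        final.append({h for h in hits if h[2] == best})
    return final


def oracle_overlap_counts(
    alignments: list[tuple[str, int, int, str, int]],
    d_min: int = 5,
    d_max: int = 15,
) -> np.ndarray:
    """Pair counts by brute force over all sense/antisense alignment pairs.

    ``alignments`` entries are (ref_id, start, end, strand, count).  Every
    sense/antisense pair on the same reference contributes count_s * count_a
    to the overlap bin d = antisense5' - sense5' + 1.
    """
    counts = np.zeros(d_max - d_min + 1, dtype=np.int64)
    sense = [(r, s, c) for r, s, e, st, c in alignments if st == "+"]
    anti = [(r, e - 1, c) for r, s, e, st, c in alignments if st == "-"]
    for r_s, p, c_s in sense:
        for r_a, q, c_a in anti:
            if r_s != r_a:
                continue
            d = q - p + 1
            if d_min <= d <= d_max:
                counts[d - d_min] += c_s * c_a
    return counts


def oracle_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by literal step-up enumeration."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def oracle_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors recomputed from the definition."""
    counts = np.asarray(counts, dtype=float)
    geomeans = np.exp(np.log(np.where(counts > 0, counts, np.nan)).mean(axis=1))
    usable = ~np.isnan(geomeans) & (counts > 0).all(axis=1)
    factors = []
    for j in range(counts.shape[1]):
        ratios = counts[usable, j] / geomeans[usable]
        factors.append(float(np.median(ratios)))
    return np.array(factors)


def oracle_mannwhitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    U is computed by direct pair counting (wins + half-ties), not ranks.
    """
    from itertools import combinations

    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(idx_a: tuple[int, ...]) -> float:
        set_a = set(idx_a)
        a = [pooled[i] for i in idx_a]
        b = [pooled[i] for i in range(len(pooled)) if i not in set_a]
        return sum(
            1.0 if xa > yb else 0.5 if xa == yb else 0.0 for xa in a for yb in b
        )

    obs = u_stat(tuple(range(n1)))
    center = n1 * (len(pooled) - n1) / 2
    dev = abs(obs - center)
    assignments = list(combinations(range(len(pooled)), n1))
    extreme = sum(1 for c in assignments if abs(u_stat(c) - center) >= dev - 1e-12)
    return obs, extreme / len(assignments)
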