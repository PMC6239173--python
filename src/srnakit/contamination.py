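"""Gonadal-contamination detection for head small-RNA libraries.

Two complementary detectors:

* spike-in simulation — mix a defined fraction of gonadal reads into a
  ping-pong-negative head library and re-score the 5'-overlap signature;
* miRNA contamination signature — differential miRNA abundance between
  conditions, with Benjamini-Hochberg adjustment, and the overlap of the
  top-k simulated-contamination miRNAs with the observed comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import align
from .core import ReadSet
from .pingpong import OverlapSignature, signature_from_alignments
from .synthetic import GroundTruth, ReferenceBundle, mix_libraries


def downsample(reads: ReadSet, n: int, seed: int) -> ReadSet:
    """Sample exactly n reads without replacement (deterministic per seed)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > len(reads.reads):
        raise ValueError(f"cannot downsample to {n} from {len(reads.reads)} reads")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads.reads), size=n, replace=False))
    return ReadSet(reads.library_id, [reads.reads[int(i)] for i in idx])


def spike_and_test(
    head: ReadSet,
    gonad: ReadSet,
    n_head: int,
    n_spike: int,
    seed: int,
    ref: ReferenceBundle,
    size_range: tuple[int, int] = (24, 28),
    pair_mode: str = "product",
) -> tuple[OverlapSignature, dict]:
    """Mix gonadal reads into a head library and re-score the ping-pong signature.

    Reads in the piRNA size range are aligned to the TE family consensus set
    with <= 1 mismatch (one placement per multimapper, seeded), then the
    5'-overlap signature is computed and classified.  Returns the signature
    and a bookkeeping dict (realized spike fraction, origin counts).
    """
    mixed, gt = mix_libraries(head, gonad, n_head, n_spike, seed)
    sized = mixed.select_sizes(*size_range)
    aln = align(sized, ref.family_seqs(), max_mm=1, mode="random_one", seed=seed)
    sig = signature_from_alignments(aln, size_range=size_range, pair_mode=pair_mode)
    total = n_head + n_spike
    info = {
        "n_head": n_head,
        "n_spike": n_spike,
        "spike_fraction": n_spike / total if total else 0.0,
        "n_sized": len(sized.reads),
        "n_aligned": aln.n_reads_aligned,
        "call": sig.call,
        "z_10": sig.z_10,
        "n_pairs_10": sig.n_pairs_10,
        "origin_counts": gt.df["origin"].value_counts().to_dict(),
    }
    return sig, info


@dataclass
class MirnaCountTable:
    """Raw miRNA precursor counts per library plus library totals."""

    counts: pd.DataFrame  # precursors x libraries
    totals: pd.Series  # total reads per library (>= column sums)
    groups: dict[str, str] | None = None

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        colsums = self.counts.sum(axis=0)
        for lib in self.counts.columns:
            if self.totals[lib] < colsums[lib]:
                raise ValueError(f"library total below column sum for {lib!r}")


def mirna_counts(
    libraries: list[ReadSet], ref: ReferenceBundle, seed: int = 0
) -> MirnaCountTable:
    """Count reads matching miRNA precursors (<= 1 mismatch, sense strand).

    Reads matching several precursors are assigned to one uniformly at
    random (seeded).
    """
    precursors = ref.precursor_seqs()
    cols = {}
    totals = {}
    for i, lib in enumerate(libraries):
        aln = align(lib, precursors, max_mm=1, mode="random_one",
                    seed=seed + i, strands="fwd")
        per = {}
        for a in aln:
            per[a.ref_id] = per.get(a.ref_id, 0) + a.count
        cols[lib.library_id] = per
        totals[lib.library_id] = lib.total_count
    counts = (
        pd.DataFrame(cols, index=sorted(precursors)).fillna(0).astype(int)
    )
    return MirnaCountTable(counts=counts, totals=pd.Series(totals))


def _normalized(tbl: MirnaCountTable) -> pd.DataFrame:
    """Counts scaled to a common depth (mean library total)."""
    scale = tbl.totals.mean() / tbl.totals
    return tbl.counts * scale


def differential_mirna(
    tbl: MirnaCountTable,
    group_a: list[str],
    group_b: list[str],
    blocks: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-miRNA differential abundance between two library groups.

    Unpaired: an exact conditional binomial test on pooled counts — given
    x_a + x_b reads for a miRNA, x_a ~ Binomial(n, T_a / (T_a + T_b)) under
    the null, where T are group library totals.  Blocked: an exact sign test
    on per-block direction of the totals-normalized counts.  Benjamini-
    Hochberg adjustment across all tested miRNAs; log2 fold change from
    totals-normalized group means with a 0.5 pseudocount.

    Returns a DataFrame indexed by miRNA with columns log2fc, pval, padj.
    """
    tbl.validate()
    for lib in list(group_a) + list(group_b):
        if tbl.totals[lib] == 0:
            raise ValueError(f"zero-total library {lib!r}")
    if blocks is None and (len(group_a) < 2 or len(group_b) < 2):
        raise ValueError("unpaired test requires >= 2 libraries per group")

    norm = _normalized(tbl)
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    pvals = np.ones(len(tbl.counts))
    if blocks is None:
        ta = float(tbl.totals[group_a].sum())
        tb = float(tbl.totals[group_b].sum())
        p_null = ta / (ta + tb)
        xa = tbl.counts[group_a].sum(axis=1).to_numpy()
        xb = tbl.counts[group_b].sum(axis=1).to_numpy()
        for i, (a_i, n_i) in enumerate(zip(xa, xa + xb)):
            if n_i > 0:
                pvals[i] = stats.binomtest(int(a_i), int(n_i), p_null).pvalue
    else:
        for la, lb in blocks:
            if la not in group_a or lb not in group_b:
                raise ValueError("each block must pair one library from each group")
        diffs = np.stack(
            [(norm[la] - norm[lb]).to_numpy() for la, lb in blocks], axis=1
        )
        for i in range(diffs.shape[0]):
            row = diffs[i]
            m = int((row != 0).sum())
            if m > 0:
                k = int((row > 0).sum())
                pvals[i] = stats.binomtest(k, m, 0.5).pvalue

    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc.to_numpy(), "pval": pvals, "padj": padj},
        index=tbl.counts.index,
    )


def contamination_signature(
    sim_de: pd.DataFrame, obs_de: pd.DataFrame, k: int = 10, alpha: float = 0.01
) -> dict:
    """Overlap of the top-k simulated-contamination miRNAs with observed changes.

    Ranks sim_de by adjusted p (raw p as tiebreak), takes the top k, and
    reports how many of them have adjusted p < alpha in obs_de.
    """
    if not sim_de.index.equals(obs_de.index) and set(sim_de.index) != set(obs_de.index):
        raise ValueError("differential results must share the same miRNA universe")
    if k > len(sim_de):
        raise ValueError(f"k={k} exceeds the miRNA universe ({len(sim_de)})")
    top = sim_de.sort_values(["padj", "pval"]).head(k)
    hits = [m for m in top.index if obs_de.loc[m, "padj"] < alpha]
    return {
        "k": k,
        "alpha": alpha,
        "top_k": list(top.index),
        "overlap": len(hits),
        "overlapping_mirnas": hits,
    }
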