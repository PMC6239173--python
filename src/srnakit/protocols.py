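"""Desk-scale experiment protocols built from the pipeline stages.

These wire the simulator to the analysis stages for the standard
contamination experiments: a ping-pong-negative head library spiked with a
small fraction of gonadal reads, re-scored over many seeded replicates.
Scaled 1:10 relative to the original library sizes (245,000 + 5,000 reads
instead of 2.45e6 + 5e4) so a full 100-replicate sweep runs on one CPU in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contamination import spike_and_test
from .synthetic import LibrarySpec, ReferenceBundle, make_reference, simulate_library

HEAD_N_READS = 245_000
SPIKE_N_READS = 5_000
GONAD_N_READS = 50_000

HEAD_MIX = {
    "mirna": 0.30,
    "sirna_21": 0.35,
    "pirna_like": 0.10,
    "degradation": 0.20,
    "decoy": 0.05,
}
GONAD_MIX = {
    "mirna": 0.30,
    "sirna_21": 0.20,
    "pirna_like": 0.30,
    "degradation": 0.15,
    "decoy": 0.05,
}
GONAD_RHO = 0.6
GONAD_HOTSPOTS = 64


def spike_reference(seed: int) -> ReferenceBundle:
    return make_reference(
        n_families=4,
        n_insertions_per_family=2,
        n_mirnas=20,
        n_clusters=2,
        seed=seed,
        family_len_range=(3000, 5000),
    )


def head_spec(seed: int, n_reads: int = HEAD_N_READS) -> LibrarySpec:
    return LibrarySpec(
        n_reads=n_reads,
        class_mix=dict(HEAD_MIX),
        pingpong_rho=0.0,
        seq_error_rate=0.01,
        editing_rate=0.04,
        seed=seed,
        library_id=f"head{seed}",
    )


def gonad_spec(seed: int, n_reads: int = GONAD_N_READS) -> LibrarySpec:
    return LibrarySpec(
        n_reads=n_reads,
        class_mix=dict(GONAD_MIX),
        pingpong_rho=GONAD_RHO,
        antisense_bias={"pirna_like": 0.8},
        pirna_hotspots=GONAD_HOTSPOTS,
        seq_error_rate=0.01,
        seed=seed,
        library_id=f"gonad{seed}",
    )


@dataclass
class SpikeSweepResult:
    """Per-replicate signature summaries for spiked and unspiked libraries."""

    spiked_z10: list[float] = field(default_factory=list)
    spiked_pairs10: list[float] = field(default_factory=list)
    spiked_calls: list[str] = field(default_factory=list)
    null_z10: list[float] = field(default_factory=list)
    null_calls: list[str] = field(default_factory=list)


def run_spike_replicates(
    master_seed: int,
    n_replicates: int = 100,
    include_null: bool = True,
    n_head: int = HEAD_N_READS,
    n_spike: int = SPIKE_N_READS,
) -> SpikeSweepResult:
    """Replicate spike-in experiments with independent libraries per seed.

    Each replicate draws fresh head and gonadal libraries on a shared
    reference, mixes ``n_spike`` gonadal reads into ``n_head`` head reads
    (2% at default scale), and scores the 5'-overlap signature of the
    24-28-nt TE-aligned fraction; optionally also scores the unspiked head
    library as the matched null.
    """
    ref = spike_reference(master_seed)
    seeds = np.random.SeedSequence(master_seed).generate_state(3 * n_replicates)
    result = SpikeSweepResult()
    for i in range(n_replicates):
        s_head, s_gonad, s_mix = (int(x) for x in seeds[3 * i : 3 * i + 3])
        head, _ = simulate_library(head_spec(s_head, n_head), ref)
        gonad, _ = simulate_library(gonad_spec(s_gonad), ref)
        sig, _ = spike_and_test(head, gonad, n_head, n_spike, s_mix, ref)
        result.spiked_z10.append(sig.z_10)
        result.spiked_pairs10.append(sig.n_pairs_10)
        result.spiked_calls.append(sig.call)
        if include_null:
            sig0, _ = spike_and_test(head, gonad, n_head, 0, s_mix, ref)
            result.null_z10.append(sig0.z_10)
            result.null_calls.append(sig0.call)
    return result
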