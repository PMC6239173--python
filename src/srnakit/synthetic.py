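"""Synthetic small-RNA libraries with planted, parameterized ground truth.

Generates a reference bundle (TE family consensus sequences, diverged
genomic insertions, piRNA-cluster-like regions with guaranteed-unique
subsequences, miRNA precursors, blocklist decoys, and a synthetic genome)
and read libraries with controlled class mixture, strand bias, planted
10-nt 5'-overlap ping-pong pairs, per-family siRNA abundance multipliers,
A->G editing, and single-substitution sequencing errors.  Every read gets
a ground-truth record so downstream estimates can be validated against
planted parameters.

All randomness flows from one ``numpy.random.default_rng(seed)`` per call;
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Read, ReadSet, revcomp

CLASSES = ("mirna", "sirna_21", "pirna_like", "degradation", "decoy")
#: classes derived from double-stranded precursors, eligible for A->G editing
DS_DERIVED = frozenset({"sirna_21"})

#: discrete triangular length distribution for piRNA-like reads, peak at 26
PIRNA_LENGTHS = np.arange(24, 29)
PIRNA_LENGTH_P = np.array([1, 2, 3, 2, 1], dtype=float) / 9.0

DEGRADATION_LEN_RANGE = (18, 30)
SIRNA_LENGTH = 21

DEFAULT_ANTISENSE_BIAS = {
    "mirna": 0.0,
    "sirna_21": 0.5,
    "pirna_like": 0.5,
    "degradation": 0.1,  # degradation products are sense-biased
    "decoy": 0.5,
}

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, n)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Copy of seq with each base substituted independently at the given rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = np.searchsorted(_BASE_BYTES, arr)  # ACGT are sorted by byte value
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    idx[hit] = (idx[hit] + rng.integers(1, 4, hit.size)) % 4
    return _BASE_BYTES[idx].tobytes().decode("ascii")


@dataclass
class TEFamily:
    id: str
    seq: str


@dataclass
class TEInsertion:
    id: str
    family_id: str
    seq: str
    start: int  # genome coordinates, 0-based half-open
    end: int


@dataclass
class PirnaCluster:
    id: str
    start: int
    end: int
    #: genome intervals inside the cluster whose sequence occurs at no insertion
    unique_regions: list[tuple[int, int]]


@dataclass
class Mirna:
    id: str
    precursor: str
    mature_start: int
    mature_end: int

    @property
    def mature(self) -> str:
        return self.precursor[self.mature_start : self.mature_end]


@dataclass
class ReferenceBundle:
    genome_id: str
    genome: str
    te_families: list[TEFamily]
    te_insertions: list[TEInsertion]
    pirna_clusters: list[PirnaCluster]
    mirnas: list[Mirna]
    blocklist: dict[str, str]

    def family_seqs(self) -> dict[str, str]:
        return {f.id: f.seq for f in self.te_families}

    def insertion_seqs(self) -> dict[str, str]:
        return {i.id: i.seq for i in self.te_insertions}

    def precursor_seqs(self) -> dict[str, str]:
        return {m.id: m.precursor for m in self.mirnas}

    def validate(self) -> None:
        ids = (
            [f.id for f in self.te_families]
            + [i.id for i in self.te_insertions]
            + [c.id for c in self.pirna_clusters]
            + [m.id for m in self.mirnas]
            + list(self.blocklist)
        )
        if len(ids) != len(set(ids)):
            raise ValueError("reference ids are not unique")
        for c in self.pirna_clusters:
            for s, e in c.unique_regions:
                sub = self.genome[s:e]
                for ins in self.te_insertions:
                    if sub in ins.seq or revcomp(sub) in ins.seq:
                        raise ValueError(
                            f"cluster-unique region of {c.id} occurs in insertion {ins.id}"
                        )


def make_reference(
    n_families: int,
    n_insertions_per_family: int,
    n_mirnas: int,
    n_clusters: int,
    seed: int,
    family_len_range: tuple[int, int] = (3000, 8000),
    divergence: float = 0.01,
    cluster_fragments: int = 4,
    cluster_unique_len: int = 300,
    n_blocklist: int = 3,
    spacer_len: int = 200,
) -> ReferenceBundle:
    """Build a deterministic synthetic reference bundle.

    Each cluster carries at least one >=200-nt subsequence absent from every
    insertion (validated, explicit failure otherwise), so cluster-exclusive
    read partitioning has a guaranteed substrate.
    """
    for name, v in [
        ("n_families", n_families),
        ("n_insertions_per_family", n_insertions_per_family),
        ("n_mirnas", n_mirnas),
        ("n_clusters", n_clusters),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    if cluster_unique_len < 200:
        raise ValueError("cluster_unique_len must be >= 200 for the uniqueness contract")

    rng = np.random.default_rng(seed)
    families = [
        TEFamily(f"TEfam{i}", _random_seq(rng, int(rng.integers(*family_len_range))))
        for i in range(n_families)
    ]

    genome_parts: list[str] = []
    cursor = 0

    def _append(seq: str) -> tuple[int, int]:
        nonlocal cursor
        genome_parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start, cursor

    insertions: list[TEInsertion] = []
    for fam in families:
        for j in range(n_insertions_per_family):
            _append(_random_seq(rng, spacer_len))
            ins_seq = _diverge(fam.seq, divergence, rng)
            s, e = _append(ins_seq)
            insertions.append(TEInsertion(f"{fam.id}_ins{j}", fam.id, ins_seq, s, e))

    clusters: list[PirnaCluster] = []
    for k in range(n_clusters):
        _append(_random_seq(rng, spacer_len))
        frag_parts: list[str] = []
        unique_offsets: list[tuple[int, int]] = []
        insert_at = int(rng.integers(0, cluster_fragments + 1))
        off = 0
        for fi in range(cluster_fragments + 1):
            if fi == insert_at:
                uniq = _random_seq(rng, cluster_unique_len)
                frag_parts.append(uniq)
                unique_offsets.append((off, off + cluster_unique_len))
                off += cluster_unique_len
            if fi < cluster_fragments:
                fam = families[int(rng.integers(n_families))]
                flen = int(rng.integers(300, 801))
                fstart = int(rng.integers(0, len(fam.seq) - flen + 1))
                frag = fam.seq[fstart : fstart + flen]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                frag_parts.append(frag)
                off += flen
        cseq = "".join(frag_parts)
        s, e = _append(cseq)
        clusters.append(
            PirnaCluster(
                f"cluster{k}", s, e, [(s + us, s + ue) for us, ue in unique_offsets]
            )
        )
    _append(_random_seq(rng, spacer_len))

    mirnas = []
    for i in range(n_mirnas):
        plen = int(rng.integers(60, 121))
        mlen = int(rng.integers(21, 24))
        mstart = int(rng.integers(10, plen - mlen - 9))
        mirnas.append(Mirna(f"mir{i}", _random_seq(rng, plen), mstart, mstart + mlen))

    blocklist = {
        f"decoy{i}": _random_seq(rng, int(rng.integers(500, 2001)))
        for i in range(n_blocklist)
    }

    bundle = ReferenceBundle(
        genome_id="synth1",
        genome="".join(genome_parts),
        te_families=families,
        te_insertions=insertions,
        pirna_clusters=clusters,
        mirnas=mirnas,
        blocklist=blocklist,
    )
    bundle.validate()
    return bundle


@dataclass
class LibrarySpec:
    """Parameters of one simulated library; see module docstring."""

    n_reads: int
    class_mix: dict[str, float]
    pingpong_rho: float = 0.0
    antisense_bias: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANTISENSE_BIAS)
    )
    sirna_fc: dict[str, float] = field(default_factory=dict)
    editing_rate: float = 0.0
    seq_error_rate: float = 0.0
    mirna_profile: Sequence[float] | None = None
    cluster_unique_frac: float = 0.0
    #: when set, antisense piRNA-like 5' ends recur at this many positions
    #: (summed over families), emulating the positional reuse of real piRNA
    #: 5' ends; required for a signature that survives subsampling
    pirna_hotspots: int | None = None
    seed: int = 0
    library_id: str = "lib"

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        unknown = set(self.class_mix) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total})")
        for name, p in [
            ("pingpong_rho", self.pingpong_rho),
            ("editing_rate", self.editing_rate),
            ("seq_error_rate", self.seq_error_rate),
            ("cluster_unique_frac", self.cluster_unique_frac),
            *[(f"class_mix[{k}]", v) for k, v in self.class_mix.items()],
            *[(f"antisense_bias[{k}]", v) for k, v in self.antisense_bias.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {p})")
        if self.pingpong_rho > 0 and self.class_mix.get("pirna_like", 0.0) == 0:
            raise ValueError("pingpong_rho > 0 requires a nonzero pirna_like class")
        if self.editing_rate > 0 and not any(
            self.class_mix.get(c, 0.0) > 0 for c in DS_DERIVED
        ):
            raise ValueError("editing_rate > 0 requires a nonzero ds-derived class")


@dataclass
class GroundTruth:
    """Per-read truth table (one row per emitted read)."""

    df: pd.DataFrame

    def feature_counts(self) -> pd.DataFrame:
        """True per-feature read counts by class and strand."""
        return (
            self.df.groupby(["source_id", "label", "strand"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )

    def validate_against(self, reads: ReadSet) -> None:
        ids = {r.id for r in reads}
        gt_ids = set(self.df["read_id"])
        if ids != gt_ids:
            raise ValueError("ground truth does not cover the read set exactly")


class _Emitter:
    """Accumulates reads and ground-truth rows with sequential ids."""

    def __init__(self, library_id: str):
        self.library_id = library_id
        self.reads: list[Read] = []
        self.rows: dict[str, list] = {
            k: []
            for k in (
                "read_id",
                "label",
                "source_id",
                "strand",
                "five_prime",
                "length",
                "edited",
                "error",
                "pp_partner",
            )
        }

    def emit(
        self,
        label: str,
        source_id: str,
        strand: str,
        five_prime: int,
        seq: str,
        edited: bool = False,
        error: bool = False,
        pp_partner: bool = False,
    ) -> None:
        rid = f"{self.library_id}:r{len(self.reads):07d}"
        self.reads.append(Read(rid, seq, 1))
        r = self.rows
        r["read_id"].append(rid)
        r["label"].append(label)
        r["source_id"].append(source_id)
        r["strand"].append(strand)
        r["five_prime"].append(five_prime)
        r["length"].append(len(seq))
        r["edited"].append(edited)
        r["error"].append(error)
        r["pp_partner"].append(pp_partner)

    def finish(self) -> tuple[ReadSet, GroundTruth]:
        df = pd.DataFrame(self.rows)
        df["origin"] = self.library_id
        return ReadSet(self.library_id, self.reads), GroundTruth(df)


def _mutate_one(seq: str, pos: int, new_base: str) -> str:
    return seq[:pos] + new_base + seq[pos + 1 :]


def _apply_error(seq: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(seq)))
    base = seq[pos]
    options = [b for b in "ACGT" if b != base]
    return _mutate_one(seq, pos, options[int(rng.integers(len(options)))])


def _edit_one_a(seq: str, rng: np.random.Generator) -> str | None:
    a_pos = [i for i, ch in enumerate(seq) if ch == "A"]
    if not a_pos:
        return None
    return _mutate_one(seq, a_pos[int(rng.integers(len(a_pos)))], "G")


def simulate_library(spec: LibrarySpec, ref: ReferenceBundle) -> tuple[ReadSet, GroundTruth]:
    """Simulate one library according to ``spec`` on reference ``ref``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.class_mix.get(c, 0.0) for c in CLASSES])
    n_per_class = rng.multinomial(spec.n_reads, probs)
    em = _Emitter(spec.library_id)
    bias = {**DEFAULT_ANTISENSE_BIAS, **spec.antisense_bias}

    for cls, n in zip(CLASSES, n_per_class):
        if n == 0:
            continue
        if cls == "mirna":
            _gen_mirna(em, ref, n, spec, rng)
        elif cls == "sirna_21":
            _gen_sirna(em, ref, n, spec, bias["sirna_21"], rng)
        elif cls == "pirna_like":
            _gen_pirna_like(em, ref, n, spec, bias["pirna_like"], rng)
        elif cls == "degradation":
            _gen_degradation(em, ref, n, bias["degradation"], spec, rng)
        elif cls == "decoy":
            _gen_decoy(em, ref, n, bias["decoy"], spec, rng)

    return em.finish()


def _maybe_error(seq: str, spec: LibrarySpec, rng: np.random.Generator) -> tuple[str, bool]:
    if spec.seq_error_rate > 0 and rng.random() < spec.seq_error_rate:
        return _apply_error(seq, rng), True
    return seq, False


def _gen_mirna(em, ref, n, spec, rng) -> None:
    mirnas = ref.mirnas
    if spec.mirna_profile is not None:
        p = np.asarray(spec.mirna_profile, dtype=float)
        if p.size != len(mirnas):
            raise ValueError("mirna_profile length does not match reference miRNAs")
        p = p / p.sum()
    else:
        p = np.full(len(mirnas), 1.0 / len(mirnas))
    picks = rng.choice(len(mirnas), size=n, p=p)
    for i in picks:
        m = mirnas[int(i)]
        seq, err = _maybe_error(m.mature, spec, rng)
        em.emit("mirna", m.id, "+", m.mature_start, seq, error=err)


def _gen_sirna(em, ref, n, spec, anti_bias, rng) -> None:
    n_cluster = int(rng.binomial(n, spec.cluster_unique_frac)) if spec.cluster_unique_frac else 0
    n_ins = n - n_cluster

    # insertion-derived siRNAs, weighted by length x planted family multiplier
    fam_fc = spec.sirna_fc
    ins = ref.te_insertions
    w = np.array(
        [(len(i.seq) - SIRNA_LENGTH + 1) * fam_fc.get(i.family_id, 1.0) for i in ins],
        dtype=float,
    )
    picks = rng.choice(len(ins), size=n_ins, p=w / w.sum())
    pos_r = rng.random(n_ins)
    anti_r = rng.random(n_ins) < anti_bias
    edit_r = rng.random(n_ins) < spec.editing_rate if spec.editing_rate else np.zeros(n_ins, bool)
    records = []
    for k in range(n_ins):
        src = ins[int(picks[k])]
        start = int(pos_r[k] * (len(src.seq) - SIRNA_LENGTH + 1))
        frag = src.seq[start : start + SIRNA_LENGTH]
        if anti_r[k]:
            seq, strand, fp = revcomp(frag), "-", start + SIRNA_LENGTH - 1
        else:
            seq, strand, fp = frag, "+", start
        records.append([src.id, strand, fp, seq, bool(edit_r[k])])

    # cluster-unique siRNAs (genome coordinates)
    if n_cluster:
        regions = [
            (c.id, s, e) for c in ref.pirna_clusters for s, e in c.unique_regions
        ]
        rw = np.array([e - s - SIRNA_LENGTH + 1 for _, s, e in regions], dtype=float)
        rpicks = rng.choice(len(regions), size=n_cluster, p=rw / rw.sum())
        rpos = rng.random(n_cluster)
        ranti = rng.random(n_cluster) < anti_bias
        redit = (
            rng.random(n_cluster) < spec.editing_rate
            if spec.editing_rate
            else np.zeros(n_cluster, bool)
        )
        for k in range(n_cluster):
            cid, s, e = regions[int(rpicks[k])]
            start = s + int(rpos[k] * (e - s - SIRNA_LENGTH + 1))
            frag = ref.genome[start : start + SIRNA_LENGTH]
            if ranti[k]:
                seq, strand, fp = revcomp(frag), "-", start + SIRNA_LENGTH - 1
            else:
                seq, strand, fp = frag, "+", start
            records.append([cid, strand, fp, seq, bool(redit[k])])

    # plant edits; a flagged read without any A hands its flag to an A-bearing one
    no_a = [i for i, r in enumerate(records) if r[4] and "A" not in r[3]]
    if no_a:
        candidates = [i for i, r in enumerate(records) if not r[4] and "A" in r[3]]
        take = min(len(no_a), len(candidates))
        if take:
            moved = rng.choice(len(candidates), size=take, replace=False)
            for i in no_a:
                records[i][4] = False
            for j in moved:
                records[candidates[int(j)]][4] = True
        else:
            for i in no_a:
                records[i][4] = False

    for src_id, strand, fp, seq, edit in records:
        edited = False
        if edit:
            new = _edit_one_a(seq, rng)
            if new is not None:
                seq, edited = new, True
        seq, err = _maybe_error(seq, spec, rng)
        em.emit("sirna_21", src_id, strand, fp, seq, edited=edited, error=err)


def _gen_pirna_like(em, ref, n, spec, anti_bias, rng) -> None:
    fams = ref.te_families
    w = np.array([len(f.seq) for f in fams], dtype=float)
    picks = rng.choice(len(fams), size=n, p=w / w.sum())
    lens = rng.choice(PIRNA_LENGTHS, size=n, p=PIRNA_LENGTH_P)
    pos_r = rng.random(n)
    anti_r = rng.random(n)
    rho_r = rng.random(n)
    hotspots: list[tuple[int, int]] | None = None
    if spec.pirna_hotspots:
        # recurrent antisense 5' positions, allocated to families by length;
        # placed so that any read length (<=28) and any 10-overlap partner fit
        hotspots = []
        alloc = rng.multinomial(spec.pirna_hotspots, w / w.sum())
        for fi, n_h in enumerate(alloc):
            flen = len(fams[fi].seq)
            for a5 in rng.integers(27, flen - 19 + 1, size=n_h):
                hotspots.append((fi, int(a5)))
        if not hotspots:
            hotspots = None
    pending: deque[tuple[TEFamily, int]] = deque()
    rho = spec.pingpong_rho
    for k in range(n):
        length = int(lens[k])
        if pending:
            fam, a5 = pending.popleft()
            start = a5 - 9  # 10-nt 5'-5' overlap: sense 5' = antisense 5' - 9
            seq = fam.seq[start : start + length]
            seq, err = _maybe_error(seq, spec, rng)
            em.emit("pirna_like", fam.id, "+", start, seq, error=err, pp_partner=True)
            continue
        fam = fams[int(picks[k])]
        flen = len(fam.seq)
        antisense = anti_r[k] < anti_bias
        spawn = antisense and rho > 0 and rho_r[k] < rho
        if antisense and hotspots is not None:
            fi, a5 = hotspots[int(pos_r[k] * len(hotspots))]
            fam = fams[fi]
            flen = len(fam.seq)
            start = a5 - length + 1
        elif spawn:
            # constrain the antisense 5' end so any partner length fits
            lo, hi = length - 1, flen - 19
            a5 = lo + int(pos_r[k] * (hi - lo + 1))
            start = a5 - length + 1
        else:
            start = int(pos_r[k] * (flen - length + 1))
            a5 = start + length - 1
        frag = fam.seq[start : start + length]
        if antisense:
            seq, strand, fp = revcomp(frag), "-", a5
            if spawn:
                pending.append((fam, a5))
        else:
            seq, strand, fp = frag, "+", start
        seq, err = _maybe_error(seq, spec, rng)
        em.emit("pirna_like", fam.id, strand, fp, seq, error=err)


def _gen_degradation(em, ref, n, anti_bias, spec, rng) -> None:
    fams = ref.te_families
    w = np.array([len(f.seq) for f in fams], dtype=float)
    picks = rng.choice(len(fams), size=n, p=w / w.sum())
    lens = rng.integers(DEGRADATION_LEN_RANGE[0], DEGRADATION_LEN_RANGE[1] + 1, size=n)
    pos_r = rng.random(n)
    anti_r = rng.random(n) < anti_bias
    for k in range(n):
        fam = fams[int(picks[k])]
        length = int(lens[k])
        start = int(pos_r[k] * (len(fam.seq) - length + 1))
        frag = fam.seq[start : start + length]
        if anti_r[k]:
            seq, strand, fp = revcomp(frag), "-", start + length - 1
        else:
            seq, strand, fp = frag, "+", start
        seq, err = _maybe_error(seq, spec, rng)
        em.emit("degradation", fam.id, strand, fp, seq, error=err)


def _gen_decoy(em, ref, n, anti_bias, spec, rng) -> None:
    items = sorted(ref.blocklist.items())
    w = np.array([len(s) for _, s in items], dtype=float)
    picks = rng.choice(len(items), size=n, p=w / w.sum())
    lens = rng.integers(DEGRADATION_LEN_RANGE[0], DEGRADATION_LEN_RANGE[1] + 1, size=n)
    pos_r = rng.random(n)
    anti_r = rng.random(n) < anti_bias
    for k in range(n):
        bid, bseq = items[int(picks[k])]
        length = min(int(lens[k]), len(bseq))
        start = int(pos_r[k] * (len(bseq) - length + 1))
        frag = bseq[start : start + length]
        if anti_r[k]:
            seq, strand, fp = revcomp(frag), "-", start + length - 1
        else:
            seq, strand, fp = frag, "+", start
        seq, err = _maybe_error(seq, spec, rng)
        em.emit("decoy", bid, strand, fp, seq, error=err)


def mix_libraries(
    a: ReadSet,
    b: ReadSet,
    n_from_a: int,
    n_from_b: int,
    seed: int,
    gt_a: GroundTruth | None = None,
    gt_b: GroundTruth | None = None,
) -> tuple[ReadSet, GroundTruth]:
    """Sample without replacement from two libraries and pool the samples.

    Per-read origin is recorded in the returned ground truth; if the input
    ground truths are supplied their rows are carried over.
    """
    if n_from_a < 0 or n_from_b < 0:
        raise ValueError("sample sizes must be >= 0")
    if n_from_a > len(a.reads):
        raise ValueError(f"cannot sample {n_from_a} reads from {len(a.reads)}")
    if n_from_b > len(b.reads):
        raise ValueError(f"cannot sample {n_from_b} reads from {len(b.reads)}")
    rng = np.random.default_rng(seed)
    idx_a = np.sort(rng.choice(len(a.reads), size=n_from_a, replace=False))
    idx_b = np.sort(rng.choice(len(b.reads), size=n_from_b, replace=False))
    reads = [a.reads[int(i)] for i in idx_a] + [b.reads[int(i)] for i in idx_b]
    mixed = ReadSet(f"{a.library_id}+{b.library_id}", reads)

    frames = []
    for src, idx, gt in ((a, idx_a, gt_a), (b, idx_b, gt_b)):
        ids = [src.reads[int(i)].id for i in idx]
        if gt is not None:
            sub = gt.df.set_index("read_id").loc[ids].reset_index()
        else:
            sub = pd.DataFrame({"read_id": ids})
        sub["origin"] = src.library_id
        frames.append(sub)
    df = pd.concat(frames, ignore_index=True)
    return mixed, GroundTruth(df)
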