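"""File-format interfaces: FASTA/FASTQ reads, SAM alignments, BED intervals.

Collapsed FASTA uses the ``id_count`` header dialect (``>name_12`` means the
sequence was observed 12 times).  SAM is written with flags 0/16, 1-based
positions, a simple full-length match CIGAR, and an NM tag.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Alignment, AlignmentSet, Mismatch, Read, ReadSet

_COUNT_SUFFIX = re.compile(r"^(.*)_(\d+)$")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Reference FASTA as an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reads_fasta(path: str | Path, library_id: str | None = None) -> ReadSet:
    """Read a (possibly collapsed) FASTA read file; ``id_count`` headers set counts."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_SUFFIX.match(rec.id)
        if m:
            reads.append(Read(m.group(1), str(rec.seq).upper(), int(m.group(2))))
        else:
            reads.append(Read(rec.id, str(rec.seq).upper(), 1))
    return ReadSet(library_id or Path(path).stem, reads)


def read_reads_fastq(path: str | Path, library_id: str | None = None) -> ReadSet:
    reads = [
        Read(rec.id, str(rec.seq).upper(), 1) for rec in SeqIO.parse(str(path), "fastq")
    ]
    return ReadSet(library_id or Path(path).stem, reads)


def write_reads_fasta(reads: ReadSet, path: str | Path, collapsed: bool = True) -> None:
    """Write reads as FASTA; collapsed mode appends ``_count`` to each id."""
    records = (
        SeqRecord(
            Seq(r.seq),
            id=f"{r.id}_{r.count}" if collapsed else r.id,
            description="",
        )
        for r in reads
    )
    SeqIO.write(records, str(path), "fasta")


def write_reads_fastq(reads: ReadSet, path: str | Path, quality: int = 40) -> None:
    """Write reads as FASTQ with a constant quality value (expands multiplicities)."""
    def _records():
        for r in reads:
            for i in range(r.count):
                rid = r.id if r.count == 1 else f"{r.id}.{i}"
                rec = SeqRecord(Seq(r.seq), id=rid, description="")
                rec.letter_annotations["phred_quality"] = [quality] * len(r.seq)
                yield rec

    SeqIO.write(_records(), str(path), "fastq")


def write_sam(aln: AlignmentSet, path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": rid, "LN": length} for rid, length in aln.ref_lengths.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {rid: i for i, rid in enumerate(aln.ref_lengths)}
        for a in aln:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = tid[a.ref_id]
            seg.reference_start = a.start  # pysam handles the 1-based conversion
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.end - a.start}M"
            seg.set_tag("NM", len(a.mismatches))
            seg.set_tag("IH", a.n_best)
            seg.set_tag("XC", a.count)
            out.write(seg)


def read_sam(path: str | Path, library_id: str | None = None) -> AlignmentSet:
    """Load an AlignmentSet from SAM; mismatch details are not reconstructed."""
    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r") as f:
        ref_lengths = dict(zip(f.references, f.lengths))
        for seg in f:
            if seg.is_unmapped:
                continue
            strand = "-" if seg.is_reverse else "+"
            count = seg.get_tag("XC") if seg.has_tag("XC") else 1
            n_best = seg.get_tag("IH") if seg.has_tag("IH") else 1
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            mms = tuple(Mismatch(-1, "N", "N") for _ in range(nm))
            alignments.append(
                Alignment(
                    seg.query_name,
                    seg.reference_name,
                    seg.reference_start,
                    seg.reference_end,
                    strand,
                    mms,
                    int(count),
                    int(n_best),
                )
            )
    lib = library_id or Path(path).stem
    aligned = len({a.read_id for a in alignments})
    return AlignmentSet(lib, alignments, ref_lengths, n_reads_aligned=aligned)


def write_alignment_summary(alns: Iterable[AlignmentSet], path: str | Path) -> None:
    """TSV of per-library totals: reads in, reads aligned, placements."""
    with open(path, "w") as out:
        out.write("library\tn_reads_input\tn_reads_aligned\tn_placements\n")
        for a in alns:
            out.write(
                f"{a.library_id}\t{a.n_reads_input}\t{a.n_reads_aligned}\t"
                f"{len(a.alignments)}\n"
            )


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) intervals as 0-based half-open BED."""
    with open(path, "w") as out:
        for chrom, start, end, name in intervals:
            out.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    intervals = []
    with open(path) as f:
        for line in f:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else ""
            intervals.append((parts[0], int(parts[1]), int(parts[2]), name))
    return intervals
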