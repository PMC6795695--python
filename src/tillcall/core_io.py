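"""Readers and writers for the standard formats the pipeline touches.

Coordinate convention: **1-based inclusive** everywhere inside the package
(matching the text-pileup format and the mutation-table position field).
BED output converts to 0-based half-open at the boundary, and nowhere else.

The multi-sample pileup reader implements the samtools text-pileup dialect
(six columns per sample: depth, base string, quality string).  Base
qualities are parsed but carried no further: mutation support is counted
from read bases alone.  Upper/lower case (read strand) is collapsed because
calling is strand-agnostic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceContig",
    "PileupColumn",
    "ReadPairRecord",
    "PileupParseError",
    "FastaFormatError",
    "read_pileup",
    "write_pileup",
    "read_fasta",
    "write_fasta",
    "read_genome_fasta",
    "write_bed",
    "read_pairs_from_sam",
    "coverage_from_sam",
]

#: allele order used throughout: A, C, G, T, deletion (*), N
ALLELES = ("A", "C", "G", "T", "*")
ALLELE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "*": 4, "N": 5}

VALID_SEQUENCE_CHARS = frozenset("ACGTN")

CONTIG_ID_RE = re.compile(r"^ctg\d{6}$")


class PileupParseError(ValueError):
    """Raised when a pileup line cannot be decoded (names the line number)."""


class FastaFormatError(ValueError):
    """Raised on duplicate contig ids or disallowed sequence characters."""


@dataclass(frozen=True)
class ReferenceContig:
    """One contig of the constructed exome reference, with provenance.

    ``source_start``/``source_end`` are 1-based inclusive positions on the
    source assembly; both are 0 for de-novo contigs, whose placement on a
    chromosome is unknown.
    """

    contig_id: str
    sequence: str
    source: str = "denovo"  # one of {assembly_1, assembly_2, denovo}
    source_chrom: str = ""
    source_start: int = 0
    source_end: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_SEQUENCE_CHARS
        if bad:
            raise FastaFormatError(
                f"contig {self.contig_id!r}: disallowed sequence character(s) "
                f"{sorted(bad)}"
            )
        if self.source != "denovo" and self.source_chrom:
            span = self.source_end - self.source_start + 1
            if span != len(self.sequence):
                raise FastaFormatError(
                    f"contig {self.contig_id!r}: source span {span} != "
                    f"sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PileupColumn:
    """Per-sample allele counts at one reference position.

    ``counts`` maps sample id to ``(nA, nC, nG, nT, nDel, nN)``.  Per-sample
    depth is ``nA+nC+nG+nT+nDel``; N calls are excluded from depth and never
    support anything.
    """

    contig_id: str
    pos: int  # 1-based
    ref_base: str  # A, C, G, T or N
    counts: Mapping[str, tuple[int, int, int, int, int, int]]

    def depth(self, sample_id: str) -> int:
        c = self.counts[sample_id]
        return c[0] + c[1] + c[2] + c[3] + c[4]

    def allele_count(self, sample_id: str, allele: str) -> int:
        return self.counts[sample_id][ALLELE_INDEX[allele]]


@dataclass(frozen=True)
class ReadPairRecord:
    """A paired-end fragment reduced to what duplicate marking needs.

    Mates are canonically ordered so that ``left_start_1 <= left_start_2``.
    """

    query_name: str
    contig_id: str
    left_start_1: int
    left_start_2: int
    orientation: str  # FR, RF, FF or RR
    base_quality_sum: int = 0

    def __post_init__(self) -> None:
        if self.left_start_1 > self.left_start_2:
            raise ValueError(
                f"{self.query_name}: mates not canonically ordered "
                f"({self.left_start_1} > {self.left_start_2})"
            )


# ---------------------------------------------------------------------------
# pileup


def _decode_base_string(
    bases: str, ref_base: str, expected_depth: int, line_no: int
) -> tuple[int, int, int, int, int, int]:
    """Decode one per-sample pileup base string into allele counts.

    Consumes read-start (``^`` + mapq char), read-end (``$``) and
    indel-length tokens (``+NNseq`` / ``-NNseq``); insertions and the
    following-position deletion announcements are ignored — only the ``*``
    placeholder at the deleted position itself counts, as a deletion allele.
    """
    n = [0, 0, 0, 0, 0, 0]  # A C G T * N
    ref_upper = ref_base.upper()
    i = 0
    counted = 0
    length = len(bases)
    while i < length:
        c = bases[i]
        if c == "^":
            i += 2  # '^' plus the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < length and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(
                    f"line {line_no}: indel token without length at offset {i}"
                )
            i = j + int(bases[i + 1 : j])
            continue
        if c in ".,":
            if ref_upper == "N":
                n[5] += 1
            else:
                n[ALLELE_INDEX[ref_upper]] += 1
        elif c.upper() in "ACGT":
            n[ALLELE_INDEX[c.upper()]] += 1
        elif c == "*":
            n[4] += 1
        elif c.upper() == "N" or c in "<>":
            n[5] += 1
        else:
            raise PileupParseError(
                f"line {line_no}: unexpected character {c!r} in base string"
            )
        counted += 1
        i += 1
    if counted != expected_depth:
        raise PileupParseError(
            f"line {line_no}: decoded {counted} read bases but depth column "
            f"says {expected_depth}"
        )
    return tuple(n)  # type: ignore[return-value]


def read_pileup(
    path: str | Path | IO[str],
    sample_order: Sequence[str],
    min_mapq: int = 2,  # noqa: ARG001 - MAPQ filtering happens at pileup generation
) -> Iterator[PileupColumn]:
    """Stream a multi-sample samtools text pileup as :class:`PileupColumn`.

    ``sample_order`` gives the sample id for each (depth, bases, quals)
    column triplet, left to right.  The MAPQ floor is applied by whatever
    produced the pileup; it is accepted here so that configuration travels
    with the reader, but reads below it never appear in the text.
    """
    n_samples = len(sample_order)
    close = False
    if isinstance(path, (str, Path)):
        handle: IO[str] = open(path)
        close = True
    else:
        handle = path
    try:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 + 3 * n_samples:
                raise PileupParseError(
                    f"line {line_no}: expected {3 + 3 * n_samples} columns for "
                    f"{n_samples} samples, found {len(fields)}"
                )
            contig_id, pos_s, ref_base = fields[0], fields[1], fields[2]
            counts: dict[str, tuple[int, int, int, int, int, int]] = {}
            for k, sample_id in enumerate(sample_order):
                depth_s, bases = fields[3 + 3 * k], fields[4 + 3 * k]
                depth = int(depth_s)
                if depth == 0:
                    counts[sample_id] = (0, 0, 0, 0, 0, 0)
                    continue
                counts[sample_id] = _decode_base_string(
                    bases, ref_base, depth, line_no
                )
            yield PileupColumn(
                contig_id=contig_id,
                pos=int(pos_s),
                ref_base=ref_base.upper(),
                counts=counts,
            )
    finally:
        if close:
            handle.close()


def write_pileup(
    columns: Iterable[PileupColumn],
    sample_order: Sequence[str],
    path: str | Path | IO[str],
) -> None:
    """Write columns in the plain text-pileup dialect ``read_pileup`` reads.

    Encoding is canonical: reference matches as ``.``, mismatches as
    uppercase letters, deletions as ``*``, qualities as ``I``.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle: IO[str] = open(path, "w")
        close = True
    else:
        handle = path
    try:
        for col in columns:
            fields = [col.contig_id, str(col.pos), col.ref_base]
            for sample_id in sample_order:
                c = col.counts.get(sample_id, (0, 0, 0, 0, 0, 0))
                depth = c[0] + c[1] + c[2] + c[3] + c[4]
                if depth == 0 and c[5] == 0:
                    fields.extend(["0", "*", "*"])
                    continue
                parts = []
                for allele, count in zip(ALLELES, c[:5]):
                    if count == 0:
                        continue
                    sym = "." if allele == col.ref_base else allele
                    parts.append(sym * count)
                parts.append("N" * c[5])
                bases = "".join(parts)
                fields.extend([str(depth + c[5]), bases, "I" * (depth + c[5])])
            handle.write("\t".join(fields) + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# FASTA with provenance headers


def _contig_to_record(contig: ReferenceContig) -> SeqRecord:
    desc = (
        f"source={contig.source} chrom={contig.source_chrom or '.'} "
        f"start={contig.source_start} end={contig.source_end}"
    )
    return SeqRecord(Seq(contig.sequence), id=contig.contig_id, description=desc)


def write_fasta(contigs: Iterable[ReferenceContig], path: str | Path) -> None:
    """Write reference contigs with provenance carried in the header."""
    records = []
    seen: set[str] = set()
    for contig in contigs:
        if contig.contig_id in seen:
            raise FastaFormatError(f"duplicate contig id {contig.contig_id!r}")
        seen.add(contig.contig_id)
        records.append(_contig_to_record(contig))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ReferenceContig]:
    """Read a provenance-annotated reference FASTA written by ``write_fasta``.

    Headers without provenance key=value tags are accepted and treated as
    de-novo contigs.
    """
    contigs: list[ReferenceContig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FastaFormatError(f"duplicate contig id {record.id!r}")
        seen.add(record.id)
        tags = dict(
            part.split("=", 1)
            for part in record.description.split()[1:]
            if "=" in part
        )
        chrom = tags.get("chrom", ".")
        contigs.append(
            ReferenceContig(
                contig_id=record.id,
                sequence=str(record.seq).upper(),
                source=tags.get("source", "denovo"),
                source_chrom="" if chrom == "." else chrom,
                source_start=int(tags.get("start", 0)),
                source_end=int(tags.get("end", 0)),
            )
        )
    return contigs


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a plain source-assembly FASTA as a chrom -> sequence mapping."""
    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


# ---------------------------------------------------------------------------
# BED


def write_bed(regions, path: str | Path) -> None:
    """Write regions as BED6, converting 1-based inclusive to 0-based half-open.

    Input must already be sorted by (chrom, start); sorting is the region
    builder's contract, not the writer's.
    """
    prev = None
    with open(path, "w") as handle:
        for i, region in enumerate(regions, start=1):
            key = (region.chrom, region.start)
            if prev is not None and key < prev:
                raise ValueError(
                    f"regions not sorted by (chrom, start) at record {i}"
                )
            prev = key
            handle.write(
                f"{region.chrom}\t{region.start - 1}\t{region.end}\t"
                f"region_{i:06d}\t0\t.\n"
            )


# ---------------------------------------------------------------------------
# SAM adapter (thin; alignment itself is upstream)


def read_pairs_from_sam(path: str | Path) -> Iterator[ReadPairRecord]:
    """Yield canonical :class:`ReadPairRecord` from a coordinate-sorted SAM/BAM.

    Only primary, mapped, properly-paired records contribute; each pair is
    emitted once, at its leftmost mate.
    """
    import pysam

    pending: dict[str, object] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if (
                aln.is_unmapped
                or aln.mate_is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or not aln.is_paired
            ):
                continue
            if aln.query_name in pending:
                first = pending.pop(aln.query_name)
                a, b = sorted(
                    [first, aln], key=lambda r: (r.reference_start, r.is_reverse)
                )
                orientation = ("R" if a.is_reverse else "F") + (
                    "R" if b.is_reverse else "F"
                )
                qual = sum(a.query_qualities or []) + sum(b.query_qualities or [])
                yield ReadPairRecord(
                    query_name=aln.query_name,
                    contig_id=sam.get_reference_name(a.reference_id),
                    left_start_1=a.reference_start + 1,
                    left_start_2=b.reference_start + 1,
                    orientation=orientation,
                    base_quality_sum=int(qual),
                )
            else:
                pending[aln.query_name] = aln


def coverage_from_sam(path: str | Path, min_mapq: int = 0) -> dict[str, "object"]:
    """Per-base read depth per reference sequence from a SAM/BAM file.

    Returns chrom -> numpy int array where index 0 is position 1.  Depth is
    counted over aligned reference positions of reads with MAPQ >= min_mapq.
    """
    import numpy as np
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        depth = {
            name: np.zeros(length, dtype=np.int32)
            for name, length in zip(sam.references, sam.lengths)
        }
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            name = sam.get_reference_name(aln.reference_id)
            for start, end in aln.get_blocks():
                depth[name][start:end] += 1
    return depth
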