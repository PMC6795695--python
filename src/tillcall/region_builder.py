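"""Coverage-driven exome-reference construction.

The exome reference is built from the unmutagenized control's alignment
depth against one or more source assemblies: maximal runs of positions at
or above a depth floor (default 17 reads) are marked, extended by flanking
sequence on either side (default 500 bp, because capture coverage decays
gradually across intron-exon boundaries rather than dropping abruptly),
merged when the extended regions come closer than a proximity cutoff
(default: gaps under 301 bp merge), and finally excised with provenance.
Externally assembled contigs (minimum length 500 bp) may be appended as an
extra source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import ReferenceContig

__all__ = [
    "CoverageTrack",
    "ExomeRegion",
    "RegionConfig",
    "call_core_regions",
    "flank_and_merge",
    "excise_contigs",
    "build_reference",
    "read_coverage_tsv",
    "read_coverage_bedgraph",
]


@dataclass
class CoverageTrack:
    """Dense per-base read depth for one chromosome; index 0 is position 1."""

    chrom: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def chrom_length(self) -> int:
        return int(self.depth.size)

    @classmethod
    def from_positions(
        cls, chrom: str, chrom_length: int, depths: Mapping[int, int]
    ) -> "CoverageTrack":
        """Build from a sparse {1-based position: depth} mapping."""
        arr = np.zeros(chrom_length, dtype=np.int64)
        for pos, d in depths.items():
            arr[pos - 1] = d
        return cls(chrom, arr)


@dataclass(frozen=True)
class ExomeRegion:
    """A flank-extended high-coverage interval, 1-based inclusive.

    ``core_start``/``core_end`` span the pre-flank high-coverage run(s) the
    region was grown from (first core start to last core end after merging).
    """

    chrom: str
    start: int
    end: int
    core_start: int
    core_end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.core_start <= self.core_end <= self.end):
            raise ValueError(
                f"invalid region nesting on {self.chrom}: "
                f"{self.start} <= {self.core_start} <= {self.core_end} <= {self.end}"
            )
        if self.start < 1:
            raise ValueError("region start before position 1")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionConfig:
    """Region-extraction parameters.

    min_depth
        Depth floor defining a high-coverage position (inclusive).
    flank
        Bases added on each side of a core run before merging.
    merge_gap
        Two extended regions merge when the gap between them is strictly
        less than this many bases (gap == merge_gap stays split).
    min_denovo_length
        Shortest externally assembled contig retained in the reference.
    """

    min_depth: int = 17
    flank: int = 500
    merge_gap: int = 301
    min_denovo_length: int = 500

    def __post_init__(self) -> None:
        if min(self.min_depth, self.flank, self.merge_gap) < 0:
            raise ValueError("region parameters must be non-negative")


def call_core_regions(
    track: CoverageTrack, cfg: RegionConfig
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions with depth >= cfg.min_depth.

    Returns sorted, non-overlapping 1-based inclusive intervals.
    """
    above = track.depth >= cfg.min_depth
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    starts, ends = edges[0::2] + 1, edges[1::2]  # to 1-based inclusive
    return list(zip(starts.tolist(), ends.tolist()))


def flank_and_merge(
    cores: Sequence[tuple[int, int]],
    cfg: RegionConfig,
    chrom_length: int,
    chrom: str = "",
) -> list[ExomeRegion]:
    """Extend cores by the flank, clip to the chromosome, merge near regions.

    The proximity test runs on the flank-extended coordinates; the gap
    between consecutive extended regions (``next.start - prev.end - 1``)
    merges them when strictly below ``cfg.merge_gap``.  Merging is
    transitive, so output gaps are all >= ``cfg.merge_gap``.  Adjacent or
    overlapping extended regions (gap <= 0) always merge.
    """
    merged: list[list[int]] = []  # [start, end, core_start, core_end]
    prev_core_end = 0
    for core_start, core_end in cores:
        if core_end < core_start or core_start <= prev_core_end:
            raise ValueError("cores must be sorted and non-overlapping")
        prev_core_end = core_end
        start = max(1, core_start - cfg.flank)
        end = min(chrom_length, core_end + cfg.flank)
        gap = start - merged[-1][1] - 1 if merged else None
        if merged and (gap <= 0 or gap < cfg.merge_gap):
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][3] = core_end
        else:
            merged.append([start, end, core_start, core_end])
    return [
        ExomeRegion(chrom=chrom, start=s, end=e, core_start=cs, core_end=ce)
        for s, e, cs, ce in merged
    ]


def _format_contig_id(index: int) -> str:
    return f"ctg{index:06d}"


def excise_contigs(
    regions: Sequence[ExomeRegion],
    assembly: Mapping[str, str],
    source_tag: str,
    start_index: int = 1,
) -> list[ReferenceContig]:
    """Cut region sequences out of a source assembly with provenance.

    Contig ids are assigned sequentially in sorted (chrom, start) order,
    starting at ``start_index`` so numbering continues across assemblies.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    contigs = []
    for offset, region in enumerate(ordered):
        if region.chrom not in assembly:
            raise KeyError(f"region chromosome {region.chrom!r} not in assembly")
        chrom_seq = assembly[region.chrom]
        if region.end > len(chrom_seq):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {len(chrom_seq)}"
            )
        contigs.append(
            ReferenceContig(
                contig_id=_format_contig_id(start_index + offset),
                sequence=chrom_seq[region.start - 1 : region.end],
                source=source_tag,
                source_chrom=region.chrom,
                source_start=region.start,
                source_end=region.end,
            )
        )
    return contigs


def build_reference(
    tracks_per_assembly: Sequence[tuple[Sequence[CoverageTrack], Mapping[str, str], str]],
    denovo_contigs: Iterable[ReferenceContig] = (),
    cfg: RegionConfig | None = None,
) -> tuple[list[ReferenceContig], dict]:
    """Assemble the full exome reference from prioritized sources.

    ``tracks_per_assembly`` pairs the control coverage tracks with their
    source assembly and a source tag, in priority order (the read partition
    that sends assembly-1-unmapped reads to assembly 2 happens upstream at
    alignment time).  De-novo contigs shorter than ``cfg.min_denovo_length``
    are dropped and the survivors renumbered into the global id sequence.

    Returns the contig list and a per-source summary of contig counts and
    total lengths.
    """
    cfg = cfg or RegionConfig()
    contigs: list[ReferenceContig] = []
    summary: dict = {"per_source": {}, "n_contigs": 0, "total_bp": 0}
    next_index = 1
    for tracks, assembly, source_tag in tracks_per_assembly:
        regions: list[ExomeRegion] = []
        for track in sorted(tracks, key=lambda t: t.chrom):
            cores = call_core_regions(track, cfg)
            regions.extend(
                flank_and_merge(cores, cfg, track.chrom_length, chrom=track.chrom)
            )
        excised = excise_contigs(regions, assembly, source_tag, next_index)
        next_index += len(excised)
        contigs.extend(excised)
        summary["per_source"][source_tag] = {
            "n_contigs": len(excised),
            "total_bp": sum(len(c) for c in excised),
        }
    kept_denovo = []
    for contig in denovo_contigs:
        if len(contig) < cfg.min_denovo_length:
            continue
        kept_denovo.append(
            ReferenceContig(
                contig_id=_format_contig_id(next_index + len(kept_denovo)),
                sequence=contig.sequence,
                source="denovo",
            )
        )
    contigs.extend(kept_denovo)
    summary["per_source"]["denovo"] = {
        "n_contigs": len(kept_denovo),
        "total_bp": sum(len(c) for c in kept_denovo),
    }
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("contig id collision in assembled reference")
    summary["n_contigs"] = len(contigs)
    summary["total_bp"] = sum(len(c) for c in contigs)
    return contigs, summary


# ---------------------------------------------------------------------------
# coverage input formats


def read_coverage_tsv(path) -> list[CoverageTrack]:
    """Read per-base depth as chrom<TAB>pos<TAB>depth (1-based, sparse ok)."""
    per_chrom: dict[str, dict[int, int]] = {}
    max_pos: dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos_s, depth_s = line.split()[:3]
            pos = int(pos_s)
            per_chrom.setdefault(chrom, {})[pos] = int(depth_s)
            max_pos[chrom] = max(max_pos.get(chrom, 0), pos)
    return [
        CoverageTrack.from_positions(chrom, max_pos[chrom], depths)
        for chrom, depths in per_chrom.items()
    ]


def read_coverage_bedgraph(path) -> list[CoverageTrack]:
    """Read depth from bedGraph (0-based half-open intervals)."""
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start_s, end_s, value_s = line.split()[:4]
            per_chrom.setdefault(chrom, []).append(
                (int(start_s), int(end_s), int(float(value_s)))
            )
    tracks = []
    for chrom, intervals in per_chrom.items():
        length = max(end for _, end, _ in intervals)
        arr = np.zeros(length, dtype=np.int64)
        for start, end, value in intervals:
            arr[start:end] = value
        tracks.append(CoverageTrack(chrom, arr))
    return tracks
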