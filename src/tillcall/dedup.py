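"""Coordinate-based PCR-duplicate marking for paired-end alignments.

Two fragments are duplicates when both mates' leftmost alignment positions
and the pair orientation coincide on the same contig — the standard
coordinate criterion.  Within a duplicate group exactly one pair is kept:
the one with the highest base-quality sum, ties broken by lexicographically
smallest query name, so the kept set is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .core_io import ReadPairRecord

__all__ = ["DuplicateKey", "mark_duplicates", "dedup_rate"]


@dataclass(frozen=True)
class DuplicateKey:
    contig_id: str
    left_start_1: int
    left_start_2: int
    orientation: str

    @classmethod
    def of(cls, pair: ReadPairRecord) -> "DuplicateKey":
        return cls(
            pair.contig_id, pair.left_start_1, pair.left_start_2, pair.orientation
        )


def _flush(
    buffer: list[ReadPairRecord],
) -> Iterator[tuple[ReadPairRecord, bool]]:
    groups: dict[DuplicateKey, list[ReadPairRecord]] = {}
    for pair in buffer:
        groups.setdefault(DuplicateKey.of(pair), []).append(pair)
    keep: set[str] = set()
    for members in groups.values():
        best = min(members, key=lambda p: (-p.base_quality_sum, p.query_name))
        keep.add(best.query_name)
    for pair in buffer:
        yield pair, pair.query_name not in keep


def mark_duplicates(
    pairs: Iterable[ReadPairRecord],
) -> Iterator[tuple[ReadPairRecord, bool]]:
    """Flag every pair as kept (False) or duplicate (True).

    Input must be sorted by (contig_id, left_start_1); pairs sharing a
    leftmost position are buffered together, so memory stays proportional
    to the deepest position, never the file.  Singleton keys are never
    flagged, and rerunning on the kept set flags nothing.
    """
    buffer: list[ReadPairRecord] = []
    current: tuple[str, int] | None = None
    for pair in pairs:
        key = (pair.contig_id, pair.left_start_1)
        if current is not None and key < current:
            raise ValueError(
                f"input not sorted by (contig, leftmost start) at "
                f"{pair.query_name} ({key} after {current})"
            )
        if key != current:
            yield from _flush(buffer)
            buffer = []
            current = key
        buffer.append(pair)
    yield from _flush(buffer)


def dedup_rate(pairs: Iterable[ReadPairRecord]) -> float:
    """Fraction of pairs flagged as duplicates; 0.0 on empty input."""
    total = dups = 0
    for _, is_dup in mark_duplicates(pairs):
        total += 1
        dups += is_dup
    return dups / total if total else 0.0
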