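"""Population statistics, flanking sequences, and mutation-table export.

The headline summary statistics of an EMS TILLING population are the
mutation spectrum (counts per substitution/deletion type), the fraction of
canonical alkylation transitions CG->TA (a quality proxy: the higher the
fraction, the cleaner the call set), the heterozygous:homozygous ratio
(expected 2:1 in an M2 generation), and the mutation rate per Mbp, whose
denominator is the number of positions covered deeply enough to have
supported a call at all.

Export follows the searchable-database convention: a flat CSV convertible
to a single-table SQLite database queryable by mutant id or by contig id,
each row carrying the flanking sequence with the mutated base marked as
``[control/mutant]`` for direct primer design.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller import MutationCall
from .core_io import ReferenceContig

__all__ = [
    "PopulationStats",
    "MutationRecord",
    "FlankingSequence",
    "summarize",
    "coverage_sweep",
    "extract_flanks",
    "records_from_calls",
    "export_csv",
    "export_sqlite",
    "query_by_contig",
    "query_by_mutant",
]

CSV_FIELDS = [
    "mutant_id",
    "contig_id",
    "pos",
    "mutation_type",
    "control_call",
    "mutant_call",
    "zygosity",
    "chromosome_location",
    "mut_depth",
    "flanking_sequence",
]


@dataclass
class PopulationStats:
    type_counts: dict[tuple[str, str, str], int]
    n_total: int
    n_het: int
    n_hom: int
    cg_ta_fraction: float
    het_hom_ratio: float | None  # None when there are no homozygous calls
    mutations_per_mbp: float | None
    per_sample: dict[str, dict] = field(default_factory=dict)


@dataclass(frozen=True)
class MutationRecord:
    """One export row of the mutation table."""

    mutant_id: str
    contig_id: str
    pos: int
    mutation_type: str
    control_call: str
    mutant_call: str
    zygosity: str
    chromosome_location: str
    mut_depth: int
    flanking_sequence: str


@dataclass(frozen=True)
class FlankingSequence:
    sequence: str
    left_length: int
    right_length: int
    short_flank_warning: bool


def summarize(
    calls: Sequence[MutationCall], callable_bp: int | None = None
) -> PopulationStats:
    """Spectrum, CG->TA fraction, het:hom ratio and rate for a call set.

    ``callable_bp`` is the callable-space denominator (positions covered at
    or above the calling support threshold, summed over samples); omit it
    and no rate is reported.
    """
    type_counts: dict[tuple[str, str, str], int] = {}
    n_het = n_hom = 0
    n_cg_ta = 0
    per_sample: dict[str, dict] = {}
    for call in calls:
        key = (call.mutation_kind, call.control_base, call.mutant_allele)
        type_counts[key] = type_counts.get(key, 0) + 1
        if call.zygosity == "heterozygous":
            n_het += 1
        else:
            n_hom += 1
        n_cg_ta += call.is_canonical_ems
        entry = per_sample.setdefault(
            call.sample_id, {"n_calls": 0, "depth_sum": 0}
        )
        entry["n_calls"] += 1
        entry["depth_sum"] += call.sample_depth
    for entry in per_sample.values():
        entry["mean_depth"] = entry.pop("depth_sum") / entry["n_calls"]
    n_total = len(calls)
    return PopulationStats(
        type_counts=type_counts,
        n_total=n_total,
        n_het=n_het,
        n_hom=n_hom,
        cg_ta_fraction=n_cg_ta / n_total if n_total else 0.0,
        het_hom_ratio=n_het / n_hom if n_hom else None,
        mutations_per_mbp=(
            n_total / (callable_bp / 1e6) if callable_bp else None
        ),
        per_sample=per_sample,
    )


def coverage_sweep(
    calls: Sequence[MutationCall], support_values: Sequence[int]
) -> pd.DataFrame:
    """Call counts by zygosity as the support threshold is raised.

    For each threshold, counts calls with mut_support >= threshold split
    into heterozygous and homozygous series; both are non-increasing in the
    threshold, so the sweep shows how much of the call set survives a
    stricter support requirement.
    """
    rows = []
    for threshold in support_values:
        surviving = [c for c in calls if c.mut_support >= threshold]
        rows.append(
            {
                "min_support": threshold,
                "n_het": sum(c.zygosity == "heterozygous" for c in surviving),
                "n_hom": sum(c.zygosity == "homozygous" for c in surviving),
            }
        )
    return pd.DataFrame(rows, columns=["min_support", "n_het", "n_hom"])


def extract_flanks(
    call: MutationCall,
    reference: Mapping[str, str],
    min_flank: int = 50,
    max_flank: int = 200,
) -> FlankingSequence:
    """Flanking sequence around a call with the site marked ``[ref/alt]``.

    Up to ``max_flank`` bases are taken on each side, truncated at contig
    boundaries; a side shorter than ``min_flank`` raises the warning flag
    (such fragments may be too short for primer design).  Deletions are
    marked ``[ref/-]``.
    """
    seq = reference[call.contig_id]
    if not 1 <= call.pos <= len(seq):
        raise ValueError(
            f"position {call.pos} outside contig {call.contig_id} "
            f"(length {len(seq)})"
        )
    left_start = max(0, call.pos - 1 - max_flank)
    left = seq[left_start : call.pos - 1]
    right = seq[call.pos : call.pos + max_flank]
    alt = "-" if call.mutant_allele == "DEL" else call.mutant_allele
    marker = f"[{call.control_base}/{alt}]"
    return FlankingSequence(
        sequence=f"{left}{marker}{right}",
        left_length=len(left),
        right_length=len(right),
        short_flank_warning=len(left) < min_flank or len(right) < min_flank,
    )


def records_from_calls(
    calls: Iterable[MutationCall],
    contigs: Sequence[ReferenceContig],
    min_flank: int = 50,
    max_flank: int = 200,
) -> list[MutationRecord]:
    """Assemble export rows: flanks from the reference, location from provenance.

    De-novo contigs have no chromosome assignment and are reported as
    "unplaced".
    """
    reference = {c.contig_id: c.sequence for c in contigs}
    location = {
        c.contig_id: (c.source_chrom if c.source != "denovo" else "unplaced")
        or "unplaced"
        for c in contigs
    }
    records = []
    for call in calls:
        flank = extract_flanks(call, reference, min_flank, max_flank)
        mutant_call = "-" if call.mutant_allele == "DEL" else call.mutant_allele
        records.append(
            MutationRecord(
                mutant_id=call.sample_id,
                contig_id=call.contig_id,
                pos=call.pos,
                mutation_type=call.mutation_kind,
                control_call=call.control_base,
                mutant_call=mutant_call,
                zygosity=call.zygosity,
                chromosome_location=location[call.contig_id],
                mut_depth=call.mut_support,
                flanking_sequence=flank.sequence,
            )
        )
    return records


def calls_to_frame(calls: Sequence[MutationCall]) -> pd.DataFrame:
    """Tabular form of a call list (the ``call`` stage's CSV payload)."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "contig_id": c.contig_id,
                "pos": c.pos,
                "mutation_kind": c.mutation_kind,
                "control_base": c.control_base,
                "mutant_allele": c.mutant_allele,
                "zygosity": c.zygosity,
                "mut_support": c.mut_support,
                "sample_depth": c.sample_depth,
            }
            for c in calls
        ],
        columns=[
            "sample_id",
            "contig_id",
            "pos",
            "mutation_kind",
            "control_base",
            "mutant_allele",
            "zygosity",
            "mut_support",
            "sample_depth",
        ],
    )


def calls_from_frame(frame: pd.DataFrame) -> list[MutationCall]:
    return [
        MutationCall(
            sample_id=row.sample_id,
            contig_id=row.contig_id,
            pos=int(row.pos),
            mutation_kind=row.mutation_kind,
            control_base=row.control_base,
            mutant_allele=row.mutant_allele,
            zygosity=row.zygosity,
            mut_support=int(row.mut_support),
            sample_depth=int(row.sample_depth),
        )
        for row in frame.itertuples(index=False)
    ]


def export_csv(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write the mutation table as UTF-8 CSV with the fixed header."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_FIELDS)
        for record in records:
            writer.writerow([getattr(record, name) for name in CSV_FIELDS])


def export_sqlite(csv_path: str | Path, db_path: str | Path) -> None:
    """Load a mutation-table CSV into a single indexed SQLite table.

    The ``mutations`` table is indexed on mutant_id and contig_id, the two
    identifiers the database is searched by.
    """
    with open(csv_path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != CSV_FIELDS:
            raise ValueError(
                f"CSV header {reader.fieldnames} does not match the expected "
                f"mutation-table fields {CSV_FIELDS}"
            )
        rows = []
        for i, row in enumerate(reader, start=2):
            for name in CSV_FIELDS:
                if row.get(name) in (None, ""):
                    raise ValueError(f"row {i}: missing field {name!r}")
            rows.append(tuple(row[name] for name in CSV_FIELDS))
    con = sqlite3.connect(db_path)
    try:
        con.execute("DROP TABLE IF EXISTS mutations")
        con.execute(
            """CREATE TABLE mutations (
                mutant_id TEXT NOT NULL,
                contig_id TEXT NOT NULL,
                pos INTEGER NOT NULL,
                mutation_type TEXT NOT NULL,
                control_call TEXT NOT NULL,
                mutant_call TEXT NOT NULL,
                zygosity TEXT NOT NULL,
                chromosome_location TEXT NOT NULL,
                mut_depth INTEGER NOT NULL,
                flanking_sequence TEXT NOT NULL
            )"""
        )
        con.executemany(
            f"INSERT INTO mutations VALUES ({','.join('?' * len(CSV_FIELDS))})",
            rows,
        )
        con.execute("CREATE INDEX idx_mutant ON mutations (mutant_id)")
        con.execute("CREATE INDEX idx_contig ON mutations (contig_id)")
        con.commit()
    finally:
        con.close()


def _rows_to_records(rows) -> list[MutationRecord]:
    return [
        MutationRecord(
            mutant_id=r[0],
            contig_id=r[1],
            pos=int(r[2]),
            mutation_type=r[3],
            control_call=r[4],
            mutant_call=r[5],
            zygosity=r[6],
            chromosome_location=r[7],
            mut_depth=int(r[8]),
            flanking_sequence=r[9],
        )
        for r in rows
    ]


def query_by_contig(db_path: str | Path, contig_id: str) -> list[MutationRecord]:
    """All mutations on a contig, deepest supported first."""
    con = sqlite3.connect(db_path)
    try:
        rows = con.execute(
            "SELECT * FROM mutations WHERE contig_id = ? "
            "ORDER BY mut_depth DESC, pos ASC",
            (contig_id,),
        ).fetchall()
    finally:
        con.close()
    return _rows_to_records(rows)


def query_by_mutant(db_path: str | Path, mutant_id: str) -> list[MutationRecord]:
    """All mutations carried by one mutant line, in genomic order."""
    con = sqlite3.connect(db_path)
    try:
        rows = con.execute(
            "SELECT * FROM mutations WHERE mutant_id = ? "
            "ORDER BY contig_id ASC, pos ASC",
            (mutant_id,),
        ).fetchall()
    finally:
        con.close()
    return _rows_to_records(rows)
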