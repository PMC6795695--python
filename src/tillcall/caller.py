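"""Population-scale EMS mutation calling over a multi-sample pileup.

A variant is called an induced mutation in a mutant line when three
criteria hold at its position:

1. the position is non-polymorphic between the unmutagenized control and
   the reference (the control's majority allele is the reference base and
   its minor-allele fraction stays under a cap), and the variant allele is
   *present* in exactly one mutant sample — the chance of the same EMS
   lesion arising independently in two plants is negligible, so shared
   alleles are either varietal polymorphisms or systematic artefacts;
2. the mutant allele is covered by enough reads in its carrier
   (``min_mut_support``, 3 at the permissive floor, 10 for high-confidence
   sets) so that sequencing error is an implausible origin;
3. enough *other* mutant samples show adequate coverage of the control
   allele at the position (``min_informative_samples``), guaranteeing the
   population could have revealed the allele elsewhere had it been shared.

Zygosity is then read off the mutant-allele fraction f of the carrier:
an M2 homozygote is expected near f = 1 and a heterozygote near f = 0.5,
so f >= hom_min_fraction classifies homozygous, het_min_fraction <= f <
hom_min_fraction heterozygous, and smaller f is left uncalled.

Insertions are never called (insertion pileup tokens are consumed and
discarded upstream); deletions are treated as a fifth allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .core_io import ALLELES, PileupColumn

__all__ = [
    "CallerConfig",
    "MutationCall",
    "ColumnVerdict",
    "CallResult",
    "control_is_concordant",
    "candidate_alleles",
    "population_coverage_ok",
    "classify_zygosity",
    "call_position",
    "call_population",
]


@dataclass
class CallerConfig:
    """Thresholds of the three calling criteria and zygosity bands.

    min_mut_support
        Reads of the mutant allele required in the carrier (criterion 2).
    min_informative_samples
        Other mutant samples that must show the control allele adequately
        (criterion 3); scale with population size.
    min_other_depth
        Reads of the control allele that make another sample informative.
    presence_min_reads
        Reads that make an allele count as "present" in a sample when
        testing uniqueness — a single stray error read in a second sample
        should not kill a true call.
    control_max_minor_fraction
        Cap on the control's non-reference read fraction for concordance.
    hom_min_fraction / het_min_fraction
        Mutant-allele-fraction bands for zygosity.
    min_mapq
        Mapping-quality floor applied when the pileup is generated.
    """

    min_mut_support: int = 3
    min_informative_samples: int = 50
    min_other_depth: int = 3
    presence_min_reads: int = 2
    control_max_minor_fraction: float = 0.1
    hom_min_fraction: float = 0.85
    het_min_fraction: float = 0.15
    min_mapq: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.het_min_fraction < self.hom_min_fraction <= 1:
            raise ValueError(
                "need 0 <= het_min_fraction < hom_min_fraction <= 1"
            )


@dataclass(frozen=True)
class MutationCall:
    sample_id: str
    contig_id: str
    pos: int
    mutation_kind: str  # substitution | deletion
    control_base: str
    mutant_allele: str  # A/C/G/T or DEL
    zygosity: str  # heterozygous | homozygous
    mut_support: int
    sample_depth: int

    @property
    def is_canonical_ems(self) -> bool:
        """True for the alkylation transitions C->T and G->A."""
        return (self.control_base, self.mutant_allele) in {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class ColumnVerdict:
    """Audit record: why a (position, allele) was or was not called."""

    contig_id: str
    pos: int
    status: str
    detail: str = ""


def control_is_concordant(
    col: PileupColumn, control_id: str, cfg: CallerConfig
) -> tuple[bool, str]:
    """Check the position is non-polymorphic between control and reference.

    Returns (flag, validated control base).  Concordant means the control's
    majority allele equals the reference base and the control minor-allele
    fraction (all non-reference reads over depth) does not exceed the cap.
    """
    depth = col.depth(control_id)
    if depth == 0:
        return False, ""
    ref_count = col.allele_count(control_id, col.ref_base)
    majority = max(ALLELES, key=lambda a: col.allele_count(control_id, a))
    if col.allele_count(control_id, majority) > ref_count:
        return False, ""
    if (depth - ref_count) / depth > cfg.control_max_minor_fraction:
        return False, ""
    return True, col.ref_base


def candidate_alleles(
    col: PileupColumn, cfg: CallerConfig, mutant_samples: Sequence[str]
) -> dict[str, list[str]]:
    """Map each non-reference allele to the mutant samples it is present in.

    Presence means support >= cfg.presence_min_reads.  Alleles present in
    no sample are omitted; the caller treats a presence list of length one
    as a candidate and anything longer as not unique.
    """
    carriers: dict[str, list[str]] = {}
    for sample_id in mutant_samples:
        counts = col.counts[sample_id]
        for allele, count in zip(ALLELES, counts):
            if allele == col.ref_base or count < cfg.presence_min_reads:
                continue
            carriers.setdefault(allele, []).append(sample_id)
    return carriers


def population_coverage_ok(
    col: PileupColumn,
    carrier: str,
    control_base: str,
    cfg: CallerConfig,
    mutant_samples: Sequence[str],
) -> tuple[bool, int]:
    """Criterion 3: enough other samples covered the control allele.

    Counts non-carrier mutant samples with >= cfg.min_other_depth reads of
    the control base; returns the flag and the informative-sample count.
    """
    n_informative = sum(
        1
        for sample_id in mutant_samples
        if sample_id != carrier
        and col.allele_count(sample_id, control_base) >= cfg.min_other_depth
    )
    return n_informative >= cfg.min_informative_samples, n_informative


def classify_zygosity(
    mut_support: int, sample_depth: int, cfg: CallerConfig
) -> str | None:
    """Zygosity from the mutant-allele fraction; None below the het floor."""
    if sample_depth <= 0:
        raise ValueError("sample depth must be positive")
    if not 0 < mut_support <= sample_depth:
        raise ValueError("need 0 < mut_support <= sample_depth")
    f = mut_support / sample_depth
    if f >= cfg.hom_min_fraction:
        return "homozygous"
    if f >= cfg.het_min_fraction:
        return "heterozygous"
    return None


def call_position(
    col: PileupColumn,
    cfg: CallerConfig,
    mutant_samples: Sequence[str],
    control_id: str,
) -> tuple[list[MutationCall], list[ColumnVerdict]]:
    """Apply all three criteria plus zygosity at one pileup column.

    Each non-reference allele is evaluated independently, so a multi-allelic
    column may produce calls in different samples.  Every rejected candidate
    leaves an audit verdict; columns with no allele reaching presence in any
    sample stay silent.
    """
    calls: list[MutationCall] = []
    verdicts: list[ColumnVerdict] = []
    carriers = candidate_alleles(col, cfg, mutant_samples)
    if not carriers:
        return calls, verdicts
    if col.ref_base == "N":
        verdicts.append(
            ColumnVerdict(col.contig_id, col.pos, "ref_is_N", "reference base is N")
        )
        return calls, verdicts
    concordant, control_base = control_is_concordant(col, control_id, cfg)
    if not concordant:
        detail = (
            "no control coverage"
            if col.depth(control_id) == 0
            else "control disagrees with reference"
        )
        verdicts.append(
            ColumnVerdict(col.contig_id, col.pos, "polymorphic_in_control", detail)
        )
        return calls, verdicts
    for allele in ALLELES:
        if allele not in carriers:
            continue
        present_in = carriers[allele]
        if len(present_in) > 1:
            verdicts.append(
                ColumnVerdict(
                    col.contig_id,
                    col.pos,
                    "not_unique",
                    f"allele {allele} present in {len(present_in)} samples",
                )
            )
            continue
        carrier = present_in[0]
        mut_support = col.allele_count(carrier, allele)
        if mut_support < cfg.min_mut_support:
            verdicts.append(
                ColumnVerdict(
                    col.contig_id,
                    col.pos,
                    "insufficient_support",
                    f"{carrier}: {mut_support} < {cfg.min_mut_support} reads "
                    f"of allele {allele}",
                )
            )
            continue
        ok, n_informative = population_coverage_ok(
            col, carrier, control_base, cfg, mutant_samples
        )
        if not ok:
            verdicts.append(
                ColumnVerdict(
                    col.contig_id,
                    col.pos,
                    "insufficient_population_coverage",
                    f"only {n_informative} informative samples",
                )
            )
            continue
        sample_depth = col.depth(carrier)
        zygosity = classify_zygosity(mut_support, sample_depth, cfg)
        if zygosity is None:
            verdicts.append(
                ColumnVerdict(
                    col.contig_id,
                    col.pos,
                    "insufficient_support",
                    f"{carrier}: allele fraction {mut_support}/{sample_depth} "
                    "below heterozygous floor",
                )
            )
            continue
        calls.append(
            MutationCall(
                sample_id=carrier,
                contig_id=col.contig_id,
                pos=col.pos,
                mutation_kind="deletion" if allele == "*" else "substitution",
                control_base=control_base,
                mutant_allele="DEL" if allele == "*" else allele,
                zygosity=zygosity,
                mut_support=mut_support,
                sample_depth=sample_depth,
            )
        )
        verdicts.append(
            ColumnVerdict(
                col.contig_id, col.pos, "called", f"{carrier} {allele}"
            )
        )
    return calls, verdicts


@dataclass
class CallResult:
    """Calls, audit verdicts and the callable-space bookkeeping."""

    calls: list[MutationCall] = field(default_factory=list)
    verdicts: list[ColumnVerdict] = field(default_factory=list)
    #: per mutant sample, positions with depth >= the support threshold —
    #: the denominator of the per-sample mutation rate
    callable_positions: dict[str, int] = field(default_factory=dict)
    n_columns: int = 0

    @property
    def total_callable_positions(self) -> int:
        return sum(self.callable_positions.values())


def call_population(
    columns: Iterable[PileupColumn],
    cfg: CallerConfig,
    samples: Sequence[str],
    control_id: str,
    keep_verdicts: bool = True,
) -> CallResult:
    """Run the caller over a streamed pileup; constant memory in positions.

    ``samples`` is every sample in the pileup including the control;
    callable-space counters track, per mutant sample, the positions whose
    depth reaches ``cfg.min_mut_support`` — the same floor a call there
    would have needed.
    """
    if control_id not in samples:
        raise ValueError(f"control {control_id!r} not in sample list")
    mutant_samples = [s for s in samples if s != control_id]
    result = CallResult(
        callable_positions={s: 0 for s in mutant_samples}
    )
    for col in columns:
        missing = [s for s in samples if s not in col.counts]
        if missing:
            raise ValueError(
                f"pileup column {col.contig_id}:{col.pos} lacks sample(s) "
                f"{missing}"
            )
        result.n_columns += 1
        for sample_id in mutant_samples:
            if col.depth(sample_id) >= cfg.min_mut_support:
                result.callable_positions[sample_id] += 1
        calls, verdicts = call_position(col, cfg, mutant_samples, control_id)
        result.calls.extend(calls)
        if keep_verdicts:
            result.verdicts.extend(verdicts)
    return result
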