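"""Synthetic M2 exome-capture population generator.

Emulates the data the caller consumes — a reference, a per-line mutation
truth table, and a multi-sample pileup — with the statistical structure of
an EMS TILLING-by-sequencing experiment:

* each mutant line carries Poisson-distributed induced mutations
  (default 20 per Mbp), overwhelmingly the canonical alkylation
  transitions C->T / G->A (default 98%), heterozygous with probability
  2/3 as expected when an M2 individual segregates an M1 lesion, with a
  small admixture of single-base deletions;
* the unmutagenized control is sequenced deep (mean 29.5x) while mutant
  lines get shallow, uneven coverage (per-line means drawn from 1.2-11.3x
  by default, or fixed for power analyses); depth is position-independent
  Poisson — capture-efficiency variation along contigs is deliberately
  not modelled;
* varietal SNPs (line-versus-reference polymorphisms) appear homozygous
  in every sample including the control, which is what lets the caller
  separate them from induced mutations;
* sequencing error substitutes a uniformly chosen wrong base at a fixed
  per-read rate; read-pair simulation injects PCR duplicates for the
  duplicate-marking stage.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .core_io import ALLELES, PileupColumn, ReadPairRecord, ReferenceContig

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_reference",
    "simulate_population",
    "simulate_pileup",
    "simulate_read_pairs",
    "sample_names",
    "CONTROL_ID",
]

CONTROL_ID = "control"

_BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
# for each reference base index, the three other base indices
_OTHER_BASES = np.array(
    [[j for j in range(4) if j != i] for i in range(4)], dtype=np.int64
)


@dataclass
class SimConfig:
    """Study-condition knobs of the synthetic population.

    Depth means are reads per base position; rates are events per Mbp per
    line except ``varietal_snp_rate_per_mbp``, which is genome-wide and
    shared.  ``mutant_depth_mean`` may be a (low, high) range sampled per
    line, or a single number applied to every line.
    """

    n_contigs: int = 20
    contig_length_bp: int = 2_000
    n_lines: int = 40
    control_depth_mean: float = 29.5
    mutant_depth_mean: float | tuple[float, float] = (1.2, 11.3)
    mutation_rate_per_mbp: float = 20.0
    p_canonical_ems: float = 0.98
    p_het: float = 2.0 / 3.0
    p_deletion: float = 0.001
    seq_error_rate: float = 0.002
    pcr_dup_rate: float = 0.05
    varietal_snp_rate_per_mbp: float = 50.0
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_canonical_ems",
            "p_het",
            "p_deletion",
            "seq_error_rate",
            "pcr_dup_rate",
            "gc_content",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.mutation_rate_per_mbp < 0 or self.varietal_snp_rate_per_mbp < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """One simulated variant; varietal SNPs use line_id ALL (shared)."""

    line_id: str
    contig_id: str
    pos: int
    control_base: str
    mutant_allele: str  # A/C/G/T or DEL
    zygosity: str
    is_varietal_snp: bool = False


def sample_names(cfg: SimConfig) -> list[str]:
    """Pileup sample order: control first, then the mutant lines."""
    return [CONTROL_ID] + [f"mut{i:03d}" for i in range(1, cfg.n_lines + 1)]


def simulate_reference(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[ReferenceContig]:
    """Random contigs with the configured GC content."""
    rng = rng or np.random.default_rng(cfg.seed)
    p = np.array(
        [
            (1 - cfg.gc_content) / 2,
            cfg.gc_content / 2,
            cfg.gc_content / 2,
            (1 - cfg.gc_content) / 2,
        ]
    )
    contigs = []
    for i in range(1, cfg.n_contigs + 1):
        idx = rng.choice(4, size=cfg.contig_length_bp, p=p)
        seq = "".join(_BASES[j] for j in idx)
        contigs.append(ReferenceContig(contig_id=f"ctg{i:06d}", sequence=seq))
    return contigs


def _draw_allele(ref_base: str, rng: np.random.Generator) -> str:
    others = [b for b in _BASES if b != ref_base]
    return others[rng.integers(len(others))]


def simulate_population(
    reference: Sequence[ReferenceContig],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TruthRecord]:
    """Draw the truth table: varietal SNPs plus per-line induced mutations.

    Mutation counts per line are Poisson(rate x genome Mbp); canonical
    events are placed on C/G sites and flip C->T or G->A, the remainder on
    any site with a uniformly chosen wrong base.  Positions are unique per
    line and never coincide with a varietal SNP.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    genome_bp = sum(len(c) for c in reference)
    genome_mbp = genome_bp / 1e6
    # flat site index over the concatenated genome
    bounds = np.cumsum([0] + [len(c) for c in reference])
    all_seq = "".join(c.sequence for c in reference)
    seq_arr = np.frombuffer(all_seq.encode(), dtype=np.uint8)
    cg_sites = np.flatnonzero((seq_arr == ord("C")) | (seq_arr == ord("G")))

    def locate(flat: int) -> tuple[str, int, str]:
        ci = int(np.searchsorted(bounds, flat, side="right")) - 1
        return reference[ci].contig_id, flat - int(bounds[ci]) + 1, all_seq[flat]

    truth: list[TruthRecord] = []
    varietal_flat: set[int] = set()
    n_varietal = rng.poisson(cfg.varietal_snp_rate_per_mbp * genome_mbp)
    while len(varietal_flat) < n_varietal:
        varietal_flat.add(int(rng.integers(genome_bp)))
    for flat in sorted(varietal_flat):
        contig_id, pos, ref_base = locate(flat)
        truth.append(
            TruthRecord(
                line_id="ALL",
                contig_id=contig_id,
                pos=pos,
                control_base=ref_base,
                mutant_allele=_draw_allele(ref_base, rng),
                zygosity="homozygous",
                is_varietal_snp=True,
            )
        )

    lam = cfg.mutation_rate_per_mbp * genome_mbp
    if len(cg_sites) == 0 and cfg.p_canonical_ems > 0 and lam > 0:
        raise ValueError("no C/G sites available for canonical EMS events")
    for line in range(1, cfg.n_lines + 1):
        line_id = f"mut{line:03d}"
        n_mut = rng.poisson(lam)
        if n_mut > genome_bp // 2:
            raise ValueError(
                "mutation rate exhausts unique positions in the genome"
            )
        taken: set[int] = set()
        made = 0
        while made < n_mut:
            canonical = rng.random() < cfg.p_canonical_ems
            if canonical:
                flat = int(cg_sites[rng.integers(len(cg_sites))])
            else:
                flat = int(rng.integers(genome_bp))
            if flat in taken or flat in varietal_flat:
                continue
            taken.add(flat)
            made += 1
            contig_id, pos, ref_base = locate(flat)
            if rng.random() < cfg.p_deletion:
                allele = "DEL"
            elif canonical:
                allele = "T" if ref_base == "C" else "A"
            else:
                allele = _draw_allele(ref_base, rng)
            truth.append(
                TruthRecord(
                    line_id=line_id,
                    contig_id=contig_id,
                    pos=pos,
                    control_base=ref_base,
                    mutant_allele=allele,
                    zygosity=(
                        "heterozygous"
                        if rng.random() < cfg.p_het
                        else "homozygous"
                    ),
                )
            )
    return truth


def _resample_cell(
    depth: int,
    ref_idx: int,
    alt_idx: int,
    zygosity: str,
    eps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele counts (A,C,G,T,*) for one carrier sample-position cell.

    A homozygote's reads all intend the mutant allele, a heterozygote's
    split Binomial(depth, 1/2); each read then errs with probability eps
    to a uniformly chosen base other than its intended allele.
    """
    counts = np.zeros(5, dtype=np.int64)
    if depth == 0:
        return counts
    n_alt = depth if zygosity == "homozygous" else int(rng.binomial(depth, 0.5))
    for intended, n in ((alt_idx, n_alt), (ref_idx, depth - n_alt)):
        if n == 0:
            continue
        n_err = int(rng.binomial(n, eps))
        counts[intended] += n - n_err
        if n_err:
            targets = [j for j in range(4) if j != intended]
            for t in rng.integers(len(targets), size=n_err):
                counts[targets[t]] += 1
    return counts


def line_depth_means(
    cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample mean depths, control first (order of ``sample_names``)."""
    if isinstance(cfg.mutant_depth_mean, (int, float)):
        means = np.full(cfg.n_lines, float(cfg.mutant_depth_mean))
    else:
        low, high = cfg.mutant_depth_mean
        means = rng.uniform(low, high, size=cfg.n_lines)
    return np.concatenate(([cfg.control_depth_mean], means))


def simulate_pileup(
    reference: Sequence[ReferenceContig],
    truth: Sequence[TruthRecord],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> Iterator[PileupColumn]:
    """Stream pileup columns for every reference position.

    Depth per sample-position is Poisson with the sample's mean; carriers
    get the mutant allele at the het/hom intended fraction; every sample
    including the control carries the varietal SNPs; sequencing error
    moves reads to a uniformly chosen wrong base.  N counts are always 0.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    samples = sample_names(cfg)
    means = line_depth_means(cfg, rng)
    eps = cfg.seq_error_rate

    by_contig: dict[str, list[TruthRecord]] = {}
    for rec in truth:
        by_contig.setdefault(rec.contig_id, []).append(rec)

    for contig in reference:
        length = len(contig)
        n_samples = len(samples)
        ref_idx = np.frombuffer(contig.sequence.encode(), dtype=np.uint8)
        ref_map = np.full(256, -1, dtype=np.int64)
        for base, idx in _BASE_INDEX.items():
            ref_map[ord(base)] = idx
        ref_idx = ref_map[ref_idx]  # -1 where reference is N

        depth = rng.poisson(means, size=(length, n_samples))
        counts = np.zeros((length, n_samples, 5), dtype=np.int64)
        n_err = rng.binomial(depth, eps)
        # everyone starts as a clean reference read stack
        pos_all = np.arange(length)
        valid = ref_idx >= 0
        counts[pos_all[valid], :, ref_idx[valid]] = (depth - n_err)[valid]
        # scatter error reads over the three non-reference bases
        err_pos, err_smp = np.nonzero(n_err)
        err_pos_ok = err_pos[valid[err_pos]]
        err_smp_ok = err_smp[valid[err_pos]]
        if err_pos_ok.size:
            split = rng.multinomial(
                n_err[err_pos_ok, err_smp_ok], [1 / 3] * 3
            )
            others = _OTHER_BASES[ref_idx[err_pos_ok]]
            for k in range(3):
                np.add.at(
                    counts, (err_pos_ok, err_smp_ok, others[:, k]), split[:, k]
                )

        for rec in by_contig.get(contig.contig_id, ()):
            if rec.control_base == "N":
                continue
            alt_idx = 4 if rec.mutant_allele == "DEL" else _BASE_INDEX[rec.mutant_allele]
            r_idx = _BASE_INDEX[rec.control_base]
            if rec.is_varietal_snp:
                targets = range(n_samples)  # shared by control and all lines
            else:
                targets = (samples.index(rec.line_id),)
            for s in targets:
                counts[rec.pos - 1, s] = _resample_cell(
                    int(depth[rec.pos - 1, s]),
                    r_idx,
                    alt_idx,
                    rec.zygosity,
                    eps,
                    rng,
                )

        for p in range(length):
            row = counts[p]
            yield PileupColumn(
                contig_id=contig.contig_id,
                pos=p + 1,
                ref_base=contig.sequence[p],
                counts={
                    samples[s]: (
                        int(row[s, 0]),
                        int(row[s, 1]),
                        int(row[s, 2]),
                        int(row[s, 3]),
                        int(row[s, 4]),
                        0,
                    )
                    for s in range(n_samples)
                },
            )


def simulate_read_pairs(
    reference: Sequence[ReferenceContig],
    cfg: SimConfig,
    n_pairs: int = 10_000,
    rng: np.random.Generator | None = None,
    fragment_mean: float = 300.0,
    fragment_sd: float = 30.0,
    read_length: int = 125,
) -> tuple[list[ReadPairRecord], int]:
    """Coordinate-sorted read pairs with PCR duplicates injected.

    Each emitted pair is, with probability ``cfg.pcr_dup_rate``, a copy of
    a previously emitted fragment (same coordinates and orientation, fresh
    name and qualities); otherwise a new fragment with Normal(300, 30) bp
    length is placed uniformly.  Returns the pairs sorted for duplicate
    marking plus the number of unique fragments generated.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lengths = np.array([len(c) for c in reference], dtype=float)
    weights = lengths / lengths.sum()
    pairs: list[ReadPairRecord] = []
    originals: list[tuple[str, int, int, str]] = []
    for i in range(n_pairs):
        if originals and rng.random() < cfg.pcr_dup_rate:
            key = originals[int(rng.integers(len(originals)))]
        else:
            ci = int(rng.choice(len(reference), p=weights))
            contig = reference[ci]
            frag = max(2 * read_length, int(round(rng.normal(fragment_mean, fragment_sd))))
            frag = min(frag, len(contig))
            start = int(rng.integers(1, max(2, len(contig) - frag + 2)))
            key = (contig.contig_id, start, start + frag - read_length, "FR")
            originals.append(key)
        pairs.append(
            ReadPairRecord(
                query_name=f"frag{i:07d}",
                contig_id=key[0],
                left_start_1=key[1],
                left_start_2=key[2],
                orientation=key[3],
                base_quality_sum=int(rng.integers(200, 5000)),
            )
        )
    pairs.sort(key=lambda p: (p.contig_id, p.left_start_1, p.query_name))
    return pairs, len(originals)
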