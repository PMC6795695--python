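"""Independent brute-force reference implementations used as test oracles.

Everything here is written the slow, literal way, without touching the
package internals beyond plain data types, so that agreement with the
package is evidence and not tautology.
"""

from __future__ import annotations

import numpy as np

from tillcall.caller import CallerConfig
from tillcall.core_io import ALLELES, PileupColumn

# ---------------------------------------------------------------------------
# region building: mark -> dilate every marked position -> union -> gap-merge


def naive_regions(depth, min_depth, flank, merge_gap):
    """Per-position brute force over a depth array (index 0 = position 1):
    every qualifying position is dilated by the flank, the dilations are
    unioned (overlap or adjacency), and near unions are merged."""
    length = len(depth)
    dilated = [
        [max(1, p - flank), min(length, p + flank)]
        for p in range(1, length + 1)
        if depth[p - 1] >= min_depth
    ]
    if not dilated:
        return []
    intervals = [dilated[0][:]]
    for start, end in dilated[1:]:
        if start <= intervals[-1][1] + 1:
            intervals[-1][1] = max(intervals[-1][1], end)
        else:
            intervals.append([start, end])
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        gap = start - merged[-1][1] - 1
        if gap < merge_gap or gap <= 0:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# duplicate marking: group-by on the full key, argmax on quality


def naive_mark_duplicates(pairs):
    groups = {}
    for pair in pairs:
        key = (pair.contig_id, pair.left_start_1, pair.left_start_2,
               pair.orientation)
        groups.setdefault(key, []).append(pair)
    kept = set()
    for members in groups.values():
        best = sorted(members,
                      key=lambda p: (-p.base_quality_sum, p.query_name))[0]
        kept.add(best.query_name)
    return {pair.query_name: pair.query_name not in kept for pair in pairs}


# ---------------------------------------------------------------------------
# calling: enumerate every (position, allele, sample) triple literally


def naive_call_population(columns, cfg: CallerConfig, samples, control_id):
    """Returns a set of call tuples (contig, pos, sample, allele, zygosity)."""
    mutants = [s for s in samples if s != control_id]
    calls = set()
    for col in columns:
        if col.ref_base == "N":
            continue
        # criterion 1a: control concordant with the reference
        ctrl = col.counts[control_id]
        depth_c = sum(ctrl[:5])
        if depth_c == 0:
            continue
        ref_i = ALLELES.index(col.ref_base)
        if any(ctrl[i] > ctrl[ref_i] for i in range(5)):
            continue
        if (depth_c - ctrl[ref_i]) / depth_c > cfg.control_max_minor_fraction:
            continue
        for ai, allele in enumerate(ALLELES):
            if allele == col.ref_base:
                continue
            present = [s for s in mutants
                       if col.counts[s][ai] >= cfg.presence_min_reads]
            # criterion 1b: present in exactly one mutant sample
            if len(present) != 1:
                continue
            carrier = present[0]
            support = col.counts[carrier][ai]
            # criterion 2: enough reads of the mutant allele
            if support < cfg.min_mut_support:
                continue
            # criterion 3: control allele adequately covered elsewhere
            informative = sum(
                1 for s in mutants
                if s != carrier and col.counts[s][ref_i] >= cfg.min_other_depth)
            if informative < cfg.min_informative_samples:
                continue
            depth_s = sum(col.counts[carrier][:5])
            f = support / depth_s
            if f >= cfg.hom_min_fraction:
                zyg = "homozygous"
            elif f >= cfg.het_min_fraction:
                zyg = "heterozygous"
            else:
                continue
            calls.add((col.contig_id, col.pos, carrier, allele, zyg))
    return calls


# ---------------------------------------------------------------------------
# adversarial pileup text encoder (deliberately ugly, unlike the writer)


def encode_column_text(counts_per_sample, ref_base, rng: np.random.Generator,
                       contig="ctg000001", pos=1):
    """Encode allele counts into one pileup line, exercising the dialect.

    Random symbol order, random case for mismatches, '^'/'$' markers and
    indel-length tokens are sprinkled in; the stated depth column counts
    read bases only, never markers.
    """
    fields = [contig, str(pos), ref_base]
    for counts in counts_per_sample:
        symbols = []
        for allele, n in zip(ALLELES, counts[:5]):
            for _ in range(n):
                if allele == ref_base:
                    symbols.append("." if rng.random() < 0.5 else ",")
                elif allele == "*":
                    symbols.append("*")
                else:
                    symbols.append(allele if rng.random() < 0.5
                                   else allele.lower())
        symbols.extend("N" if rng.random() < 0.5 else "n"
                       for _ in range(counts[5]))
        rng.shuffle(symbols)
        depth = len(symbols)
        decorated = []
        for sym in symbols:
            if rng.random() < 0.1:
                sym = "^" + chr(33 + int(rng.integers(0, 60))) + sym
            if rng.random() < 0.1:
                sym = sym + "$"
            if rng.random() < 0.08:  # insertion/deletion announcement token
                ins_len = int(rng.integers(1, 4))
                ins = "".join("ACGT"[int(rng.integers(4))]
                              for _ in range(ins_len))
                sym = sym + ("+" if rng.random() < 0.5 else "-") + str(ins_len) + ins
            decorated.append(sym)
        if depth == 0:
            fields.extend(["0", "*", "*"])
        else:
            fields.extend([str(depth), "".join(decorated), "I" * depth])
    return "\t".join(fields)
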