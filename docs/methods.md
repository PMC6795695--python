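# Methods

## Problem setting

An EMS-mutagenized M₂ population is exome-captured and sequenced: one
unmutagenized control deeply (~29.5 reads/base) and each mutant line
shallowly and unevenly (per-line means of roughly 1.2–11.3 reads/base are
typical). Induced mutations are rare (tens per Mbp per line), private to a
line, and overwhelmingly C→T / G→A transitions; confounders are varietal
SNPs (shared by the control), sequencing error, PCR duplication, and — in
polyploids — homeolog cross-mapping. `tillcall` covers the analysis from
reference construction through a searchable mutation table.

## Coverage-driven reference construction

With no annotation available, coding regions are recovered from the
control's alignment depth against a source assembly. The procedure is:

1. mark maximal runs of positions with depth ≥ `min_depth` (default 17,
   inclusive);
2. extend each run by `flank` bases on both sides (default 500), clipped
   at chromosome ends — capture coverage decays gradually across
   intron–exon boundaries, so flanks retain mappable context;
3. merge extended regions whose gap is strictly less than `merge_gap`
   (default 301; a gap of exactly 301 stays split, gap ≤ 0 always merges,
   merging is transitive);
4. excise sequences with provenance (source assembly, chromosome, 1-based
   inclusive coordinates) and number contigs `ctg000001…` in genomic
   order, continuing across assemblies; append externally assembled
   contigs of length ≥ 500 bp as unplaced.

The proximity test runs on flank-extended coordinates, not cores. Applied
to cores it could leave overlapping contigs (two cores 900 bp apart would
each carry 500 bp flanks); post-flank merging guarantees disjoint, sorted
output, and the tested invariant is that output gaps are all ≥
`merge_gap`. Depth is used as aligned, before duplicate removal.

## Duplicate marking

Fragments are keyed by (contig, both mates' leftmost positions,
orientation) — the standard coordinate criterion; the algorithm streams
position-sorted input with memory proportional to the deepest single
start position. One pair per key is kept: highest base-quality sum, ties
broken by query name, making the kept set reproducible and the operation
idempotent. Optical duplicates and UMIs are out of scope.

## Mutation calling

Every non-reference allele at every pileup column is evaluated
independently (so a column can yield calls in different lines for
different alleles). A call requires:

1. **Control concordance** — the control's majority allele equals the
   reference base and its minor-allele fraction (all non-reference reads
   over depth) is ≤ `control_max_minor_fraction` (default 0.1). A strict
   unanimity rule would reject most deep control columns through stray
   error reads; the cap tolerates them while still excluding varietal
   SNPs, which appear at high fraction in the control.
2. **Uniqueness** — the allele is *present* (≥ `presence_min_reads`
   reads, default 2) in exactly one mutant line. The floor of 2 exists so
   a single error read in a second line does not veto a true call;
   presence in two or more lines rejects the allele as `not_unique`.
3. **Support** — the carrier has ≥ `min_mut_support` reads of the allele
   (default 3; high-confidence analyses use 10, the threshold at which
   the published durum call set reaches 94 % canonical transitions).
4. **Population coverage** — ≥ `min_informative_samples` (default 50)
   *other* mutant lines each show ≥ `min_other_depth` (default 3) reads
   of the control allele, guaranteeing the population could have exposed
   a shared allele. The 50-line default fits a ~100-line experiment and
   must be scaled down for smaller populations (tests use 20 of 40 lines,
   mirroring the same 0.5 fraction).

Zygosity follows from the carrier's mutant-allele fraction
*f* = support/depth: homozygous at *f* ≥ `hom_min_fraction` (0.85),
heterozygous at `het_min_fraction` ≤ *f* < 0.85 (floor 0.15), otherwise
no call. The bands are centred between the M₂ expectations *f* ≈ 0.5
(heterozygote) and *f* ≈ 1.0 (homozygote) with room for binomial sampling
noise at ≥ 10× depth, and are configurable because an analyst may prefer
a different minor-allele ratio. A sub-floor fraction is recorded as an
`insufficient_support` verdict with an explanatory detail (the audit
status set has no dedicated no-call state). Deletions are treated as a
fifth allele (`*` in the pileup, `DEL` in output); insertions are never
called and their pileup tokens are consumed and discarded. Columns whose
reference base is N are flagged non-callable.

Every rejected candidate leaves an audit verdict; columns where no allele
reaches presence in any line stay silent, keeping the audit trail
proportional to the interesting positions.

**Monotonicity.** The call count is non-increasing in `min_mut_support`,
`min_informative_samples` and `min_other_depth`, and the property suite
asserts this. It is *not* monotone in `presence_min_reads`: raising that
threshold shrinks other lines' presence sets, so alleles previously
rejected as shared become unique and the call count can rise before the
carrier itself drops below the threshold. The parameter is therefore
documented as a noise-tolerance knob, not a stringency knob.

**Callable space.** The mutation rate per Mbp divides total calls by the
number of (line, position) pairs whose depth reaches the support
threshold — the positions where a mutation could have been called at all.
The per-line rate uses the line's own callable positions.

## Summary statistics and export

`summarize` reports per-type counts, the CG→TA fraction (C→T plus G→A
substitutions over all calls; a spectrum quality proxy), the het:hom
ratio computed from counts (reported as missing when no homozygous calls
exist), and rates as above. `coverage_sweep` re-thresholds recorded
support values, giving the non-increasing het and hom series used to pick
an operating point. Export rows carry up to 200 bp of flank per side
(truncated at contig edges; a side under 50 bp raises a warning flag)
with the site marked `[ref/alt]` (`[ref/-]` for deletions); stripping the
marker and restoring the reference base reproduces an exact reference
substring, which is tested. The SQLite table is indexed for the two query
modes (by contig, sorted by supporting depth; by mutant line, in genomic
order). Chromosome location comes from contig provenance; de-novo contigs
are "unplaced".

## Synthetic populations

The generator emulates exactly the structure the caller assumes:
per-line mutation counts Poisson(rate × genome Mbp) at unique positions
(default 20/Mbp); canonical transitions with probability
`p_canonical_ems` (default 0.98) placed on C/G sites; heterozygous with
probability `p_het` (default 2/3); single-base deletions at `p_deletion`
(0.001); varietal SNPs (default 50/Mbp) homozygous in every sample
including the control; depth position-independent Poisson with per-line
means drawn from 1.2–11.3× (or fixed for power analyses) and 29.5× for
the control; read errors at 0.002/read moved to a uniformly chosen wrong
base; read pairs with ~300 bp fragments and duplicates injected at
`pcr_dup_rate`. All outputs are byte-deterministic under the seed, and
the pileup writer/parser round-trip is exact.

Deliberately **not** modelled: capture-efficiency and GC bias along
contigs, indel sequencing errors, and homeolog collapse (near-identical
subgenome copies mapping to one contig). Passing tests therefore show the
calling logic is correct under its own assumptions, not that real
polyploid data is free of homeolog-driven false positives — on real data
those are mitigated by the uniqueness criterion and the CG→TA fraction
diagnostic, and the caller itself is homeolog-agnostic.

## Problem sizes and numerical choices

The parameter-recovery suite simulates 40 lines × 200 contigs × 2 kb at a
fixed 30× with `min_mut_support` 10 and `min_informative_samples` 20 —
about 300 true mutations, enough for recall/precision/zygosity checks and
a ±2σ het:hom window around 2:1. Oracle-equivalence checks run the full
caller against a literal enumerate-every-triple implementation on 500
random 200-column 8-sample pileups, and the region builder against a
dilate-and-union recomputation on 1,000 random 5 kb tracks. Duplicate-rate
recovery uses 10⁴ pairs at 50 % injection (3σ binomial band). Thresholds
are compared inclusively everywhere ("at least n" semantics); interval
arithmetic is 1-based inclusive internally with BED conversion only at
output; ties in duplicate selection and in the control-majority test are
broken deterministically (query name; reference base wins majority ties).

## Known limitations

* The caller streams but keeps all calls and verdicts in memory; for
  genome-scale runs verdicts can be disabled (`keep_verdicts=False`).
* Coverage files without explicit chromosome lengths are padded to the
  assembly length at the CLI boundary; the library-level track carries
  its own length.
* `dedup` emits flagged records and metrics, not rewritten BAM output;
  alignment files are consumed, never produced.
* Base qualities are parsed from pileups but unused in calling; the
  support thresholds subsume a per-base quality filter.
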