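# Methods

Models, parameters and numerical choices, module by module. Defaults
given here are the library defaults; all are overridable.

## Coordinates and variants (`core`, `io`)

All coordinates are **0-based, half-open** internally; 1-based
coordinates appear only at VCF serialization. `PhasedVariant` records
are biallelic and normalized: alleles are trimmed of shared prefix and
suffix, then left-aligned against the reference (iteratively shifting an
indel left while the flanking base matches), so that any two call sets
compare on identical keys `(contig, pos, ref, alt)`. Genotypes are
pipe-separated phased calls (`0|1`, `1|0`, `1|1`), optionally with a
phase-block identifier; half-calls (`1|.`, `.|1`) mark positions covered
by only one haplotype.

`AlignmentBlock` stores an alignment as M/I/D segments (match/mismatch
collapsed into M), serialized as PAF with a `cg:Z` CIGAR tag. The
readers are hand-rolled so that malformed input fails with the file name
and line number; the VCF subset is single-sample with `GT`/`PS` only.

## Liftover (`liftover`)

A `CoordinateMap` is a set of alignment blocks that must be disjoint on
*both* genomes (checked at construction), giving a one-to-one mapping.
Point liftover walks the segments: M positions map bijectively,
positions inside I/D holes return `None`. Interval liftover in strict
mode requires mapped endpoints after snapping them inward to the nearest
mapped base within the same block; it returns `None` when the interval
is entirely unmapped. Consequently **round-trip identity holds exactly
on M segments** — a property the acceptance suite verifies on 1,000
random positions per haplotype.

`slice_query` cuts a block to a query window, preserving target
coordinates — used to project reads placed on a haplotype onto the
reference through the truth alignment.

## Simulator (`simulate`)

`simulate_diploid` generates a uniform-random reference of
`region_length` bp (default 500,000) and plants variants per haplotype:

- SNVs at `snv_rate` per bp (default 0.005, i.e. ~5 het SNVs/kb —
  typical of a highly polymorphic target region), indels at
  `indel_rate` (default 0.0007) with geometric-ish short lengths.
- CpG-affecting substitutions at `cpg_flip_rate` (default 0.02 of CpG
  sites): one third are homozygous (`1|1`). Heterozygous-only flips can
  never remove a CpG from *both* haplotypes, so homozygous losses are
  required for the "reference-only" CpG class to be non-empty.
- Structural variants from `sv_spec` as (type, size) with type in
  {DEL, INS, DUP}; DUP is a tandem duplication (an insertion carrying a
  copy of the adjacent sequence). SV size must be < region/10.
- `n_genes` non-overlapping gene models of `gene_length` bp.

Determinism: every stage draws from
`np.random.SeedSequence([seed, crc32(stage_name)])`, so adding or
re-running one stage never perturbs another; seeds must lie in
[0, 2³¹).

Read simulators:

- **HiFi** (`simulate_hifi`): normal read lengths (mean 12,000 bp,
  SD 1,500), substitution errors at 0.2%, total diploid coverage
  `coverage` (default 30×, i.e. 15× per haplotype), optional
  amplification duplicates and reference-window dropouts. Each read
  carries its true haplotype, its error-free haplotype alignment, and
  its reference alignment projected through the truth map.
- **Linked reads** (`simulate_linked`): barcoded short-read molecules
  with optional barcode collisions (two molecules at least
  `collision_min_distance` apart sharing a barcode). Infeasible
  collision geometry (distance unreachable within the region) raises
  `ConfigError` instead of looping.
- **Bisulfite** (`simulate_bisulfite`): emits per-CpG, per-replicate
  (methylated, unmethylated) count evidence directly — downstream
  methods consume counts, and bisulfite alignment is out of scope. Each
  haplotype CpG has a true level drawn bimodally (0.05–0.2 or 0.8–0.95,
  shared between haplotypes at homologous positions); coverage is
  Poisson (default 30× per replicate, 3 replicates); a conversion
  failure leak of 1 − 0.995 inflates observed methylation. `dmr_spec`
  windows (reference coordinates) override the levels to 0.5 ∓ Δ/2
  (haplotype 1 hypo-, haplotype 2 hypermethylated).
- **RNA** (`simulate_rna`): per gene and replicate, the **total** count
  is negative binomial (mean 200, dispersion 0.1) — biological noise
  shared by both alleles — and the haplotype-1 count given the total is
  binomial with success probability fold/(1+fold). Putting the
  overdispersion on the total rather than on independent per-allele
  draws is what makes a binomial allelic-imbalance test calibrated; an
  infinite fold silences haplotype 2 entirely.

`corrupt_assembly` plants controlled defects for evaluation: phase
switches at given reference positions, contig breaks, collapse of a
tandem duplication (dropping the inserted copy), and random
substitutions. `collapsed_read_placements` projects the carrier
haplotype's reads onto the collapsed contig, splitting reads that cross
a copy boundary (as an aligner would), so the surviving copy shows
uniformly doubled coverage.

## Linked-read filtering (`linked`)

Barcode-level filtering around a target region, applied in order:

1. **Screening**: drop barcodes with ≤ 2 reads or reads containing `N`.
2. **On-target selection**: keep barcodes with ≥ 1 read inside the
   target.
3. **Collision removal**: drop barcodes whose maximum adjacent
   mapped-read gap exceeds 40 kb — two distant molecules sharing one
   barcode.
4. **Window gating**: tile the target into 160-kb windows; per window,
   keep barcodes with strictly more than 10 reads there.
5. **Density capping**: inside each window, iteratively remove whole
   barcodes (smallest contribution first, ties lexicographic) while any
   10-kb bin exceeds 70× read coverage — flattening pile-ups near the
   enrichment cut sites.

## HiFi partitioning (`hifi`)

- **Duplicate marking**: reads with identical placement (contig, start,
  end, strand) and sequence identity ≥ 0.99 (edlib) are grouped; the
  longest read (ties by id) is primary.
- **Recruitment**: ≥ 1 bp overlap with the target interval.
- **Downsampling**: per 10-kb bin (by alignment start), remove the
  shortest read (ties by id) while the bin's summed read length exceeds
  `target_cov × bin_size`. Removing shortest-first preserves the long
  reads that drive assembly contiguity.
- **Reliable hets**: intersect two het call sets on normalized keys,
  then keep only those phased in a phased call set, copying phase
  orientation and block.
- **Haplotagging**: for each read, compare the read base at each covered
  phased SNV to the two haplotype alleles; with support counts s1/s2 the
  read is H1 if s1 ≥ s2 + 1, H2 if s2 ≥ s1 + 1, else untagged. Indel
  hets and deleted positions are uninformative. Untagged reads go to
  *both* haplotype partitions (they harm neither assembly).

## Assembly evaluation (`evaluate`)

- **Variant derivation**: per haplotype, alignment blocks ≥ 10 kb
  (shorter blocks are noise-prone) are required to be one-to-one;
  mismatches and indel segments become normalized variants. A site is a
  diploid call when both haplotypes cover it (genotype from
  presence/absence per haplotype) and a half-call when only one does.
- **FNR/FDR**: benchmark comparison on normalized keys, optionally
  restricted to confident regions; genotype discordance among matched
  sites is reported separately.
- **Phasing errors**: per phase block, the test/truth het orientations
  form a binary disagreement vector; the switch error rate is the
  fraction of adjacent flips, and the Hamming error rate is
  `min(k, n−k)/n` (global flips are not errors). Blocks aggregate
  weighted by het count. Both equal exhaustive brute-force enumeration
  (verified up to length 12). A single unrepaired switch in the middle
  of a block yields Hamming ≈ 0.5 — the catastrophic failure mode that
  block-wise switch counting would understate.
- **Contiguity**: NGA50/LGA50 computed from *aligned block* lengths
  against the target span (not contig lengths), so misassemblies do not
  inflate the statistic.
- **Collapsed repeats**: threshold = control mean + 3 SD of per-base
  control coverage; 10-kb windows at 1-kb steps above threshold are
  merged; merged regions ≥ 10 kb are reported. The 3-SD rule keeps the
  false-positive rate low without a tuned absolute cutoff; at only ~2×
  excess the margin depends on local placement noise (doubled coverage
  sits ~1.2 SD above the threshold at 30× per haplotype).

## HLA typing (`hla`)

Global (Needleman–Wunsch) edit distance via edlib, banded at
`2·|len(a)−len(b)| + 50` with an automatic unbanded fallback when the
band is exceeded — banded equals full DP on all inputs, just faster.
The call reports all database alleles at minimum distance, the typing
resolution in digits (2 × colon-separated fields), a `novel` flag for
nonzero distance, and an explicit `untyped` state for an empty region.

## Methylation (`methylation`)

- **CpG classification**: CpGs found on each personal haplotype and the
  reference; a haplotype CpG is *shared* when the homologous position on
  the other haplotype (through reference coordinates) is also CpG,
  otherwise *haplotype-specific*; a reference CpG absent from both
  haplotypes is *reference-only*. Reported fractions are rounded
  **half-up** to 2 decimals (`percent`), matching how such tables are
  conventionally printed — banker's rounding would print 2.37 for
  2.375.
- **Site table**: evidence from both haplotypes is joined on reference
  coordinates (union of lifted positions), columns indexed by
  (M/U, haplotype, replicate). `shared_only` filtering keeps sites
  covered in ≥ 2 replicates on *each* haplotype.
- **Smoothing**: per track, a local weighted (tricube × coverage)
  average over a window of at least 50 CpGs and at least 800 bp,
  whichever is larger; sites separated by more than `max_gap` never
  share a window.
- **DMR calling**: per site, a pooled-variance t-like statistic between
  the two haplotypes' smoothed replicate levels with a variance floor of
  1e-4 (avoids infinite t on constant tracks); runs of |t| > 3.6 with
  ≥ 3 CpGs and mean raw level difference ≥ 0.10 become DMRs. Because
  the smoothing support is ~50 sites, a short planted DMR is recovered
  with full coverage of the planted window but boundaries widened to
  roughly the smoothing window — the call's *extent* is
  resolution-limited by design.
- **Array concordance**: EPIC-style beta = M/(M + U + 100) (the +100
  stabilizes low-intensity probes), and Pearson r² between array and
  sequencing levels stratified by whether a probe lies within 5 bp of a
  variant (probe-SNP interference).

## Allele-specific expression (`ase`)

Gene models are lifted from the reference onto each haplotype; genes
overlapping indels (either endpoint unmapped, or lifted length differing
from the original) are flagged and excluded from testing, with the
clipped interval still reported when one exists. Uniquely aligned,
duplicate-free, haplotype-assigned reads are counted per gene, replicate
and haplotype; ambiguous reads are excluded (conservative and
deterministic, rather than fractional assignment).

Samples (replicate × haplotype) are normalized by **median-of-ratios
size factors**: per gene the ratio of its count to the geometric mean
across samples, median over genes with all-positive counts. Note the
factors are defined only up to the geometric-mean normalization:
scaling one sample by c scales its factor by c^((m−1)/m) but the
*ratio* between factors by exactly c. A genome-wide allelic imbalance
is absorbed by the factors and is unidentifiable from allele counts
alone — power simulations must plant imbalance on a gene subset.

Per gene, a two-sided exact binomial test of hap1 fraction = 0.5 on the
size-factor-normalized summed counts, Benjamini–Hochberg adjusted;
significant when adjusted p < α (strictly; default α = 0.05). The count
matrix is exported in a (replicate × haplotype)-column layout usable
directly by negative-binomial frameworks for users who prefer a Wald
test.

## Limitations

- The simulator plants substitution errors only in reads; no real
  aligner is run anywhere — alignments are constructed by projection,
  so alignment artifacts (soft-clipping, mapping ambiguity in repeats)
  are out of scope.
- The VCF subset is single-sample `GT`/`PS`; multi-sample files and
  other FORMAT fields are rejected.
- The exact binomial ASE test ignores replicate-level overdispersion of
  the *allelic fraction*; it is calibrated under the shared-total NB ×
  binomial allocation model and will be anticonservative if allelic
  fractions themselves vary biologically between replicates.
- DMR boundaries are resolution-limited by the smoothing window (see
  above); collapsed-repeat detection at 2× excess operates close to the
  mean + 3 SD threshold and is sensitive to local coverage fluctuations.
- HLA typing is whole-region edit distance against a genomic allele
  database; it does not model exon-only (CDS) typing or novel-allele
  breakpoint placement.
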