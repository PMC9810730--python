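# targhap

A toolkit for building, evaluating and interpreting **targeted
haplotype-resolved assemblies** of megabase-scale genomic regions, with
downstream haplotype-aware analyses: variant derivation and phasing
evaluation, linked-read barcode filtering, HiFi read partitioning,
collapsed-repeat detection, HLA allele typing, allele-specific
methylation (DMR calling) and allele-specific expression testing.

Regions such as the MHC combine extreme polymorphism, segmental
duplications and dense gene content. Enrichment-based sequencing of such
a region followed by separate assembly of each parental haplotype
resolves variation that reference-mapping approaches miss, and enables
allele-level analyses — which allele of a gene is expressed, which
haplotype carries a methylated promoter, which HLA alleles are present.
`targhap` implements the coordinate machinery, the filtering and
partitioning logic, the evaluation metrics and the statistical tests for
this workflow, together with a fully seeded diploid simulator that
provides ground truth for every stage.

## Package layout

| Module | Contents |
|---|---|
| `targhap.core` | `GenomicInterval`, `PhasedVariant` (normalized, phased genotypes), `AlignmentBlock` (M/I/D segments), evidence records |
| `targhap.io` | FASTA / FASTQ / PAF (`cg:Z` CIGAR) / VCF subset / BED readers and writers with line-accurate errors |
| `targhap.liftover` | One-to-one `CoordinateMap` between genomes, point/interval liftover, alignment slicing |
| `targhap.simulate` | Seeded diploid simulator: SNVs, indels, SVs, CpG flips, gene models, methylation profiles; HiFi, linked-read, bisulfite and RNA read/evidence simulators; controlled assembly corruption |
| `targhap.linked` | Barcode-level linked-read filtering: screening, on-target selection, collision removal, window gating, density capping |
| `targhap.hifi` | Duplicate marking, recruitment, coverage-capped downsampling, reliable-het construction, read haplotagging and partitioning |
| `targhap.evaluate` | Assembly-derived phased variants, FNR/FDR vs a benchmark, switch/Hamming phasing errors, NGA50/LGA50, collapsed-repeat detection |
| `targhap.hla` | Edit-distance HLA typing against an allele database, typing resolution |
| `targhap.methylation` | CpG classification (shared / haplotype-specific / reference-only), smoothing, DMR calling, array-vs-sequencing concordance |
| `targhap.ase` | Gene-model liftover, allelic counting, median-of-ratios size factors, exact binomial imbalance test with BH adjustment |

Every stage is also exposed on the command line as a `targhap`
subcommand operating on plain text files.

## Worked example

Simulate a 100-kb phased diploid region with truth files and HiFi reads,
then run the evaluation stages against the truth. All outputs below are
the actual printed results of these commands.

```sh
targhap simulate --seed 11 --region-length 100000 --out demo
```

Derive phased variants from the haplotype-to-reference alignments and
compare them to the truth VCF:

```sh
targhap eval-variants --hap1 demo/hap1.fa --hap2 demo/hap2.fa \
    --reference demo/reference.fa \
    --paf1 demo/truth_hap1.paf --paf2 demo/truth_hap2.paf \
    --benchmark demo/truth.vcf --out demo/derived.vcf
```
```json
{
  "n_calls": 777,
  "n_half_calls": 0,
  "fnr": 0.0,
  "fdr": 0.0,
  "matched": 777,
  "genotype_discordant": 0
}
```

Tag the simulated HiFi reads by phased-SNV allele majority:

```sh
targhap haplotag --reads demo/hifi.fastq --alignments demo/hifi_to_ref.paf \
    --hets demo/truth.vcf --out demo/tags.tsv
```
```json
{"H1": 125, "H2": 124, "untagged": 0}
```

Phasing error of the derived calls against the truth, and contiguity of
the truth alignments over the target:

```sh
targhap eval-phasing --test demo/derived.vcf --truth demo/truth.vcf
```
```json
{
  "switch_error_rate": 0.0,
  "hamming_error_rate": 0.0,
  "n_switches": 0
}
```
```sh
targhap eval-contiguity --paf demo/truth_maps.paf --target ref:0-100000
```
```json
{
  "nga50": 100000,
  "lga50": 1,
  "total_aligned": 200000,
  "fraction_of_target": 1.0
}
```

Classify CpG sites between the personal haplotypes and the reference:

```sh
targhap meth-classify --hap1 demo/hap1.fa --hap2 demo/hap2.fa \
    --reference demo/reference.fa \
    --paf1 demo/truth_hap1.paf --paf2 demo/truth_hap2.paf
```
```json
{
  "hap1_specific_pct": "2.23",
  "hap2_specific_pct": "2.15",
  "reference_only_pct": "0.75"
}
```

The same stages are available as library calls; see the test suite for
worked API examples of every function.

## Tests

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

The suite covers hand-traced unit examples, brute-force and oracle
cross-checks (exhaustive phasing-error enumeration, dynamic-programming
edit distance, median-of-ratios recomputation), property tests on seeded
simulations, and `tests/test_acceptance.py`, which pins the end-to-end
contracts with runtime budgets.

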