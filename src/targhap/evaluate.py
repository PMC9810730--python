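"""Assembly evaluation against a reference and benchmark call sets.

Covers assembly-to-reference diploid variant derivation (a dipcall-like
procedure on one-to-one alignment blocks at least 10 kb long),
switch/Hamming phasing error rates, FNR/FDR against a benchmark within
optional high-confidence regions, NGA50/LGA50 contiguity, collapsed
repeat detection by excess read depth (mean + k standard deviations of
a control region), and per-window variant/CpG-variant densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import (
    AlignmentBlock,
    EvalReport,
    GenomicInterval,
    PhasedVariant,
    left_align,
)
from .liftover import CoordinateMap, MapError

DEFAULT_MIN_BLOCK = 10_000


@dataclass(frozen=True)
class ContiguityStats:
    nga50: Optional[int]
    lga50: Optional[int]
    total_aligned: int
    fraction_of_target: float


@dataclass(frozen=True)
class CollapsedRegion:
    interval: GenomicInterval
    mean_coverage: float
    threshold: float


# ---------------------------------------------------------------------------
# dipcall-like variant derivation

def _variants_from_block(
    block: AlignmentBlock,
    query_seq: str,
    reference: str,
) -> list[tuple[int, str, str]]:
    """Walk a block's segments: M mismatches -> SNVs, I/D -> anchored
    normalized indels.  Positions are reference (target) coordinates."""
    out: list[tuple[int, str, str]] = []
    q, t = block.query_start, block.target_start
    for op, ln in block.segments:
        if op == "M":
            qs = query_seq[q : q + ln]
            ts = reference[t : t + ln]
            for i in range(ln):
                if qs[i] != ts[i]:
                    out.append((t + i, ts[i], qs[i]))
            q += ln
            t += ln
        elif op == "I":
            if t == 0:
                q += ln
                continue  # cannot anchor an insertion before the region
            anchor = reference[t - 1]
            pos, ref, alt = left_align(
                t - 1, anchor, anchor + query_seq[q : q + ln], reference
            )
            out.append((pos, ref, alt))
            q += ln
        else:  # D
            if t == 0:
                t += ln
                continue
            anchor = reference[t - 1]
            pos, ref, alt = left_align(
                t - 1, anchor + reference[t : t + ln], anchor, reference
            )
            out.append((pos, ref, alt))
            t += ln
    return out


def derive_phased_variants(
    hap1_blocks: Sequence[AlignmentBlock],
    hap2_blocks: Sequence[AlignmentBlock],
    hap1_seqs: dict[str, str],
    hap2_seqs: dict[str, str],
    reference: str,
    contig: str = "ref",
    min_block: int = DEFAULT_MIN_BLOCK,
) -> tuple[list[PhasedVariant], list[PhasedVariant]]:
    """Derive a diploid phased call set from the two haplotypes' one-to-one
    alignments against the reference.

    Returns (diploid calls, half-calls).  A position covered by only one
    haplotype yields a half-call (genotype ``1|.`` / ``.|1``), excluded
    from genotype comparison but reported.
    """
    per_hap: list[dict[tuple[int, str, str], None]] = []
    coverage_trees: list[IntervalTree] = []
    for blocks, seqs in ((hap1_blocks, hap1_seqs), (hap2_blocks, hap2_seqs)):
        kept = [b for b in blocks if b.target_span >= min_block]
        CoordinateMap(tuple(kept))  # raises MapError if not one-to-one
        tree = IntervalTree()
        calls: dict[tuple[int, str, str], None] = {}
        for b in kept:
            tree.addi(b.target_start, b.target_end)
            for key in _variants_from_block(b, seqs[b.query_contig], reference):
                calls[key] = None
        per_hap.append(calls)
        coverage_trees.append(tree)

    all_keys = sorted(set(per_hap[0]) | set(per_hap[1]))
    diploid: list[PhasedVariant] = []
    half_calls: list[PhasedVariant] = []
    for pos, ref, alt in all_keys:
        in1 = (pos, ref, alt) in per_hap[0]
        in2 = (pos, ref, alt) in per_hap[1]
        cov1 = bool(coverage_trees[0][pos])
        cov2 = bool(coverage_trees[1][pos])
        if cov1 and cov2:
            gt = f"{int(in1)}|{int(in2)}"
            diploid.append(PhasedVariant(contig, pos, ref, alt, gt))
        elif cov1 or cov2:
            gt = "1|." if in1 else ".|1"
            half_calls.append(PhasedVariant(contig, pos, ref, alt, gt))
    return diploid, half_calls


# ---------------------------------------------------------------------------
# phasing errors

def phasing_errors(
    test: Iterable[PhasedVariant], truth: Iterable[PhasedVariant]
) -> tuple[float, float]:
    """Switch and Hamming error rates over hets shared by both sets.

    Each shared het is encoded by which allele haplotype 1 carries; the
    switch rate counts adjacent pairs whose relative orientation differs
    from truth, the Hamming rate is min(d, n-d)/n per phase block
    (invariant to a global flip), both aggregated weighted by per-block
    het counts."""
    truth_by_key = {
        v.key: v for v in truth if v.is_phased and v.is_het
    }
    blocks: dict[str, list[tuple[int, int, int]]] = {}
    for v in test:
        if not (v.is_phased and v.is_het) or v.key not in truth_by_key:
            continue
        t = truth_by_key[v.key]
        bit_test = 1 if v.genotype == "1|0" else 0
        bit_truth = 1 if t.genotype == "1|0" else 0
        blocks.setdefault(v.phase_block or "_", []).append(
            (v.pos, bit_test, bit_truth)
        )
    switch_num = switch_den = 0
    ham_num = ham_den = 0
    for sites in blocks.values():
        sites.sort()
        d = [bt ^ btr for _, bt, btr in sites]
        n = len(d)
        if n >= 2:
            switch_num += sum(1 for a, b in zip(d, d[1:]) if a != b)
            switch_den += n - 1
        if n >= 1:
            ham_num += min(sum(d), n - sum(d))
            ham_den += n
    switch_rate = switch_num / switch_den if switch_den else 0.0
    hamming_rate = ham_num / ham_den if ham_den else 0.0
    return switch_rate, hamming_rate


def count_switches(
    test: Iterable[PhasedVariant], truth: Iterable[PhasedVariant]
) -> int:
    """Absolute number of switch events (adjacent-pair disagreements)."""
    rate_num = 0
    truth_by_key = {v.key: v for v in truth if v.is_phased and v.is_het}
    blocks: dict[str, list[tuple[int, int]]] = {}
    for v in test:
        if not (v.is_phased and v.is_het) or v.key not in truth_by_key:
            continue
        t = truth_by_key[v.key]
        blocks.setdefault(v.phase_block or "_", []).append(
            (v.pos, (v.genotype == "1|0") ^ (t.genotype == "1|0"))
        )
    for sites in blocks.values():
        sites.sort()
        d = [x for _, x in sites]
        rate_num += sum(1 for a, b in zip(d, d[1:]) if a != b)
    return rate_num


# ---------------------------------------------------------------------------
# benchmark comparison

@dataclass(frozen=True)
class BenchmarkResult:
    fnr: float
    fdr: float
    n_benchmark: int
    n_calls: int
    n_matched: int
    n_genotype_discordant: int


def _in_regions(v: PhasedVariant, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(v.contig)
    return bool(tree is not None and tree[v.pos])


def benchmark_compare(
    calls: Sequence[PhasedVariant],
    benchmark: Sequence[PhasedVariant],
    confident_regions: Optional[Sequence[GenomicInterval]] = None,
) -> BenchmarkResult:
    """Site-level FNR/FDR by normalized (contig, pos, ref, alt) matching,
    optionally restricted to high-confidence regions; genotype mismatches
    among matched sites are reported separately."""
    if confident_regions is not None:
        trees: dict[str, IntervalTree] = {}
        for iv in confident_regions:
            trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
        calls = [v for v in calls if _in_regions(v, trees)]
        benchmark = [v for v in benchmark if _in_regions(v, trees)]
    call_map = {v.key: v for v in calls if not v.is_half_call}
    bench_map = {v.key: v for v in benchmark}
    matched = set(call_map) & set(bench_map)
    n_bench, n_calls = len(bench_map), len(call_map)
    fnr = (n_bench - len(matched)) / n_bench if n_bench else 0.0
    fdr = (n_calls - len(matched)) / n_calls if n_calls else 0.0
    discordant = sum(
        1 for k in matched
        if _unphased(call_map[k].genotype) != _unphased(bench_map[k].genotype)
    )
    return BenchmarkResult(fnr, fdr, n_bench, n_calls, len(matched), discordant)


def _unphased(gt: str) -> tuple[str, ...]:
    return tuple(sorted(gt.replace("|", "/").split("/")))


# ---------------------------------------------------------------------------
# contiguity

def contiguity(
    blocks: Sequence[AlignmentBlock], target: GenomicInterval
) -> ContiguityStats:
    """NGA50/LGA50: sort aligned block lengths descending and accumulate
    until covering 50% of the target; NGA50 is the length of the block
    crossing the threshold, LGA50 the number of blocks used."""
    lengths = sorted((b.target_span for b in blocks), reverse=True)
    covered = IntervalTree()
    for b in blocks:
        covered.addi(b.target_start, b.target_end)
    covered.merge_overlaps()
    total_covered = sum(
        max(0, min(iv.end, target.end) - max(iv.begin, target.start))
        for iv in covered
    )
    half = target.length / 2
    acc = 0
    nga50 = lga50 = None
    for i, ln in enumerate(lengths, 1):
        acc += ln
        if acc >= half:
            nga50, lga50 = ln, i
            break
    return ContiguityStats(
        nga50=nga50,
        lga50=lga50,
        total_aligned=sum(lengths),
        fraction_of_target=total_covered / target.length,
    )


# ---------------------------------------------------------------------------
# collapsed repeats

def coverage_from_placements(
    placements: Iterable[tuple[int, int]], length: int
) -> np.ndarray:
    """Per-base coverage from (start, end) read placements."""
    cov = np.zeros(length + 1, dtype=np.int64)
    for s, e in placements:
        cov[max(0, s)] += 1
        cov[min(length, e)] -= 1
    return np.cumsum(cov)[:length]


def collapsed_regions(
    coverage: np.ndarray,
    control_coverage: np.ndarray,
    k: float = 3.0,
    min_len: int = 10_000,
    window: int = 10_000,
    step: int = 1_000,
) -> tuple[list[CollapsedRegion], int]:
    """Detect collapsed repeats as regions of excess read depth.

    The threshold is mean + k standard deviations of the control
    coverage; 10-kb windows slid at 1-kb steps with mean coverage above
    the threshold are merged, and merged regions at least ``min_len``
    long are reported together with their total base count."""
    threshold = float(np.mean(control_coverage) + k * np.std(control_coverage))
    csum = np.concatenate([[0], np.cumsum(coverage)])
    marked: list[tuple[int, int]] = []
    for s in range(0, max(1, len(coverage) - window + 1), step):
        e = min(s + window, len(coverage))
        if (csum[e] - csum[s]) / (e - s) > threshold:
            if marked and s <= marked[-1][1]:
                marked[-1] = (marked[-1][0], e)
            else:
                marked.append((s, e))
    regions = []
    total = 0
    for s, e in marked:
        if e - s >= min_len:
            mean_cov = float((csum[e] - csum[s]) / (e - s))
            regions.append(
                CollapsedRegion(GenomicInterval("assembly", s, e), mean_cov, threshold)
            )
            total += e - s
    return regions, total


# ---------------------------------------------------------------------------
# window densities

def window_density(
    positions: Iterable[int], region: GenomicInterval, window: int = 10_000
) -> np.ndarray:
    """Counts of item start positions per non-overlapping window tiled
    from the region start (half-open; boundary items go right)."""
    n = -(-region.length // window)
    counts = np.zeros(n, dtype=np.int64)
    for p in positions:
        if region.start <= p < region.end:
            counts[(p - region.start) // window] += 1
    return counts
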