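"""HiFi read preparation and haplotype partitioning.

Implements the long-read side of the targeted assembly workflow:
amplification-duplicate removal, target-region recruitment, per-bin
coverage down-sampling, construction of a reliable phased heterozygous
variant set, haplotagging by phased-allele majority, partitioning into
per-haplotype read sets (untagged reads feed both), and rescue of reads
that align to the assembled haplotypes but were missed by the initial
reference recruitment.  All operations are deterministic with stable
tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib

from .core import AlignmentBlock, GenomicInterval, PhasedVariant, TaggedRead
from .liftover import _lift_in_block


@dataclass
class ReliableHetSet:
    """Phased heterozygous variants retained by the intersection +
    phase-attachment procedure, with per-variant provenance."""

    variants: list[PhasedVariant]
    provenance: dict[tuple, tuple[str, ...]]
    n_dropped_unphased: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for v in self.variants:
            if v.genotype not in ("0|1", "1|0"):
                raise ValueError(f"reliable set requires phased hets, got {v.genotype}")
            if v.key in seen:
                raise ValueError(f"duplicate variant {v.key}")
            seen.add(v.key)


# ---------------------------------------------------------------------------
# dedup / recruit / downsample

def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def mark_duplicates(
    sequences: dict[str, str],
    alignments: dict[str, AlignmentBlock],
    min_identity: float = 0.99,
) -> tuple[set[str], set[str]]:
    """Flag amplification duplicates: identical placement (contig, start,
    end, strand) and sequence identity >= ``min_identity``.  Within a
    duplicate group the longest read is kept (ties by lexicographic id).

    Returns (primary ids, duplicate ids); reads without an alignment are
    primary by definition.
    """
    groups: dict[tuple, list[str]] = {}
    for rid, seq in sequences.items():
        b = alignments.get(rid)
        if b is None:
            continue
        key = (b.target_contig, b.target_start, b.target_end, b.strand)
        groups.setdefault(key, []).append(rid)
    duplicates: set[str] = set()
    for key, ids in groups.items():
        if len(ids) < 2:
            continue
        ids.sort(key=lambda r: (-len(sequences[r]), r))
        reps: list[str] = []
        for rid in ids:
            for rep in reps:
                if _identity(sequences[rid], sequences[rep]) >= min_identity:
                    duplicates.add(rid)
                    break
            else:
                reps.append(rid)
    primary = set(sequences) - duplicates
    return primary, duplicates


def recruit_reads(
    alignments: dict[str, Sequence[AlignmentBlock] | AlignmentBlock],
    target: GenomicInterval,
) -> set[str]:
    """Reads with any alignment block overlapping the target by >= 1 bp."""
    recruited: set[str] = set()
    for rid, blocks in alignments.items():
        if isinstance(blocks, AlignmentBlock):
            blocks = [blocks]
        for b in blocks:
            if b.target_interval.overlaps(target):
                recruited.add(rid)
                break
    return recruited


def downsample_to_coverage(
    read_lengths: dict[str, int],
    start_positions: dict[str, int],
    target_cov: float,
    bin_size: int = 10_000,
) -> set[str]:
    """Per 10-kb bin (by alignment start), remove the shortest read (ties
    by lexicographic id) while bin coverage exceeds ``target_cov``; a
    read removed in its start bin is removed globally."""
    bins: dict[int, list[str]] = {}
    for rid in read_lengths:
        bins.setdefault(start_positions[rid] // bin_size, []).append(rid)
    removed: set[str] = set()
    for b, ids in bins.items():
        ids = sorted(ids, key=lambda r: (read_lengths[r], r))
        total = sum(read_lengths[r] for r in ids)
        budget = target_cov * bin_size
        i = 0
        while total > budget and i < len(ids):
            total -= read_lengths[ids[i]]
            removed.add(ids[i])
            i += 1
    return set(read_lengths) - removed


# ---------------------------------------------------------------------------
# reliable het construction

def intersect_hets(
    set_a: Iterable[PhasedVariant], set_b: Iterable[PhasedVariant]
) -> list[PhasedVariant]:
    """Variants heterozygous in BOTH sets, matched on normalized
    (contig, pos, ref, alt); genotype taken from set A."""
    b_keys = {v.key for v in set_b if v.is_het}
    out, seen = [], set()
    for v in set_a:
        if v.is_het and v.key in b_keys and v.key not in seen:
            out.append(v)
            seen.add(v.key)
    return out


def attach_phase(
    hets: Iterable[PhasedVariant], phased: Iterable[PhasedVariant]
) -> ReliableHetSet:
    """Retain hets present and phased in the phased call set; the phase
    orientation (0|1 vs 1|0) and phase block are copied from it."""
    phased_by_key = {
        v.key: v for v in phased if v.genotype in ("0|1", "1|0")
    }
    kept: list[PhasedVariant] = []
    provenance: dict[tuple, tuple[str, ...]] = {}
    dropped = 0
    for v in hets:
        pv = phased_by_key.get(v.key)
        if pv is None:
            dropped += 1
            continue
        kept.append(v.with_genotype(pv.genotype, pv.phase_block))
        provenance[v.key] = ("intersection", "phased")
    return ReliableHetSet(kept, provenance, n_dropped_unphased=dropped)


# ---------------------------------------------------------------------------
# haplotagging

def read_base_at(
    block: AlignmentBlock, sequence: str, target_pos: int
) -> Optional[str]:
    """Base the read carries at a reference position, or None when the
    position is deleted in the read or outside the alignment."""
    if not (block.target_start <= target_pos < block.target_end):
        return None
    qpos = _lift_in_block(block, target_pos, query_side=False)
    if qpos is None or not (0 <= qpos < len(sequence)):
        return None
    return sequence[qpos]


def haplotag_reads(
    sequences: dict[str, str],
    alignments: dict[str, AlignmentBlock],
    hets: ReliableHetSet,
    margin: int = 1,
) -> list[TaggedRead]:
    """Assign each read to a haplotype by phased-SNV-allele majority.

    For each covered SNV het, the read base is compared to the allele
    each haplotype carries; with s1 (s2) support counts the read is H1
    when s1 >= s2 + margin, H2 when s2 >= s1 + margin, otherwise
    untagged.  Indel hets and deleted positions are uninformative."""
    snvs = sorted(
        (v for v in hets.variants if v.is_snv), key=lambda v: (v.contig, v.pos)
    )
    positions = [v.pos for v in snvs]
    import bisect

    tagged: list[TaggedRead] = []
    for rid in sorted(sequences):
        seq = sequences[rid]
        block = alignments.get(rid)
        s1 = s2 = 0
        interval = None
        if block is not None:
            interval = block.target_interval
            lo = bisect.bisect_left(positions, block.target_start)
            hi = bisect.bisect_left(positions, block.target_end)
            for v in snvs[lo:hi]:
                if v.contig != block.target_contig:
                    continue
                base = read_base_at(block, seq, v.pos)
                if base == v.hap_allele(1):
                    s1 += 1
                elif base == v.hap_allele(2):
                    s2 += 1
        if s1 >= s2 + margin:
            tag = "H1"
        elif s2 >= s1 + margin:
            tag = "H2"
        else:
            tag = "untagged"
        tagged.append(TaggedRead(rid, tag, len(seq), interval, s1, s2))
    return tagged


def partition_reads(tagged: Iterable[TaggedRead]) -> tuple[set[str], set[str]]:
    """Per-haplotype read sets; untagged reads are duplicated into both."""
    hap1: set[str] = set()
    hap2: set[str] = set()
    for t in tagged:
        if t.haplotype_tag in ("H1", "untagged"):
            hap1.add(t.read_id)
        if t.haplotype_tag in ("H2", "untagged"):
            hap2.add(t.read_id)
    return hap1, hap2


def rescue_supplementary(
    assembly_alignments: dict[str, Sequence[AlignmentBlock] | AlignmentBlock],
    initially_recruited: set[str],
) -> set[str]:
    """Reads aligned to either assembled haplotype (>= 1 bp) that the
    initial reference recruitment missed; fed into a second assembly pass."""
    aligned = {
        rid
        for rid, blocks in assembly_alignments.items()
        if (isinstance(blocks, AlignmentBlock) and blocks is not None)
        or (not isinstance(blocks, AlignmentBlock) and len(blocks) > 0)
    }
    return aligned - initially_recruited
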