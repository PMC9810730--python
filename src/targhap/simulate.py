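"""Synthetic diploid target region with truth labels.

The generator emulates the data regime of a CRISPR-enriched ~megabase
diploid locus (default 500 kb standing in for the 4.5 Mb MHC): ~5.7
heterozygous variants per kb (SNVs + short indels), CpG gains/losses,
kb-scale structural variants including a tandem duplication for
collapsed-repeat tests, ~12 kb HiFi-like reads, barcoded linked reads
with deliberate barcode collisions, bisulfite evidence with planted
DMRs, and RNA counts with planted allelic fold changes.  Every product
carries truth labels so downstream accuracy is computable.

Determinism: a single master seed; each stage derives its own stream by
hashing (stage name, seed), so outputs do not depend on call order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    AlignmentBlock,
    BarcodedRead,
    GenomicInterval,
    MethylationEvidence,
    PhasedVariant,
    left_align,
)
from .liftover import CoordinateMap, slice_query

BASES = np.array(list("ACGT"))
REF_NAME = "ref"


class ConfigError(ValueError):
    """Invalid or self-contradictory simulation configuration."""


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class HiFiConfig:
    mean_len: float = 12_000.0
    len_sd: float = 1_500.0
    error_rate: float = 0.002
    coverage: float = 30.0          # total diploid coverage
    duplicate_fraction: float = 0.0
    dropout_windows: tuple[tuple[int, int], ...] = ()  # reference coords


@dataclass(frozen=True)
class LinkedConfig:
    n_barcodes: int = 500
    barcode_length: int = 16
    reads_per_molecule: int = 30
    read_length: int = 150
    molecule_length: int = 50_000
    collision_fraction: float = 0.0
    collision_min_distance: int = 100_000


@dataclass(frozen=True)
class BisulfiteConfig:
    coverage: float = 30.0
    conversion_rate: float = 0.995
    n_replicates: int = 3
    # (ref_start, ref_end, delta): inside, hap1 level 0.5-delta/2, hap2 0.5+delta/2
    dmr_spec: tuple[tuple[int, int, float], ...] = ()


@dataclass(frozen=True)
class RNAConfig:
    n_replicates: int = 3
    mean_count: float = 200.0
    dispersion: float = 0.1
    # gene id -> hap1/hap2 expression fold change (math.inf silences hap2)
    ase_spec: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class SimConfig:
    region_length: int = 500_000
    snv_rate: float = 0.005
    indel_rate: float = 0.0007
    cpg_flip_rate: float = 0.02
    sv_spec: tuple[tuple[str, int], ...] = ()  # (DEL|INS|DUP, size)
    n_genes: int = 20
    gene_length: int = 4_000
    seed: int = 0
    hifi: HiFiConfig = field(default_factory=HiFiConfig)
    linked: LinkedConfig = field(default_factory=LinkedConfig)
    bisulfite: BisulfiteConfig = field(default_factory=BisulfiteConfig)
    rna: RNAConfig = field(default_factory=RNAConfig)

    def __post_init__(self) -> None:
        if self.region_length <= 0:
            raise ConfigError("region_length must be positive")
        if not (0 <= self.seed < 2**31):
            raise ConfigError("seed must lie in [0, 2^31)")
        for name in ("snv_rate", "indel_rate", "cpg_flip_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        for svtype, size in self.sv_spec:
            if svtype not in ("DEL", "INS", "DUP"):
                raise ConfigError(f"unknown SV type {svtype!r}")
            if size >= self.region_length / 10:
                raise ConfigError(
                    f"SV size {size} too large for region {self.region_length}"
                )

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific stream derived from (stage name, master seed)."""
        key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
        return np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, key])
        )


# ---------------------------------------------------------------------------
# diploid truth

@dataclass
class DiploidTruth:
    """Simulator output: reference, the two haplotypes, and all truth."""

    config: SimConfig
    reference: str
    hap1: str
    hap2: str
    truth_variants: list[PhasedVariant]
    truth_maps: dict[int, CoordinateMap]          # hap -> hap<->ref map
    gene_models: list[tuple[str, GenomicInterval]]
    # hap -> {hap CpG position -> true methylation probability}
    methylation_profiles: dict[int, dict[int, float]]
    sv_manifest: list[dict]

    def hap_seq(self, hap: int) -> str:
        return self.hap1 if hap == 1 else self.hap2

    @staticmethod
    def hap_name(hap: int) -> str:
        return f"hap{hap}"

    def variants_on(self, hap: int) -> list[PhasedVariant]:
        """Truth variants whose allele on the given haplotype is ALT."""
        return [
            v for v in self.truth_variants
            if v.is_phased and v.hap_allele(hap) == v.alt_allele
        ]


def apply_variants(
    reference: str, variants: Sequence[PhasedVariant], query_name: str
) -> tuple[str, AlignmentBlock]:
    """Apply non-overlapping variants to the reference; returns the edited
    sequence and its alignment back to the reference."""
    parts: list[str] = []
    segs: list[tuple[str, int]] = []

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if segs and segs[-1][0] == op:
            segs[-1] = (op, segs[-1][1] + ln)
        else:
            segs.append((op, ln))

    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        if v.pos < cursor:
            raise ValueError(f"overlapping variants at {v.pos}")
        parts.append(reference[cursor : v.pos])
        push("M", v.pos - cursor)
        parts.append(v.alt_allele)
        if len(v.ref_allele) == len(v.alt_allele) == 1:        # SNV
            push("M", 1)
        elif len(v.ref_allele) == 1:                            # insertion
            push("M", 1)
            push("I", len(v.alt_allele) - 1)
        elif len(v.alt_allele) == 1:                            # deletion
            push("M", 1)
            push("D", len(v.ref_allele) - 1)
        else:                                                   # block substitution
            common = min(len(v.ref_allele), len(v.alt_allele))
            push("M", common)
            if len(v.alt_allele) > common:
                push("I", len(v.alt_allele) - common)
            else:
                push("D", len(v.ref_allele) - common)
        cursor = v.pos + len(v.ref_allele)
    parts.append(reference[cursor:])
    push("M", len(reference) - cursor)
    seq = "".join(parts)
    block = AlignmentBlock(
        query_contig=query_name,
        query_start=0,
        query_end=len(seq),
        target_contig=REF_NAME,
        target_start=0,
        target_end=len(reference),
        strand="+",
        segments=tuple(segs),
    )
    return seq, block


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


class _Occupancy:
    """Tracks reference spans already claimed by a variant."""

    def __init__(self) -> None:
        self.spans: list[tuple[int, int]] = []

    def free(self, start: int, end: int) -> bool:
        return all(not (start < e and s < end) for s, e in self.spans)

    def claim(self, start: int, end: int) -> None:
        self.spans.append((start, end))


def simulate_diploid(config: SimConfig) -> DiploidTruth:
    """Generate the reference, two haplotypes and all truth tables."""
    L = config.region_length
    reference = _random_seq(config.rng("reference"), L)

    occ = _Occupancy()
    variants: list[PhasedVariant] = []
    sv_manifest: list[dict] = []

    # --- structural variants -----------------------------------------------
    rng_sv = config.rng("sv")
    margin = max(10_000, config.gene_length)
    for svtype, size in config.sv_spec:
        placed = False
        for _ in range(1000):
            p = int(rng_sv.integers(margin, L - margin - size))
            if occ.free(p - 1000, p + size + 1000):
                placed = True
                break
        if not placed:
            raise ConfigError("could not place SVs without overlap")
        hap = 1 if rng_sv.random() < 0.5 else 2
        gt = "1|0" if hap == 1 else "0|1"
        if svtype == "DEL":
            ref = reference[p - 1 : p + size]
            v = PhasedVariant(REF_NAME, p - 1, ref, ref[0], gt)
            footprint = GenomicInterval(REF_NAME, p, p + size)
        elif svtype == "INS":
            ins = _random_seq(rng_sv, size)
            anchor = reference[p - 1]
            v = PhasedVariant(REF_NAME, p - 1, anchor, anchor + ins, gt)
            footprint = GenomicInterval(REF_NAME, p - 1, p + 1)
        else:  # DUP: tandem duplication of [p, p+size)
            anchor = reference[p + size - 1]
            v = PhasedVariant(
                REF_NAME, p + size - 1, anchor, anchor + reference[p : p + size], gt
            )
            footprint = GenomicInterval(REF_NAME, p, p + size)
        npos, nref, nalt = left_align(v.pos, v.ref_allele, v.alt_allele, reference)
        v = PhasedVariant(REF_NAME, npos, nref, nalt, gt)
        variants.append(v)
        occ.claim(min(npos, p) - 2, max(npos + len(nref), p + size) + 2)
        sv_manifest.append(
            {"type": svtype, "interval": footprint, "size": size,
             "haplotype": hap, "variant_key": v.key}
        )

    # --- small variants ----------------------------------------------------
    rng_v = config.rng("smallvar")
    u = rng_v.random(L)
    snv_pos = np.flatnonzero(u < config.snv_rate)
    indel_pos = np.flatnonzero(
        (u >= config.snv_rate) & (u < config.snv_rate + config.indel_rate)
    )
    for p in snv_pos:
        p = int(p)
        if p < 2 or p > L - 3 or not occ.free(p, p + 1):
            continue
        ref = reference[p]
        alt = _other_base(rng_v, ref)
        gt = "1|0" if rng_v.random() < 0.5 else "0|1"
        variants.append(PhasedVariant(REF_NAME, p, ref, alt, gt))
        occ.claim(p, p + 1)
    for p in indel_pos:
        p = int(p)
        size = int(min(1 + rng_v.geometric(0.5), 10))
        if p < 12 or p > L - size - 12:
            continue
        gt = "1|0" if rng_v.random() < 0.5 else "0|1"
        if rng_v.random() < 0.5:  # deletion of [p+1, p+1+size)
            if not occ.free(p - 11, p + size + 2):
                continue
            ref = reference[p : p + size + 1]
            alt = ref[0]
        else:  # insertion after p
            if not occ.free(p - 11, p + 2):
                continue
            ref = reference[p]
            alt = ref + _random_seq(rng_v, size)
        npos, nref, nalt = left_align(p, ref, alt, reference)
        if not occ.free(npos, npos + len(nref) + 1):
            continue
        variants.append(PhasedVariant(REF_NAME, npos, nref, nalt, gt))
        occ.claim(npos - 1, p + len(ref) + 1)

    # --- CpG gains and losses ----------------------------------------------
    rng_c = config.rng("cpg")
    if config.cpg_flip_rate > 0:
        refarr = np.frombuffer(reference.encode(), dtype="S1")
        cg = np.flatnonzero((refarr[:-1] == b"C") & (refarr[1:] == b"G"))
        tg = np.flatnonzero((refarr[:-1] == b"T") & (refarr[1:] == b"G"))
        losses = cg[rng_c.random(cg.size) < config.cpg_flip_rate]
        gains = tg[rng_c.random(tg.size) < config.cpg_flip_rate / 2]
        for p, alt_base, ref_base in (
            [(int(p), "T", "C") for p in losses] + [(int(p), "C", "T") for p in gains]
        ):
            if p < 2 or not occ.free(p, p + 1):
                continue
            # a third of CpG flips are homozygous, so some reference CpGs
            # vanish from (or appear in) both haplotypes
            u = rng_c.random()
            gt = "1|1" if u < 1 / 3 else ("1|0" if u < 2 / 3 else "0|1")
            variants.append(PhasedVariant(REF_NAME, p, ref_base, alt_base, gt))
            occ.claim(p, p + 1)

    variants.sort(key=lambda v: v.pos)

    # --- haplotype sequences and truth maps --------------------------------
    hap_seqs: dict[int, str] = {}
    truth_maps: dict[int, CoordinateMap] = {}
    for h in (1, 2):
        carried = [v for v in variants if v.hap_allele(h) == v.alt_allele]
        seq, block = apply_variants(reference, carried, f"hap{h}")
        hap_seqs[h] = seq
        truth_maps[h] = CoordinateMap((block,))

    # --- gene models --------------------------------------------------------
    genes: list[tuple[str, GenomicInterval]] = []
    if config.n_genes > 0:
        starts = np.linspace(
            margin, L - margin - config.gene_length, config.n_genes
        ).astype(int)
        for i, s in enumerate(starts, 1):
            genes.append(
                (f"gene{i:03d}", GenomicInterval(REF_NAME, int(s), int(s) + config.gene_length))
            )

    # --- methylation profiles ----------------------------------------------
    rng_m = config.rng("methylation")
    base_level: dict[int, float] = {}

    def draw_level() -> float:
        if rng_m.random() < 0.5:
            return float(rng_m.uniform(0.05, 0.2))
        return float(rng_m.uniform(0.8, 0.95))

    profiles: dict[int, dict[int, float]] = {1: {}, 2: {}}
    for h in (1, 2):
        seq = hap_seqs[h]
        cmap = truth_maps[h]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        cpg_positions = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        for p in cpg_positions:
            p = int(p)
            refpos = cmap.lift(p, "query_to_target")
            if refpos is not None:
                if refpos not in base_level:
                    base_level[refpos] = draw_level()
                level = base_level[refpos]
            else:
                level = draw_level()
            if refpos is not None:
                for s, e, delta in config.bisulfite.dmr_spec:
                    if s <= refpos < e:
                        level = min(1.0, max(0.0, 0.5 + (delta / 2) * (1 if h == 2 else -1)))
            profiles[h][p] = level

    return DiploidTruth(
        config=config,
        reference=reference,
        hap1=hap_seqs[1],
        hap2=hap_seqs[2],
        truth_variants=variants,
        truth_maps=truth_maps,
        gene_models=genes,
        methylation_profiles=profiles,
        sv_manifest=sv_manifest,
    )


# ---------------------------------------------------------------------------
# HiFi reads

@dataclass(frozen=True)
class HiFiRead:
    read_id: str
    sequence: str
    haplotype: int
    hap_start: int
    hap_end: int
    is_duplicate_copy: bool = False


@dataclass
class HiFiSim:
    reads: list[HiFiRead]
    hap_alignments: dict[str, AlignmentBlock]   # read <-> its haplotype (error-free)
    ref_alignments: dict[str, AlignmentBlock]   # read <-> reference (through truth map)
    labels: dict[str, int]                      # read id -> haplotype

    @property
    def sequences(self) -> dict[str, str]:
        return {r.read_id: r.sequence for r in self.reads}


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    arr = list(seq)
    for p in positions:
        arr[p] = _other_base(rng, arr[p])
    return "".join(arr)


def simulate_hifi(truth: DiploidTruth, config: Optional[HiFiConfig] = None) -> HiFiSim:
    cfg = config or truth.config.hifi
    rng = truth.config.rng("hifi")
    reads: list[HiFiRead] = []
    hap_aln: dict[str, AlignmentBlock] = {}
    ref_aln: dict[str, AlignmentBlock] = {}
    labels: dict[str, int] = {}

    def dropout(ref_pos: Optional[int]) -> bool:
        if ref_pos is None:
            return False
        return any(s <= ref_pos < e for s, e in cfg.dropout_windows)

    for h in (1, 2):
        seq = truth.hap_seq(h)
        hap_len = len(seq)
        cmap = truth.truth_maps[h]
        block = cmap.blocks[0]
        target_bases = cfg.coverage / 2 * hap_len
        emitted = 0
        i = 0
        base_ids: list[str] = []
        while emitted < target_bases:
            length = int(np.clip(rng.normal(cfg.mean_len, cfg.len_sd), 1000, hap_len))
            start = int(rng.integers(0, hap_len - length + 1))
            if dropout(cmap.lift(start, "query_to_target")):
                continue
            rid = f"hifi_h{h}_{i:06d}"
            i += 1
            read_seq = _add_errors(rng, seq[start : start + length], cfg.error_rate)
            reads.append(HiFiRead(rid, read_seq, h, start, start + length))
            hap_aln[rid] = AlignmentBlock(
                rid, 0, length, f"hap{h}", start, start + length, "+",
                (("M", length),),
            )
            rblock = slice_query(block, start, start + length, new_query_contig=rid)
            if rblock is not None:
                ref_aln[rid] = rblock
            labels[rid] = h
            base_ids.append(rid)
            emitted += length
        # amplification duplicates: same placement, independently re-errored
        n_dup = int(round(cfg.duplicate_fraction * len(base_ids)))
        if n_dup:
            by_id = {r.read_id: r for r in reads}
            for rid in rng.choice(base_ids, size=n_dup, replace=False):
                src = by_id[str(rid)]
                did = src.read_id + "_dup"
                dup_seq = _add_errors(
                    rng,
                    truth.hap_seq(h)[src.hap_start : src.hap_end],
                    cfg.error_rate,
                )
                reads.append(
                    HiFiRead(did, dup_seq, h, src.hap_start, src.hap_end, True)
                )
                hap_aln[did] = replace(hap_aln[src.read_id], query_contig=did)
                if src.read_id in ref_aln:
                    ref_aln[did] = replace(ref_aln[src.read_id], query_contig=did)
                labels[did] = h
    return HiFiSim(reads, hap_aln, ref_aln, labels)


# ---------------------------------------------------------------------------
# linked reads

@dataclass
class LinkedSim:
    reads: list[BarcodedRead]
    placements: dict[str, tuple[int, int]]      # read id -> (ref position, length)
    molecules: list[tuple[str, int, int]]       # (barcode, ref start, ref end)
    colliding_barcodes: set[str]


def simulate_linked(truth: DiploidTruth, config: Optional[LinkedConfig] = None
                    ) -> LinkedSim:
    cfg = config or truth.config.linked
    rng = truth.config.rng("linked")
    L = len(truth.reference)
    if cfg.molecule_length >= L:
        raise ConfigError("molecule_length must be smaller than the region")

    barcodes: set[str] = set()
    while len(barcodes) < cfg.n_barcodes:
        barcodes.add(_random_seq(rng, cfg.barcode_length))
    barcode_list = sorted(barcodes)
    order = rng.permutation(cfg.n_barcodes)
    n_collide = int(round(cfg.collision_fraction * cfg.n_barcodes))
    colliding = {barcode_list[i] for i in order[:n_collide]}

    reads: list[BarcodedRead] = []
    placements: dict[str, tuple[int, int]] = {}
    molecules: list[tuple[str, int, int]] = []
    max_start = L - cfg.molecule_length
    if colliding and cfg.collision_min_distance > max_start:
        raise ConfigError(
            "collision_min_distance exceeds the placeable molecule start "
            f"range ({max_start} bp); shrink molecule_length or the distance"
        )

    for bc in barcode_list:
        if bc in colliding:
            while True:
                s1 = int(rng.integers(0, max_start + 1))
                s2 = int(rng.integers(0, max_start + 1))
                if abs(s1 - s2) >= cfg.collision_min_distance:
                    break
            starts = [s1, s2]
        else:
            starts = [int(rng.integers(0, max_start + 1))]
        for mi, s in enumerate(starts):
            molecules.append((bc, s, s + cfg.molecule_length))
            pos = np.sort(
                rng.integers(s, s + cfg.molecule_length - cfg.read_length,
                             cfg.reads_per_molecule)
            )
            for ri, p in enumerate(pos):
                p = int(p)
                mate_gap = 300
                p2 = min(p + mate_gap, L - cfg.read_length)
                for mate, mp in ((1, p), (2, p2)):
                    rid = f"lr_{bc}_{mi}_{ri:03d}/{mate}"
                    seq = truth.reference[mp : mp + cfg.read_length]
                    reads.append(BarcodedRead(rid, bc, seq, mate=mate))
                    placements[rid] = (mp, cfg.read_length)
    return LinkedSim(reads, placements, molecules, colliding)


# ---------------------------------------------------------------------------
# bisulfite evidence

def simulate_bisulfite(
    truth: DiploidTruth, config: Optional[BisulfiteConfig] = None
) -> list[MethylationEvidence]:
    """Per-haplotype, per-replicate (M, U) counts at every CpG of each
    personal haplotype.  A read reports C with probability equal to the
    true methylation level plus the failure-to-convert leak."""
    cfg = config or truth.config.bisulfite
    rng = truth.config.rng("bisulfite")
    evidence: list[MethylationEvidence] = []
    leak = 1.0 - cfg.conversion_rate
    for h in (1, 2):
        profile = dict(truth.methylation_profiles[h])
        positions = sorted(profile)
        if cfg.dmr_spec:
            # plant the DMRs: inside each reference window haplotype 1 is
            # hypomethylated and haplotype 2 hypermethylated by delta
            cmap = truth.truth_maps[h]
            for p in positions:
                rp = cmap.lift(p, "query_to_target")
                if rp is None:
                    continue
                for start, end, delta in cfg.dmr_spec:
                    if start <= rp < end:
                        profile[p] = 0.5 - delta / 2 if h == 1 else 0.5 + delta / 2
        for rep in range(1, cfg.n_replicates + 1):
            covs = rng.poisson(cfg.coverage, len(positions))
            for p, cov in zip(positions, covs):
                level = profile[p]
                p_obs = min(1.0, level + (1.0 - level) * leak)
                m = int(rng.binomial(cov, p_obs)) if cov else 0
                evidence.append(
                    MethylationEvidence(f"hap{h}", p, rep, m, int(cov) - m)
                )
    return evidence


# ---------------------------------------------------------------------------
# RNA counts

def simulate_rna(truth: DiploidTruth, config: Optional[RNAConfig] = None):
    """Per-gene, per-replicate haplotype-resolved counts.

    The total count of a gene in a replicate is negative binomial
    (biological/library noise, shared by both alleles); the split
    between haplotypes given the total is binomial with success
    probability fold/(1+fold) — the generative model under which
    allelic allocation carries no extra-binomial noise.

    Returns a pandas DataFrame (gene, replicate, hap1_count, hap2_count)
    and the gene -> fold truth dict.
    """
    import pandas as pd

    cfg = config or truth.config.rna
    rng = truth.config.rng("rna")
    ase = dict(cfg.ase_spec)
    rows = []
    for gene, _iv in truth.gene_models:
        fold = ase.get(gene, 1.0)
        frac1 = 1.0 if math.isinf(fold) else fold / (1.0 + fold)
        for rep in range(1, cfg.n_replicates + 1):
            total = _nb_draw(rng, cfg.mean_count, cfg.dispersion)
            c1 = int(rng.binomial(total, frac1)) if total else 0
            rows.append((gene, rep, c1, total - c1))
    df = pd.DataFrame(rows, columns=["gene", "replicate", "hap1_count", "hap2_count"])
    return df, {g: ase.get(g, 1.0) for g, _ in truth.gene_models}


def _nb_draw(rng: np.random.Generator, mu: float, dispersion: float) -> int:
    if mu <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mu))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mu)))


# ---------------------------------------------------------------------------
# assembly corruption

@dataclass
class CorruptedAssembly:
    contigs: dict[int, list[tuple[str, str]]]   # hap -> [(contig name, sequence)]
    maps: dict[int, CoordinateMap]              # hap -> contigs <-> reference
    variants: list[PhasedVariant]               # post-corruption truth variants
    manifest: dict


def corrupt_assembly(
    truth: DiploidTruth,
    switch_at: Sequence[int] = (),
    collapse_dup: bool = False,
    break_at: Sequence[int] = (),
    substitution_rate: float = 0.0,
) -> CorruptedAssembly:
    """Introduce controlled assembly defects for evaluation tests.

    ``switch_at``: reference positions; variant phase orientation flips at
    each boundary (a planted switch error).  ``collapse_dup``: remove the
    planted tandem duplication's second copy from its carrier haplotype.
    ``break_at``: reference positions at which contigs are split.
    """
    switch_points = sorted(switch_at)
    manifest: dict = {"switch_at": list(switch_points), "collapsed": None,
                      "break_at": list(break_at)}
    variants: list[PhasedVariant] = []
    drop_keys: set = set()
    if collapse_dup:
        dups = [m for m in truth.sv_manifest if m["type"] == "DUP"]
        if not dups:
            raise ConfigError("no tandem duplication in the simulation to collapse")
        dup = dups[0]
        drop_keys.add(dup["variant_key"])
        manifest["collapsed"] = dup
    for v in truth.truth_variants:
        if v.key in drop_keys:
            continue
        n_flips = sum(1 for p in switch_points if v.pos >= p)
        if n_flips % 2 and v.genotype in ("1|0", "0|1"):
            v = v.with_genotype("0|1" if v.genotype == "1|0" else "1|0")
        variants.append(v)

    rng = truth.config.rng("corrupt")
    contigs: dict[int, list[tuple[str, str]]] = {}
    maps: dict[int, CoordinateMap] = {}
    for h in (1, 2):
        carried = [v for v in variants if v.is_phased and v.hap_allele(h) == v.alt_allele]
        seq, block = apply_variants(truth.reference, carried, f"asm{h}")
        seq = _add_errors(rng, seq, substitution_rate)
        cmap = CoordinateMap((block,))
        if break_at:
            pieces: list[AlignmentBlock] = []
            cuts = sorted(
                q for q in (
                    cmap.lift(p, "target_to_query") for p in break_at
                ) if q is not None
            )
            bounds = [0] + cuts + [len(seq)]
            blocks = []
            for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
                piece = slice_query(block, a, b, new_query_contig=f"asm{h}_ctg{i}")
                if piece is not None:
                    blocks.append(replace(piece))
            contigs[h] = [
                (f"asm{h}_ctg{i}", seq[a:b])
                for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
            ]
            maps[h] = CoordinateMap(tuple(blocks))
        else:
            contigs[h] = [(f"asm{h}", seq)]
            maps[h] = CoordinateMap((replace(block, query_contig=f"asm{h}"),))
    return CorruptedAssembly(contigs, maps, variants, manifest)


def collapsed_read_placements(
    truth: DiploidTruth, hifi: HiFiSim, collapsed: CorruptedAssembly
) -> list[tuple[int, int]]:
    """Project the carrier haplotype's HiFi reads onto the collapsed
    contig: positions in or beyond the removed second copy shift left by
    the duplication size, doubling coverage over the surviving copy.

    Returns (start, end) placements on the collapsed assembly contig of
    the duplication's carrier haplotype.
    """
    dup = collapsed.manifest["collapsed"]
    if dup is None:
        raise ValueError("assembly was not collapsed")
    h = dup["haplotype"]
    size = dup["size"]
    # locate the inserted copy on the TRUE haplotype: the insertion segment
    # (after normalization it may precede or follow the original copy)
    block = truth.truth_maps[h].blocks[0]
    q = block.query_start
    copy_start = None
    for op, ln in block.segments:
        if op == "I" and ln == size:
            copy_start = q
        if op in "MI":
            q += ln
    if copy_start is None:
        raise ValueError("duplication insertion segment not found in truth map")
    # collapsed-contig coordinate where the surviving (original) copy sits;
    # reads from the inserted copy align there, doubling its coverage
    surviving_start = collapsed.maps[h].lift(
        dup["interval"].start, "target_to_query"
    )
    if surviving_start is None:
        raise ValueError("duplicated interval unmapped on the collapsed contig")
    def remap(x: int) -> int:
        if x < copy_start:
            return x
        if x < copy_start + size:
            return surviving_start + (x - copy_start)
        return x - size

    out = []
    for r in hifi.reads:
        if r.haplotype != h:
            continue
        s, e = r.hap_start, r.hap_end
        # reads crossing a copy boundary align split: each piece lands
        # where its sequence survives, so coverage over the retained copy
        # doubles uniformly
        cuts = [s] + [b for b in (copy_start, copy_start + size) if s < b < e] + [e]
        pieces = [(remap(a), remap(a) + (b - a)) for a, b in zip(cuts, cuts[1:])]
        merged = [pieces[0]]
        for p in pieces[1:]:
            if p[0] == merged[-1][1]:
                merged[-1] = (merged[-1][0], p[1])
            else:
                merged.append(p)
        out.extend(merged)
    return out
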