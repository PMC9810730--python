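"""Domain types shared by every stage of the targeted-assembly toolkit.

All genomic coordinates are 0-based, half-open on the forward strand.
1-based coordinates appear only at the VCF serialization boundary
(:mod:`targhap.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

DNA = set("ACGT")

PHASED_GENOTYPES = {"0|1", "1|0", "1|1", "0|0"}
UNPHASED_GENOTYPES = {"0/0", "0/1", "1/1"}
HALF_CALLS = {".|1", "1|.", ".|0", "0|.", "./1", "1/.", "./0", "0/."}
VALID_GENOTYPES = PHASED_GENOTYPES | UNPHASED_GENOTYPES | HALF_CALLS


class FormatError(ValueError):
    """A malformed record in one of the text formats the toolkit reads."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.contig, max(self.start, other.start), min(self.end, other.end)
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or touching intervals per contig."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.contig, i.start, i.end)):
        if out and out[-1].contig == iv.contig and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.contig, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return out


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared suffix, then shared prefix bases (keeping one anchor
    base for indels). Returns the adjusted (pos, ref, alt)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(
    pos: int, ref: str, alt: str, sequence: Optional[str] = None
) -> tuple[int, str, str]:
    """Normalize a variant: trim shared bases, then (for indels, when the
    reference sequence is available) shift left while the flanking base
    equals the last base of the varying allele."""
    if sequence is None or len(ref) == len(alt):
        return trim_alleles(pos, ref, alt)
    # vt-normalize style left shift for indels
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if min(len(ref), len(alt)) == 1:
                if pos == 0:
                    break
                prev = sequence[pos - 1]
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
                pos -= 1
            else:
                ref, alt = ref[:-1], alt[:-1]
            continue
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            continue
        break
    return pos, ref, alt


@dataclass(frozen=True)
class PhasedVariant:
    """A normalized biallelic variant with a diploid (possibly phased)
    genotype — the currency of calling, phasing and evaluation."""

    contig: str
    pos: int  # 0-based position of the first REF base
    ref_allele: str
    alt_allele: str
    genotype: str = "0|1"
    phase_block: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - DNA:
                raise ValueError(f"allele must be non-empty over ACGT: {allele!r}")
        if self.genotype not in VALID_GENOTYPES:
            raise ValueError(f"unsupported genotype {self.genotype!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_het(self) -> bool:
        return self.genotype in ("0/1", "0|1", "1|0")

    @property
    def is_phased(self) -> bool:
        return "|" in self.genotype and "." not in self.genotype

    @property
    def is_half_call(self) -> bool:
        return "." in self.genotype

    def hap_allele(self, hap: int) -> str:
        """Allele sequence carried by haplotype ``hap`` (1 or 2); requires
        a phased genotype."""
        if not self.is_phased:
            raise ValueError(f"genotype {self.genotype} is not phased")
        bit = self.genotype.split("|")[hap - 1]
        return self.alt_allele if bit == "1" else self.ref_allele

    def with_genotype(self, genotype: str, phase_block: Optional[str] = None
                      ) -> "PhasedVariant":
        return PhasedVariant(
            self.contig, self.pos, self.ref_allele, self.alt_allele,
            genotype, phase_block if phase_block is not None else self.phase_block,
        )


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignmentBlock:
    """One query-to-target alignment with M/I/D segments.

    M consumes both genomes, I consumes query only, D target only.  For
    '-' strand blocks query coordinates stay on the forward query strand
    and segments are ordered along the target.
    """

    query_contig: str
    query_start: int
    query_end: int
    target_contig: str
    target_start: int
    target_end: int
    strand: str = "+"
    segments: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        q = t = 0
        for op, ln in self.segments:
            if op not in "MID":
                raise ValueError(f"bad segment op {op!r}")
            if ln <= 0:
                raise ValueError("segment lengths must be > 0")
            if op in "MI":
                q += ln
            if op in "MD":
                t += ln
        if q != self.query_end - self.query_start:
            raise ValueError(
                f"CIGAR query span {q} != coordinate span "
                f"{self.query_end - self.query_start}"
            )
        if t != self.target_end - self.target_start:
            raise ValueError(
                f"CIGAR target span {t} != coordinate span "
                f"{self.target_end - self.target_start}"
            )

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def cigar(self) -> str:
        return "".join(f"{ln}{op}" for op, ln in self.segments)

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.target_contig, self.target_start, self.target_end)

    @staticmethod
    def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
        """Parse a cg:Z CIGAR; M/=/X all collapse to M, runs merged."""
        segs: list[tuple[str, int]] = []
        consumed = 0
        for m in _CIGAR_RE.finditer(cigar):
            ln, op = int(m.group(1)), m.group(2)
            consumed += len(m.group(0))
            if op in "=XM":
                op = "M"
            elif op not in "ID":
                raise FormatError(f"unsupported CIGAR op {op!r} in {cigar!r}")
            if segs and segs[-1][0] == op:
                segs[-1] = (op, segs[-1][1] + ln)
            else:
                segs.append((op, ln))
        if consumed != len(cigar) or not segs:
            raise FormatError(f"malformed CIGAR {cigar!r}")
        return tuple(segs)


@dataclass(frozen=True)
class BarcodedRead:
    """A short read carrying a GEM barcode."""

    read_id: str
    barcode: str
    sequence: str
    quality: Optional[str] = None
    mate: int = 1

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError("mate must be 1 or 2")
        if set(self.barcode) - set("ACGTN"):
            raise ValueError(f"barcode over ACGTN expected: {self.barcode!r}")


HAPLOTYPE_TAGS = ("H1", "H2", "untagged")


@dataclass(frozen=True)
class TaggedRead:
    """A read with its haplotype assignment."""

    read_id: str
    haplotype_tag: str
    length: int
    alignment: Optional[GenomicInterval] = None
    n_support_h1: int = 0
    n_support_h2: int = 0

    def __post_init__(self) -> None:
        if self.haplotype_tag not in HAPLOTYPE_TAGS:
            raise ValueError(f"bad haplotype tag {self.haplotype_tag!r}")


@dataclass(frozen=True)
class EvalReport:
    """Variant-calling and phasing accuracy summary."""

    n_variants: int
    n_phased: int
    fnr: float
    fdr: float
    switch_error_rate: float
    hamming_error_rate: float

    def __post_init__(self) -> None:
        for name in ("fnr", "fdr", "switch_error_rate", "hamming_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")


CPG_CLASSES = ("shared", "hap1_specific", "hap2_specific", "reference_only", "n/a")


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide (position of the C, forward strand) in one genome."""

    genome: str
    position: int
    cpg_class: str = "n/a"

    def __post_init__(self) -> None:
        if self.cpg_class not in CPG_CLASSES:
            raise ValueError(f"bad CpG class {self.cpg_class!r}")


@dataclass(frozen=True)
class MethylationEvidence:
    """Methylated (C) / unmethylated (T) read counts at one CpG site in
    one replicate."""

    genome: str
    position: int
    replicate: int
    methylated: int
    unmethylated: int

    def __post_init__(self) -> None:
        if self.methylated < 0 or self.unmethylated < 0:
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.methylated + self.unmethylated

    @property
    def level(self) -> Optional[float]:
        if self.coverage == 0:
            return None
        return self.methylated / self.coverage
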