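"""Readers and writers for the plain-text formats the pipeline touches.

Dialects implemented:

* FASTA / FASTQ (sequences over the IUPAC alphabet)
* PAF columns 1-12 plus the ``cg:Z:`` CIGAR tag (M/=/X all treated as M)
* a VCF 4.2 subset: single sample, GT genotype, optional PS phase-set tag
* BED3

Every reader/writer pair round-trips losslessly on simulator output.
POS in VCF is 1-based on disk and 0-based in memory; all other formats
are natively 0-based half-open.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .core import (
    AlignmentBlock,
    FormatError,
    GenomicInterval,
    PhasedVariant,
    left_align,
)

PathLike = Union[str, Path]

IUPAC = set("ACGTURYSWKMBDHVN")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs; empty file -> []."""
    records: list[tuple[str, str]] = []
    name: Optional[str] = None
    chunks: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    if not chunks:
                        raise FormatError(
                            f"{path}: empty sequence for {name!r} "
                            f"(header at line {header_line})"
                        )
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                if set(line.upper()) - IUPAC:
                    raise FormatError(
                        f"{path}: non-IUPAC characters at line {lineno}"
                    )
                chunks.append(line.upper())
        if name is not None:
            if not chunks:
                raise FormatError(
                    f"{path}: empty sequence for {name!r} "
                    f"(header at line {header_line})"
                )
            records.append((name, "".join(chunks)))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: PathLike, width: int = 80
) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: PathLike) -> list[tuple[str, str, str]]:
    """Read FASTQ records as (id, sequence, quality) triples."""
    out: list[tuple[str, str, str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) % 4:
        raise FormatError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed FASTQ record at line {i + 1}")
        if len(seq) != len(qual):
            raise FormatError(f"{path}: sequence/quality length mismatch at line {i + 1}")
        out.append((head[1:].split()[0], seq, qual))
    return out


def write_fastq(records: Iterable[tuple[str, str, Optional[str]]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# PAF + cg:Z

def read_paf(path: PathLike) -> list[AlignmentBlock]:
    """Read PAF alignments; every line must carry a cg:Z CIGAR tag."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: <12 PAF columns at line {lineno}")
            cigar = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
            if cigar is None:
                raise FormatError(f"{path}: missing cg:Z tag at line {lineno}")
            try:
                segments = AlignmentBlock.parse_cigar(cigar)
                block = AlignmentBlock(
                    query_contig=fields[0],
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_contig=fields[5],
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    segments=segments,
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            blocks.append(block)
    return blocks


def write_paf(
    blocks: Iterable[AlignmentBlock],
    path: PathLike,
    query_lengths: Optional[dict[str, int]] = None,
    target_lengths: Optional[dict[str, int]] = None,
) -> None:
    query_lengths = query_lengths or {}
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            n_match = sum(ln for op, ln in b.segments if op == "M")
            n_total = sum(ln for _, ln in b.segments)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_contig,
                        query_lengths.get(b.query_contig, b.query_end),
                        b.query_start,
                        b.query_end,
                        b.strand,
                        b.target_contig,
                        target_lengths.get(b.target_contig, b.target_end),
                        b.target_start,
                        b.target_end,
                        n_match,
                        n_total,
                        60,
                        f"cg:Z:{b.cigar}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF 4.2 subset (single sample, GT + PS)

def read_vcf(
    path: PathLike,
    reference: Optional[dict[str, str]] = None,
    multiallelic: str = "split",
) -> list[PhasedVariant]:
    """Read a single-sample VCF into normalized :class:`PhasedVariant`s.

    ``multiallelic`` is ``"split"`` (decompose into biallelic records) or
    ``"error"``.  Left-alignment uses ``reference`` when supplied.
    """
    if multiallelic not in ("split", "error"):
        raise ValueError("multiallelic must be 'split' or 'error'")
    variants: list[PhasedVariant] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}: <10 VCF columns at line {lineno}")
            contig, pos1, _id, ref, alts, _q, _f, _info, fmt, sample = fields[:10]
            fmt_keys = fmt.split(":")
            sample_vals = sample.split(":")
            rec = dict(zip(fmt_keys, sample_vals))
            gt = rec.get("GT")
            if gt is None:
                raise FormatError(f"{path}: no GT at line {lineno}")
            ps = rec.get("PS")
            alt_list = alts.split(",")
            if len(alt_list) > 1 and multiallelic == "error":
                raise FormatError(f"{path}: multi-allelic record at line {lineno}")
            sep = "|" if "|" in gt else "/"
            alleles = gt.replace("|", "/").split("/")
            for ai, alt in enumerate(alt_list, start=1):
                if alt in (".", "*"):
                    continue
                # genotype relative to this alt: this alt index -> 1, others -> 0
                bits = []
                for a in alleles:
                    if a == ".":
                        bits.append(".")
                    else:
                        bits.append("1" if int(a) == ai else "0")
                gt_bi = sep.join(bits)
                pos0 = int(pos1) - 1
                seq = reference.get(contig) if reference else None
                npos, nref, nalt = left_align(pos0, ref, alt, seq)
                try:
                    variants.append(
                        PhasedVariant(contig, npos, nref, nalt, gt_bi, ps)
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return variants


def write_vcf(
    variants: Sequence[PhasedVariant],
    reference: dict[str, str],
    path: PathLike,
    sample: str = "sample",
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, seq in reference.items():
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=String,Description="Phase set">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
            fmt, val = ("GT:PS", f"{v.genotype}:{v.phase_block}") if v.phase_block \
                else ("GT", v.genotype)
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\t{fmt}\t{val}\n"
            )


# ---------------------------------------------------------------------------
# BED3

def read_bed(path: PathLike) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: <3 BED columns at line {lineno}")
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
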