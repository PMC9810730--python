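"""Barcode-level filtering of linked reads for targeted assembly.

The pipeline mirrors the droplet (GEM) barcode hygiene used when
assembling a CRISPR-enriched region from linked reads: screen barcodes
by read count and N content, keep barcodes with on-target evidence,
drop barcode collisions by the adjacent-read-gap criterion, gate by
per-window read counts, and cap per-bin coverage deterministically.
It is a pure function of (reads, alignments, target, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import BarcodedRead, GenomicInterval


@dataclass
class BarcodeProfile:
    """Mapped read placements of one barcode, sorted by position."""

    barcode: str
    mapped_reads: list[tuple[int, int]]  # (position, length), sorted

    def __post_init__(self) -> None:
        self.mapped_reads = sorted(self.mapped_reads)

    @property
    def n_reads(self) -> int:
        return len(self.mapped_reads)

    @property
    def max_adjacent_gap(self) -> int:
        if len(self.mapped_reads) < 2:
            return 0
        positions = [p for p, _ in self.mapped_reads]
        return max(b - a for a, b in zip(positions, positions[1:]))


def build_profiles(
    placements: dict[str, tuple[int, int]],
    barcode_of: dict[str, str],
) -> dict[str, BarcodeProfile]:
    """Group read placements (read id -> (position, length)) by barcode."""
    grouped: dict[str, list[tuple[int, int]]] = {}
    for rid, placement in placements.items():
        grouped.setdefault(barcode_of[rid], []).append(placement)
    return {bc: BarcodeProfile(bc, reads) for bc, reads in grouped.items()}


def extract_and_screen_barcodes(
    reads: Iterable[BarcodedRead], min_reads: int = 2
) -> tuple[list[BarcodedRead], list[BarcodedRead]]:
    """Keep a barcode iff its read count is strictly > ``min_reads`` and
    the barcode sequence contains no N; everything else is rejected."""
    by_barcode: dict[str, list[BarcodedRead]] = {}
    for r in reads:
        by_barcode.setdefault(r.barcode, []).append(r)
    kept: list[BarcodedRead] = []
    rejected: list[BarcodedRead] = []
    for bc, group in by_barcode.items():
        if len(group) > min_reads and "N" not in bc:
            kept.extend(group)
        else:
            rejected.extend(group)
    return kept, rejected


def select_on_target(
    profiles: dict[str, BarcodeProfile], target: GenomicInterval
) -> set[str]:
    """Barcodes with at least one mapped read position inside the target."""
    return {
        bc for bc, p in profiles.items()
        if any(target.start <= pos < target.end for pos, _ in p.mapped_reads)
    }


def remove_collisions(
    profiles: dict[str, BarcodeProfile], max_gap: int = 40_000
) -> set[str]:
    """Barcodes whose maximum adjacent mapped-read gap is <= max_gap
    (strictly greater gaps indicate two distant molecules sharing the
    barcode and are removed)."""
    return {bc for bc, p in profiles.items() if p.max_adjacent_gap <= max_gap}


def window_gate(
    profiles: dict[str, BarcodeProfile],
    target: GenomicInterval,
    window: int = 160_000,
    min_reads: int = 10,
) -> dict[int, set[str]]:
    """Tile the target into non-overlapping windows anchored at its start
    and keep, per window, barcodes with strictly more than ``min_reads``
    mapped reads in that window.  The partial last window is gated with
    the same threshold."""
    out: dict[int, set[str]] = {}
    n_windows = max(1, -(-target.length // window))
    for w in range(n_windows):
        lo = target.start + w * window
        hi = min(lo + window, target.end)
        keep: set[str] = set()
        for bc, p in profiles.items():
            n = sum(1 for pos, _ in p.mapped_reads if lo <= pos < hi)
            if n > min_reads:
                keep.add(bc)
        out[w] = keep
    return out


def density_cap(
    profiles: dict[str, BarcodeProfile],
    barcodes: set[str],
    window_interval: GenomicInterval,
    bin_size: int = 10_000,
    max_coverage: float = 70.0,
) -> dict[int, set[str]]:
    """Iteratively cap per-bin coverage inside one window.

    Reads are assigned to the 10-kb bin containing their mapped start and
    contribute their full length to that bin's coverage.  While a bin's
    coverage exceeds ``max_coverage``, the barcode with the most reads in
    that bin is removed from that bin (ties broken by lexicographically
    smallest barcode); removal is per-bin, so a barcode removed in one
    bin survives in others.
    """
    bins: dict[int, dict[str, list[int]]] = {}
    for bc in barcodes:
        for pos, length in profiles[bc].mapped_reads:
            if window_interval.start <= pos < window_interval.end:
                b = (pos - window_interval.start) // bin_size
                bins.setdefault(b, {}).setdefault(bc, []).append(length)
    survivors: dict[int, set[str]] = {}
    for b, per_bc in bins.items():
        active = dict(per_bc)
        def coverage() -> float:
            return sum(sum(v) for v in active.values()) / bin_size
        while active and coverage() > max_coverage:
            # deterministic tie-break: most reads, then smallest barcode
            most = max(len(v) for v in active.values())
            candidates = sorted(bc for bc, v in active.items() if len(v) == most)
            del active[candidates[0]]
        survivors[b] = set(active)
    return survivors


def emit_filtered(
    reads: Iterable[BarcodedRead], surviving_barcodes: set[str]
) -> list[BarcodedRead]:
    """All reads (on- and off-target) of the surviving barcode union."""
    return [r for r in reads if r.barcode in surviving_barcodes]


@dataclass
class FilterReport:
    n_input_barcodes: int = 0
    n_screened: int = 0
    n_on_target: int = 0
    n_after_collision: int = 0
    n_window_gated: int = 0
    n_final: int = 0


def run_filter(
    reads: list[BarcodedRead],
    placements: dict[str, tuple[int, int]],
    target: GenomicInterval,
    max_gap: int = 40_000,
    window: int = 160_000,
    min_window_reads: int = 10,
    bin_size: int = 10_000,
    max_coverage: float = 70.0,
) -> tuple[list[BarcodedRead], FilterReport]:
    """Full filtering pipeline; returns surviving reads and stage counts."""
    report = FilterReport(n_input_barcodes=len({r.barcode for r in reads}))
    kept, _rejected = extract_and_screen_barcodes(reads)
    report.n_screened = len({r.barcode for r in kept})
    barcode_of = {r.read_id: r.barcode for r in kept}
    mapped = {rid: pl for rid, pl in placements.items() if rid in barcode_of}
    profiles = build_profiles(mapped, barcode_of)
    on_target = select_on_target(profiles, target)
    report.n_on_target = len(on_target)
    # collision criterion applies to on-target placements
    on_target_profiles = {
        bc: BarcodeProfile(
            bc,
            [
                (pos, ln)
                for pos, ln in profiles[bc].mapped_reads
                if target.start <= pos < target.end
            ],
        )
        for bc in on_target
    }
    no_collision = remove_collisions(on_target_profiles, max_gap)
    report.n_after_collision = len(no_collision)
    gated_profiles = {bc: on_target_profiles[bc] for bc in no_collision}
    per_window = window_gate(gated_profiles, target, window, min_window_reads)
    report.n_window_gated = len(set().union(*per_window.values())) if per_window else 0
    final: set[str] = set()
    n_windows = max(1, -(-target.length // window))
    for w in range(n_windows):
        lo = target.start + w * window
        hi = min(lo + window, target.end)
        caps = density_cap(
            gated_profiles,
            per_window.get(w, set()),
            GenomicInterval(target.contig, lo, hi),
            bin_size,
            max_coverage,
        )
        for bc_set in caps.values():
            final |= bc_set
    report.n_final = len(final)
    return emit_filtered(kept, final), report
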