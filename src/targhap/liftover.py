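"""Coordinate liftover through one-to-one alignment blocks.

A :class:`CoordinateMap` holds non-overlapping alignment blocks between an
assembled haplotype (query) and the reference (target).  Positions inside
M segments map exactly; positions inside insertions are unmapped toward
the target and positions inside deletions unmapped toward the query, so
the map restricted to M segments is a bijection.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import AlignmentBlock, GenomicInterval


class MapError(ValueError):
    """Blocks overlap on one of the genomes — not a one-to-one map."""


def _check_disjoint(spans: list[tuple[str, int, int]], genome: str) -> None:
    spans = sorted(spans)
    for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
        if c1 == c2 and s2 < e1:
            raise MapError(
                f"blocks overlap on the {genome} genome: "
                f"{c1}:{s1}-{e1} vs {c2}:{s2}-{e2}"
            )


@dataclass(frozen=True)
class CoordinateMap:
    """Ordered one-to-one alignment blocks between two genomes."""

    blocks: tuple[AlignmentBlock, ...]

    def __post_init__(self) -> None:
        _check_disjoint(
            [(b.query_contig, b.query_start, b.query_end) for b in self.blocks],
            "query",
        )
        _check_disjoint(
            [(b.target_contig, b.target_start, b.target_end) for b in self.blocks],
            "target",
        )
        object.__setattr__(
            self,
            "blocks",
            tuple(sorted(self.blocks, key=lambda b: (b.target_contig, b.target_start))),
        )

    # -- position lift ------------------------------------------------------

    def lift(self, pos: int, direction: str, contig: Optional[str] = None
             ) -> Optional[int]:
        """Lift one position; ``direction`` is ``"query_to_target"`` or
        ``"target_to_query"``.  Returns None when unmapped."""
        if direction == "query_to_target":
            return self._lift(pos, contig, query_side=True)
        if direction == "target_to_query":
            return self._lift(pos, contig, query_side=False)
        raise ValueError(f"bad direction {direction!r}")

    def _lift(self, pos: int, contig: Optional[str], query_side: bool
              ) -> Optional[int]:
        for b in self.blocks:
            c = b.query_contig if query_side else b.target_contig
            s = b.query_start if query_side else b.target_start
            e = b.query_end if query_side else b.target_end
            if contig is not None and c != contig:
                continue
            if s <= pos < e:
                return _lift_in_block(b, pos, query_side)
        return None

    # -- interval lift ------------------------------------------------------

    def lift_interval(
        self, interval: GenomicInterval, direction: str, strict: bool = True
    ) -> Optional[GenomicInterval]:
        """Lift both endpoints.  In strict mode the endpoints must fall in
        the same block; endpoints are clipped to the enclosing block."""
        query_side = direction == "query_to_target"
        if direction not in ("query_to_target", "target_to_query"):
            raise ValueError(f"bad direction {direction!r}")
        block = None
        for b in self.blocks:
            c = b.query_contig if query_side else b.target_contig
            s = b.query_start if query_side else b.target_start
            e = b.query_end if query_side else b.target_end
            if c == interval.contig and s < interval.end and interval.start < e:
                if block is not None:
                    if strict:
                        return None  # endpoints span blocks
                    continue
                block = b
        if block is None:
            return None
        s = block.query_start if query_side else block.target_start
        e = block.query_end if query_side else block.target_end
        lo = max(interval.start, s)
        hi = min(interval.end, e)
        a = _lift_in_block(block, lo, query_side, snap=1)
        z = _lift_in_block(block, hi - 1, query_side, snap=-1)
        if a is None or z is None or z < a:
            return None
        out_contig = block.target_contig if query_side else block.query_contig
        return GenomicInterval(out_contig, a, z + 1)


def _lift_in_block(
    b: AlignmentBlock, pos: int, query_side: bool, snap: int = 0
) -> Optional[int]:
    """Walk segments; exact map inside M, None inside I/D (or snap to the
    nearest mapped base in the given direction when ``snap`` is +/-1)."""
    q, t = b.query_start, b.target_start
    if b.strand == "-":
        # walk target-forward while query runs backwards from query_end
        q = b.query_end
    last_mapped = None
    for op, ln in b.segments:
        if b.strand == "+":
            if op == "M":
                if query_side and q <= pos < q + ln:
                    return t + (pos - q)
                if not query_side and t <= pos < t + ln:
                    return q + (pos - t)
                last_mapped = (q + ln - 1, t + ln - 1)
                q += ln
                t += ln
            elif op == "I":
                if query_side and q <= pos < q + ln:
                    return _snap(snap, last_mapped, t, query_side)
                q += ln
            else:  # D
                if not query_side and t <= pos < t + ln:
                    return _snap(snap, last_mapped, q, not query_side)
                t += ln
        else:
            # '-' strand: target increases, query decreases
            if op == "M":
                if query_side and q - ln <= pos < q:
                    return t + (q - 1 - pos)
                if not query_side and t <= pos < t + ln:
                    return q - 1 - (pos - t)
                q -= ln
                t += ln
            elif op == "I":
                if query_side and q - ln <= pos < q:
                    return None
                q -= ln
            else:
                if not query_side and t <= pos < t + ln:
                    return None
                t += ln
    return None


def _snap(snap: int, last_mapped, upcoming: int, toward_target: bool
          ) -> Optional[int]:
    if snap == 0:
        return None
    if snap < 0:
        if last_mapped is None:
            return None
        return last_mapped[1] if toward_target else last_mapped[0]
    return upcoming


def build_map(blocks: Sequence[AlignmentBlock]) -> CoordinateMap:
    """Validate one-to-one-ness and construct a :class:`CoordinateMap`."""
    return CoordinateMap(tuple(blocks))


def slice_query(block: AlignmentBlock, qstart: int, qend: int,
                new_query_contig: Optional[str] = None) -> Optional[AlignmentBlock]:
    """Restrict a '+' strand block to query range [qstart, qend).

    Used to project a read placed on an assembled haplotype through the
    haplotype-to-reference alignment.  The returned block's query
    coordinates are renumbered to start at 0 (read coordinates).
    """
    if block.strand != "+":
        raise NotImplementedError("slice_query supports '+' strand blocks only")
    qstart = max(qstart, block.query_start)
    qend = min(qend, block.query_end)
    if qstart >= qend:
        return None
    q, t = block.query_start, block.target_start
    # (op, len, q_lo, t_lo) pieces clipped to the query range
    segs: list[tuple[str, int]] = []
    q_first = None  # hap-coordinate of the first kept aligned query base
    q_last = None
    t_lo = t_hi = None
    for op, ln in block.segments:
        if op == "M":
            lo, hi = max(q, qstart), min(q + ln, qend)
            if lo < hi:
                segs.append(("M", hi - lo))
                if q_first is None:
                    q_first = lo
                    t_lo = t + (lo - q)
                q_last = hi
                t_hi = t + (hi - q)
            q += ln
            t += ln
        elif op == "I":
            lo, hi = max(q, qstart), min(q + ln, qend)
            if lo < hi and q_first is not None:
                segs.append(("I", hi - lo))
                q_last = hi
            q += ln
        else:  # D
            if q_first is not None and qstart < q < qend:
                segs.append(("D", ln))
                t_hi = t + ln
            t += ln
    # an alignment cannot end in I/D: trim trailing non-M segments
    while segs and segs[-1][0] != "M":
        op, ln = segs.pop()
        if op == "D":
            t_hi -= ln
        else:
            q_last -= ln
    if not segs or q_first is None or t_lo is None:
        return None
    merged: list[tuple[str, int]] = []
    for op, ln in segs:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return AlignmentBlock(
        query_contig=new_query_contig or block.query_contig,
        query_start=q_first - qstart,  # read coordinates: read base 0 at qstart
        query_end=q_last - qstart,
        target_contig=block.target_contig,
        target_start=t_lo,
        target_end=t_hi,
        strand="+",
        segments=tuple(merged),
    )
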