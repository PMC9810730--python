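"""HLA typing by minimum edit distance against an allele database.

An assembled haplotype's gene region (extracted via liftover of the gene
interval) is compared to every allele of a user-supplied FASTA by global
(Needleman-Wunsch) Levenshtein distance with unit costs.  The minimum
distance and all tied best alleles are reported; a nonzero minimum flags
a putative novel allele.  Alignment is banded for speed (band from the
length difference) and falls back to full dynamic programming when the
band is exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib


@dataclass(frozen=True)
class HLACall:
    gene: str
    best_alleles: tuple[str, ...]
    edit_distance: int
    resolution_digits: int
    novel: bool
    untyped: bool = False


def edit_distance(a: str, b: str) -> int:
    """Global alignment Levenshtein distance, banded with fallback."""
    band = 2 * abs(len(a) - len(b)) + 50
    res = edlib.align(a, b, mode="NW", task="distance", k=band)
    if res["editDistance"] < 0:  # band exceeded
        res = edlib.align(a, b, mode="NW", task="distance")
    return res["editDistance"]


def resolution_of(allele_name: str) -> int:
    """Typing resolution in digits: 2 x the number of colon-separated
    fields after the ``gene*`` prefix (C*01:02:01:02 -> 8)."""
    name = allele_name.split("*", 1)[-1]
    return 2 * len(name.split(":"))


def type_allele(
    gene: str,
    assembly_region: str,
    allele_db: Sequence[tuple[str, str]],
) -> HLACall:
    """Type one gene region against the allele database.

    ``allele_db`` is (allele name, sequence) pairs, e.g. from a genomic
    allele FASTA.  An empty region (gene unmapped in the assembly) gives
    an explicit untyped result."""
    if not allele_db:
        raise ValueError("allele database is empty")
    if not assembly_region:
        return HLACall(gene, (), -1, 0, novel=False, untyped=True)
    best: list[str] = []
    best_d = None
    for name, seq in allele_db:
        d = edit_distance(assembly_region, seq)
        if best_d is None or d < best_d:
            best_d, best = d, [name]
        elif d == best_d:
            best.append(name)
    resolution = max(resolution_of(n) for n in best)
    return HLACall(
        gene,
        tuple(sorted(best)),
        int(best_d),
        resolution,
        novel=best_d > 0,
    )
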