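"""Allele-specific expression from haplotype-resolved read counts.

Gene models are lifted from the reference onto each personal haplotype;
uniquely aligned, duplicate-free reads are counted per gene per
haplotype; samples are normalized by DESeq2-style median-of-ratios size
factors; and allelic imbalance is tested per gene with a two-sided
exact binomial test on the summed normalized counts, with
Benjamini-Hochberg adjustment across tested genes (significant when the
adjusted p-value is below alpha).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval
from .liftover import CoordinateMap


@dataclass(frozen=True)
class AlleleCounts:
    gene: str
    replicate: int
    hap1_count: int
    hap2_count: int

    def __post_init__(self) -> None:
        if self.hap1_count < 0 or self.hap2_count < 0:
            raise ValueError("counts must be non-negative")


def lift_gene_models(
    genes: Sequence[tuple[str, GenomicInterval]],
    cmap: CoordinateMap,
) -> tuple[list[tuple[str, GenomicInterval]], list[str]]:
    """Lift gene intervals from the reference to one haplotype.

    Genes overlapping structural variants are flagged (and excluded from
    downstream testing): either endpoint unmapped makes the gene
    flagged, and when clipping to the enclosing alignment still yields
    an interval, the shortened interval is reported alongside the flag."""
    lifted: list[tuple[str, GenomicInterval]] = []
    flagged: list[str] = []
    for gene, iv in genes:
        exact = (
            cmap.lift(iv.start, "target_to_query") is not None
            and cmap.lift(iv.end - 1, "target_to_query") is not None
        )
        out = cmap.lift_interval(iv, "target_to_query", strict=True)
        if not exact or out is None or out.length != iv.length:
            flagged.append(gene)
        if out is not None:
            lifted.append((gene, out))
    return lifted, flagged


def count_allelic(
    read_genes: dict[str, str],
    read_haplotypes: dict[str, Optional[int]],
    replicate_of: dict[str, int],
    duplicates: Optional[set[str]] = None,
    multimapped: Optional[set[str]] = None,
) -> tuple[list[AlleleCounts], int]:
    """Aggregate haplotype-assigned reads into per-gene, per-replicate
    allele counts.

    A read counts iff uniquely aligned (not in ``multimapped``), not a
    duplicate, overlapping a lifted gene (present in ``read_genes``) and
    assigned to a haplotype; ambiguous reads (haplotype ``None``) are
    excluded and their number returned."""
    duplicates = duplicates or set()
    multimapped = multimapped or set()
    acc: dict[tuple[str, int], list[int]] = {}
    n_ambiguous = 0
    for rid, gene in read_genes.items():
        if rid in duplicates or rid in multimapped:
            continue
        hap = read_haplotypes.get(rid)
        if hap is None:
            n_ambiguous += 1
            continue
        key = (gene, replicate_of[rid])
        acc.setdefault(key, [0, 0])[hap - 1] += 1
    counts = [
        AlleleCounts(gene, rep, h[0], h[1]) for (gene, rep), h in sorted(acc.items())
    ]
    return counts, n_ambiguous


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """DESeq2 median-of-ratios size factors for a genes x samples count
    matrix.  Genes with any zero count are excluded from the median;
    raises when no gene survives."""
    counts = count_matrix.to_numpy(dtype=np.float64)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = counts[positive]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def counts_to_matrix(counts: Iterable[AlleleCounts]) -> pd.DataFrame:
    """Genes x samples matrix with one sample per (replicate, haplotype)
    — the DESeq2-ready layout."""
    records: dict[str, dict[str, int]] = {}
    for c in counts:
        row = records.setdefault(c.gene, {})
        row[f"rep{c.replicate}_hap1"] = c.hap1_count
        row[f"rep{c.replicate}_hap2"] = c.hap2_count
    df = pd.DataFrame.from_dict(records, orient="index").fillna(0).astype(np.int64)
    return df[sorted(df.columns)].sort_index()


def allelic_imbalance_test(
    counts: Iterable[AlleleCounts],
    factors: Optional[pd.Series] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided exact binomial test of H0: hap1 fraction 0.5
    on size-factor-normalized summed counts, with Benjamini-Hochberg
    adjustment; genes with zero total count are reported untested (NA)."""
    counts = list(counts)
    matrix = counts_to_matrix(counts)
    if factors is None:
        try:
            factors = size_factors(matrix)
        except ValueError:
            factors = pd.Series(1.0, index=matrix.columns)
    rows = []
    for gene in matrix.index:
        n1 = n2 = 0.0
        for col in matrix.columns:
            v = matrix.loc[gene, col] / factors[col]
            if col.endswith("hap1"):
                n1 += v
            else:
                n2 += v
        k1, k2 = int(round(n1)), int(round(n2))
        total = k1 + k2
        if total == 0:
            rows.append((gene, k1, k2, np.nan, np.nan))
            continue
        p = stats.binomtest(k1, total, 0.5, alternative="two-sided").pvalue
        est = k1 / total
        rows.append((gene, k1, k2, est, p))
    df = pd.DataFrame(
        rows, columns=["gene", "hap1_norm", "hap2_norm", "hap1_fraction", "pvalue"]
    ).set_index("gene")
    tested = df["pvalue"].notna()
    padj = pd.Series(np.nan, index=df.index)
    if tested.any():
        padj[tested] = multipletests(df.loc[tested, "pvalue"], method="fdr_bh")[1]
    df["padj"] = padj
    df["significant"] = df["padj"] < alpha
    return df
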