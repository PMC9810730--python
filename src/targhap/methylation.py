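"""Haplotype-aware CpG accounting and differential methylation.

CpG sites are classified across the two personal haplotypes and the
reference (shared / haplotype-specific / reference-only) by lifting each
site through the haplotype-to-reference coordinate maps.  Methylation is
quantified per haplotype as M/(M+U); bead-array values use the
beta = M/(M+U+100) convention and are compared to sequencing levels
stratified by the presence of a genetic variant within 5 bp of the
interrogated CpG.  Allele-specific methylation is called on smoothed
levels (tricube-weighted, coverage-weighted local means over windows of
at least 50 CpGs and at least 800 bp) with a per-site t-statistic; DMRs
are maximal same-sign runs with |t| > 3.6, at least 3 CpGs, and a raw
methylation difference of at least 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CpGSite, GenomicInterval, MethylationEvidence, PhasedVariant
from .liftover import CoordinateMap


@dataclass(frozen=True)
class SmoothingParams:
    """bsseq-style smoothing window rule: at least ``ns`` CpGs and at
    least ``h`` bp, whichever is larger; sites separated by more than
    ``max_gap`` never share a window."""

    ns: int = 50
    h: float = 800.0
    max_gap: float = 1e8


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    n_cpgs: int
    mean_diff: float          # hap2 - hap1, raw levels
    direction: str            # "hyper_hap2" | "hyper_hap1"
    max_abs_t: float


# ---------------------------------------------------------------------------
# CpG discovery and classification

def find_cpgs(sequence: str) -> list[int]:
    """All positions i with sequence[i:i+2] == 'CG'."""
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G")).tolist()


def percent(count: int, total: int, decimals: int = 2) -> str:
    """Fraction as a percentage string, rounded half-up (1355/57010 ->
    '2.38')."""
    if total == 0:
        return "nan"
    q = Decimal(count) / Decimal(total) * 100
    exp = Decimal(10) ** -decimals
    return str(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class CpGClassification:
    hap1_sites: list[CpGSite]
    hap2_sites: list[CpGSite]
    reference_sites: list[CpGSite]
    n_unmapped: int = 0

    def _count(self, sites: list[CpGSite], cls: str) -> int:
        return sum(1 for s in sites if s.cpg_class == cls)

    @property
    def n_hap1_specific(self) -> int:
        return self._count(self.hap1_sites, "hap1_specific")

    @property
    def n_hap2_specific(self) -> int:
        return self._count(self.hap2_sites, "hap2_specific")

    @property
    def n_reference_only(self) -> int:
        return self._count(self.reference_sites, "reference_only")

    def summary(self) -> dict[str, str]:
        """Reported fractions, rounded half-up to 2 decimals."""
        return {
            "hap1_specific_pct": percent(self.n_hap1_specific, len(self.hap1_sites)),
            "hap2_specific_pct": percent(self.n_hap2_specific, len(self.hap2_sites)),
            "reference_only_pct": percent(
                self.n_reference_only, len(self.reference_sites)
            ),
        }


def classify_cpgs(
    hap1: str,
    hap2: str,
    reference: str,
    map1: CoordinateMap,
    map2: CoordinateMap,
) -> CpGClassification:
    """Classify every CpG of each haplotype as shared or haplotype-
    specific, and every reference CpG as present-in-a-haplotype or
    reference-only, by liftover through the reference.

    A site whose position is unmapped (inside a structural variant) is
    classified by absence and counted in ``n_unmapped``."""
    haps = {1: hap1, 2: hap2}
    cpgs = {h: find_cpgs(s) for h, s in haps.items()}
    ref_cpgs = find_cpgs(reference)
    maps = {1: map1, 2: map2}
    unmapped = 0

    def has_cg(seq: str, pos: Optional[int]) -> bool:
        return pos is not None and seq[pos : pos + 2] == "CG"

    out: dict[int, list[CpGSite]] = {1: [], 2: []}
    for h in (1, 2):
        other = 2 if h == 1 else 1
        for p in cpgs[h]:
            r = maps[h].lift(p, "query_to_target")
            if r is None:
                unmapped += 1
                q = None
            else:
                q = maps[other].lift(r, "target_to_query")
                if q is None:
                    unmapped += 1
            shared = has_cg(haps[other], q)
            out[h].append(
                CpGSite(f"hap{h}", p, "shared" if shared else f"hap{h}_specific")
            )
    ref_sites: list[CpGSite] = []
    for p in ref_cpgs:
        present = False
        for h in (1, 2):
            q = maps[h].lift(p, "target_to_query")
            present = present or has_cg(haps[h], q)
        ref_sites.append(
            CpGSite("ref", p, "shared" if present else "reference_only")
        )
    return CpGClassification(out[1], out[2], ref_sites, unmapped)


# ---------------------------------------------------------------------------
# quantification

def methylation_levels(evidence: Iterable[MethylationEvidence]) -> pd.DataFrame:
    """Tidy per-site per-replicate levels; zero-coverage sites are
    missing (NaN), never 0."""
    rows = [
        (e.genome, e.position, e.replicate, e.methylated, e.unmethylated, e.level)
        for e in evidence
    ]
    return pd.DataFrame(
        rows, columns=["genome", "position", "replicate", "M", "U", "level"]
    )


def epic_beta(m_intensity: float, u_intensity: float) -> float:
    """Bead-array beta value M/(M+U+100) in [0, 1)."""
    if m_intensity < 0 or u_intensity < 0:
        raise ValueError("intensities must be non-negative")
    return m_intensity / (m_intensity + u_intensity + 100.0)


def probe_stratified_correlation(
    array_betas: dict[int, float],
    sequencing_levels: dict[int, float],
    variant_positions: Iterable[int],
    probe_window: int = 5,
) -> dict[str, Optional[float]]:
    """R-squared between array and sequencing methylation, with shared
    CpGs split by whether a genetic variant lies within ``probe_window``
    bp of the interrogated site.  Degenerate strata report None."""
    variants = np.array(sorted(set(variant_positions)), dtype=np.int64)
    shared = sorted(set(array_betas) & set(sequencing_levels))

    def has_nearby_snp(p: int) -> bool:
        if variants.size == 0:
            return False
        i = np.searchsorted(variants, p)
        for j in (i - 1, i):
            if 0 <= j < variants.size and abs(int(variants[j]) - p) <= probe_window:
                return True
        return False

    strata = {"with_snp": [], "without_snp": []}
    for p in shared:
        key = "with_snp" if has_nearby_snp(p) else "without_snp"
        strata[key].append((array_betas[p], sequencing_levels[p]))
    out: dict[str, Optional[float]] = {}
    for key, pairs in strata.items():
        if len(pairs) < 2:
            out[key] = None
            continue
        x, y = np.array(pairs).T
        if np.std(x) == 0 or np.std(y) == 0:
            out[key] = None
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[key] = float(r * r)
    return out


# ---------------------------------------------------------------------------
# site table for ASM

def build_site_table(
    evidence: Iterable[MethylationEvidence],
    map1: CoordinateMap,
    map2: CoordinateMap,
    classification: Optional[CpGClassification] = None,
) -> pd.DataFrame:
    """Union table of CpG sites on reference coordinates.

    Index: reference position.  Columns: MultiIndex (kind in {M, U},
    hap, replicate).  Sites whose haplotype position does not lift to
    the reference (inside insertions) are dropped.  A ``cpg_class``
    column is attached when a classification is given."""
    maps = {1: map1, 2: map2}
    records: dict[tuple, dict] = {}
    for e in evidence:
        h = 1 if e.genome.endswith("1") else 2
        r = maps[h].lift(e.position, "query_to_target")
        if r is None:
            continue
        rec = records.setdefault(r, {})
        rec[("M", h, e.replicate)] = e.methylated
        rec[("U", h, e.replicate)] = e.unmethylated
    table = pd.DataFrame.from_dict(records, orient="index").sort_index()
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["kind", "hap", "rep"])
    table = table.fillna(0).astype(np.int64)
    if classification is not None:
        class_by_ref: dict[int, str] = {}
        for h, sites in ((1, classification.hap1_sites), (2, classification.hap2_sites)):
            for s in sites:
                r = maps[h].lift(s.position, "query_to_target")
                if r is None:
                    continue
                prev = class_by_ref.get(r)
                if prev is None or prev == "shared":
                    class_by_ref[r] = s.cpg_class
        table["cpg_class"] = [class_by_ref.get(p, "n/a") for p in table.index]
    return table


def filter_cpgs_for_dmr(table: pd.DataFrame, mode: str = "shared_only") -> pd.DataFrame:
    """Site filter ahead of DMR calling.

    ``shared_only``: haplotype-specific CpGs removed and only sites with
    nonzero coverage in at least 2 replicates in EACH haplotype group
    kept.  ``with_specific``: no coverage filter, specific CpGs kept."""
    if mode == "with_specific":
        return table
    if mode != "shared_only":
        raise ValueError("mode must be 'shared_only' or 'with_specific'")
    keep = pd.Series(True, index=table.index)
    if "cpg_class" in table.columns:
        keep &= table["cpg_class"] == "shared"
    for h in (1, 2):
        cov = table["M"][h] + table["U"][h]
        keep &= (cov > 0).sum(axis=1) >= 2
    return table[keep]


# ---------------------------------------------------------------------------
# smoothing

def _tricube(x: np.ndarray) -> np.ndarray:
    w = (1 - np.abs(x) ** 3) ** 3
    w[np.abs(x) >= 1] = 0.0
    return w


def smooth_levels(
    positions: np.ndarray,
    levels: np.ndarray,
    coverages: np.ndarray,
    params: SmoothingParams = SmoothingParams(),
) -> np.ndarray:
    """Tricube-distance-weighted, coverage-weighted local mean of one
    replicate's levels at each site.

    The window at each site is the smallest symmetric neighborhood
    containing at least ``ns`` CpGs AND spanning at least ``h`` bp;
    sites separated by more than ``max_gap`` never share a window.
    Uncovered sites (NaN level / zero coverage) contribute no weight but
    still receive a smoothed value from their neighbors."""
    positions = np.asarray(positions, dtype=np.float64)
    levels = np.asarray(levels, dtype=np.float64)
    coverages = np.asarray(coverages, dtype=np.float64)
    n = len(positions)
    out = np.full(n, np.nan)
    if n == 0:
        return out
    # clusters split at gaps > max_gap
    gaps = np.diff(positions)
    cluster_bounds = [0] + (np.flatnonzero(gaps > params.max_gap) + 1).tolist() + [n]
    for a, b in zip(cluster_bounds, cluster_bounds[1:]):
        pos = positions[a:b]
        lvl = levels[a:b]
        cov = coverages[a:b]
        m = b - a
        for i in range(m):
            p = pos[i]
            radius = params.h / 2
            if m > 1:
                lo = max(0, i - params.ns + 1)
                hi = min(m, i + params.ns)
                dists = np.sort(np.abs(pos[lo:hi] - p))
                k = min(params.ns, len(dists)) - 1
                radius = max(radius, dists[k])
            in_win = np.abs(pos - p) <= radius
            w = _tricube((pos[in_win] - p) / (radius + 1.0)) * cov[in_win]
            vals = lvl[in_win]
            ok = np.isfinite(vals) & (w > 0)
            if ok.any():
                out[a + i] = float(np.sum(w[ok] * vals[ok]) / np.sum(w[ok]))
    return out


# ---------------------------------------------------------------------------
# DMR calling

def dmr_call(
    positions: np.ndarray,
    smoothed_hap1: np.ndarray,
    smoothed_hap2: np.ndarray,
    raw_diff: np.ndarray,
    t_threshold: float = 3.6,
    min_cpgs: int = 3,
    min_diff: float = 0.10,
    var_floor: float = 1e-4,
) -> list[DMR]:
    """Call DMRs from smoothed per-replicate levels.

    ``smoothed_hapX`` are (n_sites x n_replicates) arrays; ``raw_diff``
    the per-site raw mean level difference (hap2 - hap1).  The per-site
    t statistic is (mean2 - mean1)/SE with SE from the pooled replicate
    variance of smoothed values (variance floored at ``var_floor``).
    Candidates are maximal runs of consecutive sites with |t| above the
    threshold and constant sign; runs with at least ``min_cpgs`` sites
    and an absolute mean raw difference of at least ``min_diff`` are
    returned."""
    s1 = np.asarray(smoothed_hap1, dtype=np.float64)
    s2 = np.asarray(smoothed_hap2, dtype=np.float64)
    if s1.ndim != 2 or s2.ndim != 2 or s1.shape[1] < 2 or s2.shape[1] < 2:
        raise ValueError("need >= 2 replicates per haplotype group")
    n1, n2 = s1.shape[1], s2.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(s1, axis=1), np.nanmean(s2, axis=1)
        v1 = np.nanvar(s1, axis=1, ddof=1)
        v2 = np.nanvar(s2, axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    pooled = np.maximum(pooled, var_floor)
    se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    with np.errstate(invalid="ignore"):
        t = (m2 - m1) / se
    sign = np.sign(t)
    above = np.abs(t) > t_threshold
    dmrs: list[DMR] = []
    i, n = 0, len(t)
    while i < n:
        if not above[i] or not np.isfinite(t[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        run = slice(i, j + 1)
        n_sites = j - i + 1
        diff = float(np.nanmean(raw_diff[run]))
        if n_sites >= min_cpgs and np.isfinite(diff) and abs(diff) >= min_diff:
            dmrs.append(
                DMR(
                    interval=GenomicInterval(
                        "ref", int(positions[i]), int(positions[j]) + 2
                    ),
                    n_cpgs=n_sites,
                    mean_diff=diff,
                    direction="hyper_hap2" if diff > 0 else "hyper_hap1",
                    max_abs_t=float(np.nanmax(np.abs(t[run]))),
                )
            )
        i = j + 1
    return dmrs


def call_dmrs_from_table(
    table: pd.DataFrame,
    params: SmoothingParams = SmoothingParams(),
    t_threshold: float = 3.6,
    min_cpgs: int = 3,
    min_diff: float = 0.10,
) -> list[DMR]:
    """Smooth each (haplotype, replicate) track of a site table and call
    DMRs — the full ASM pipeline after site filtering."""
    positions = table.index.to_numpy(dtype=np.int64)
    smoothed = {1: [], 2: []}
    raw = {1: [], 2: []}
    for h in (1, 2):
        reps = sorted(table["M"][h].columns)
        for r in reps:
            m = table[("M", h, r)].to_numpy(dtype=np.float64)
            u = table[("U", h, r)].to_numpy(dtype=np.float64)
            cov = m + u
            with np.errstate(invalid="ignore", divide="ignore"):
                lvl = np.where(cov > 0, m / np.where(cov > 0, cov, 1), np.nan)
            smoothed[h].append(smooth_levels(positions, lvl, cov, params))
            raw[h].append(lvl)
    s1 = np.column_stack(smoothed[1])
    s2 = np.column_stack(smoothed[2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw_diff = np.nanmean(np.column_stack(raw[2]), axis=1) - np.nanmean(
            np.column_stack(raw[1]), axis=1
        )
    return dmr_call(
        positions, s1, s2, raw_diff,
        t_threshold=t_threshold, min_cpgs=min_cpgs, min_diff=min_diff,
    )


# ---------------------------------------------------------------------------
# haplotype-aware quantification report

def haplotype_aware_quantify(
    evidence: Iterable[MethylationEvidence],
    classification: CpGClassification,
) -> pd.DataFrame:
    """Mean methylation per haplotype per CpG class (shared vs that
    haplotype's specific sites), from evidence computed against each
    personal haplotype reference."""
    class_by_site = {
        (f"hap{h}", s.position): s.cpg_class
        for h, sites in ((1, classification.hap1_sites), (2, classification.hap2_sites))
        for s in sites
    }
    acc: dict[tuple[str, str], list[float]] = {}
    pooled: dict[tuple[str, int], list[int]] = {}
    for e in evidence:
        pooled.setdefault((e.genome, e.position), [0, 0])
        pooled[(e.genome, e.position)][0] += e.methylated
        pooled[(e.genome, e.position)][1] += e.unmethylated
    for (genome, pos), (m, u) in pooled.items():
        if m + u == 0:
            continue
        cls = class_by_site.get((genome, pos), "n/a")
        acc.setdefault((genome, cls), []).append(m / (m + u))
    rows = [
        (genome, cls, len(vals), float(np.mean(vals)))
        for (genome, cls), vals in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["haplotype", "cpg_class", "n_sites", "mean_level"])
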