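"""Assembly evaluation: variant derivation, phasing errors, contiguity,
collapsed repeats, window densities."""

import itertools
import random

import numpy as np

from targhap.core import AlignmentBlock, GenomicInterval, PhasedVariant
from targhap.evaluate import (
    benchmark_compare,
    collapsed_regions,
    contiguity,
    count_switches,
    coverage_from_placements,
    derive_phased_variants,
    phasing_errors,
    window_density,
)


def _full_block(qc, n, tc="ref"):
    return AlignmentBlock(qc, 0, n, tc, 0, n, "+", (("M", n),))


class TestDeriveVariants:
    def test_identical_haplotypes_empty(self):
        ref = "ACGT" * 5000
        blocks = [_full_block("h", len(ref))]
        diploid, half = derive_phased_variants(
            [blocks[0]], [blocks[0]], {"h": ref}, {"h": ref}, ref
        )
        assert diploid == [] and half == []

    def test_single_snv_hand_trace(self):
        ref = "A" * 20_000
        hap2 = ref[:3] + "G" + ref[4:]
        b = _full_block("h", len(ref))
        diploid, _ = derive_phased_variants(
            [b], [b], {"h": ref}, {"h": hap2}, ref
        )
        assert diploid == [PhasedVariant("ref", 3, "A", "G", "0|1")]

    def test_short_blocks_excluded(self):
        ref = "A" * 5_000
        hap2 = ref[:3] + "G" + ref[4:]
        b = _full_block("h", len(ref))
        diploid, _ = derive_phased_variants(
            [b], [b], {"h": ref}, {"h": hap2}, ref, min_block=10_000
        )
        assert diploid == []

    def test_half_call_on_single_coverage(self):
        ref = "A" * 30_000
        hap1 = ref
        hap2 = ref[:15_003] + "G" + ref[15_004:]
        b1 = AlignmentBlock("h1", 0, 15_000, "ref", 0, 15_000, "+", (("M", 15_000),))
        b2 = _full_block("h2", len(ref))
        diploid, half = derive_phased_variants(
            [b1], [b2], {"h1": hap1}, {"h2": hap2}, ref
        )
        assert diploid == []
        assert half == [PhasedVariant("ref", 15_003, "A", "G", ".|1")]


def _bruteforce_rates(test_bits, truth_bits):
    """Reference implementation on one phase block."""
    n = len(test_bits)
    d = [a ^ b for a, b in zip(test_bits, truth_bits)]
    switches = sum(1 for a, b in zip(d, d[1:]) if a != b)
    switch_rate = switches / (n - 1) if n > 1 else 0.0
    ham = min(sum(d), n - sum(d)) / n
    return switch_rate, ham


def _variants_from_bits(bits, block=None):
    return [
        PhasedVariant("ref", 10 * (i + 1), "A", "G",
                      "1|0" if b else "0|1", phase_block=block)
        for i, b in enumerate(bits)
    ]


class TestPhasingErrors:
    def test_hand_example(self):
        truth = _variants_from_bits([0, 0, 0])
        test = _variants_from_bits([0, 1, 0])
        switch, ham = phasing_errors(test, truth)
        assert switch == 1.0
        assert abs(ham - 1 / 3) < 1e-12

    def test_global_flip_invariance(self):
        truth = _variants_from_bits([0, 1, 1, 0, 1])
        test = _variants_from_bits([1, 0, 0, 1, 0])
        assert phasing_errors(test, truth) == (0.0, 0.0)

    def test_exhaustive_bruteforce_small(self):
        for n in range(2, 9):
            for test_bits in itertools.product([0, 1], repeat=n):
                truth_bits = tuple((i * 7 + 3) % 2 for i in range(n))
                got = phasing_errors(
                    _variants_from_bits(test_bits),
                    _variants_from_bits(truth_bits),
                )
                want = _bruteforce_rates(test_bits, truth_bits)
                assert got == want, (test_bits, truth_bits)

    def test_random_bruteforce_len12(self):
        rng = random.Random(5)
        for _ in range(200):
            test_bits = [rng.randint(0, 1) for _ in range(12)]
            truth_bits = [rng.randint(0, 1) for _ in range(12)]
            got = phasing_errors(
                _variants_from_bits(test_bits), _variants_from_bits(truth_bits)
            )
            assert got == _bruteforce_rates(test_bits, truth_bits)

    def test_blocks_aggregated_by_het_count(self):
        truth = _variants_from_bits([0, 0], block="b1") + [
            v.with_genotype(v.genotype, "b2")
            for v in _variants_from_bits([0, 0, 0, 0])[2:]
        ]
        # mismatched ham in one block only
        test = _variants_from_bits([0, 1], block="b1") + [
            v.with_genotype(v.genotype, "b2")
            for v in _variants_from_bits([0, 0, 0, 0])[2:]
        ]
        _, ham = phasing_errors(test, truth)
        assert abs(ham - 1 / 4) < 1e-12

    def test_count_switches(self):
        truth = _variants_from_bits([0, 0, 0, 0])
        test = _variants_from_bits([0, 0, 1, 1])
        assert count_switches(test, truth) == 1


class TestBenchmarkCompare:
    def _vs(self, positions, alt="G"):
        return [
            PhasedVariant("ref", p, "A", alt, "0|1") for p in positions
        ]

    def test_identical(self):
        vs = self._vs(range(10, 110, 10))
        res = benchmark_compare(vs, vs)
        assert res.fnr == 0.0 and res.fdr == 0.0

    def test_counting(self):
        bench = self._vs(range(10, 110, 10))
        calls = bench[:8] + self._vs([500, 600], alt="C")
        res = benchmark_compare(calls, bench)
        assert res.fnr == 0.2 and res.fdr == 0.2

    def test_bed_restriction(self):
        bench = self._vs(range(10, 110, 10))
        res = benchmark_compare(
            bench, bench, confident_regions=[GenomicInterval("ref", 0, 55)]
        )
        assert res.n_benchmark == 5 and res.fnr == 0.0

    def test_genotype_discordance_reported(self):
        bench = [PhasedVariant("ref", 10, "A", "G", "1|1")]
        calls = [PhasedVariant("ref", 10, "A", "G", "0|1")]
        res = benchmark_compare(calls, bench)
        assert res.n_matched == 1
        assert res.n_genotype_discordant == 1


class TestContiguity:
    def _blocks(self, lengths):
        out = []
        offset = 0
        for i, ln in enumerate(lengths):
            out.append(
                AlignmentBlock(
                    f"c{i}", 0, ln, "ref", offset, offset + ln, "+", (("M", ln),)
                )
            )
            offset += ln
        return out

    def test_hand_trace(self):
        stats = contiguity(
            self._blocks([40_000, 35_000, 15_000, 5_000]),
            GenomicInterval("ref", 0, 100_000),
        )
        assert stats.nga50 == 35_000 and stats.lga50 == 2

    def test_single_full_block(self):
        stats = contiguity(
            self._blocks([100_000]), GenomicInterval("ref", 0, 100_000)
        )
        assert stats.nga50 == 100_000 and stats.lga50 == 1
        assert stats.fraction_of_target == 1.0

    def test_random_vs_bruteforce(self):
        rng = random.Random(17)
        for _ in range(50):
            lengths = [rng.randint(1_000, 50_000) for _ in range(rng.randint(1, 8))]
            target = GenomicInterval("ref", 0, sum(lengths) + rng.randint(0, 10_000))
            stats = contiguity(self._blocks(lengths), target)
            desc = sorted(lengths, reverse=True)
            acc, nga, lga = 0, None, None
            for i, ln in enumerate(desc, 1):
                acc += ln
                if acc >= target.length / 2:
                    nga, lga = ln, i
                    break
            assert (stats.nga50, stats.lga50) == (nga, lga)


class TestCollapsed:
    def test_uniform_no_detection(self):
        cov = np.full(50_000, 30.0)
        regions, total = collapsed_regions(cov, cov)
        assert regions == [] and total == 0

    def test_planted_excess_detected(self):
        rng = np.random.default_rng(3)
        control = rng.poisson(30, 100_000).astype(float)
        cov = rng.poisson(30, 100_000).astype(float)
        cov[40_000:65_000] += 30
        regions, total = collapsed_regions(cov, control)
        assert len(regions) == 1
        r = regions[0].interval
        assert abs(r.start - 40_000) <= 10_000
        assert abs(r.end - 65_000) <= 10_000

    def test_coverage_from_placements(self):
        cov = coverage_from_placements([(0, 10), (5, 15)], 20)
        assert cov[0] == 1 and cov[7] == 2 and cov[12] == 1 and cov[16] == 0


class TestWindowDensity:
    def test_boundary_and_conservation(self):
        region = GenomicInterval("ref", 0, 30_000)
        positions = [0, 9_999, 10_000, 25_000]
        counts = window_density(positions, region)
        assert counts.tolist() == [2, 1, 1]
        assert counts.sum() == len(positions)

    def test_empty(self):
        counts = window_density([], GenomicInterval("ref", 0, 30_000))
        assert counts.sum() == 0
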