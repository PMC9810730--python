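"""HiFi preparation and haplotype partitioning."""

import pytest

from targhap.core import AlignmentBlock, GenomicInterval, PhasedVariant
from targhap.hifi import (
    ReliableHetSet,
    attach_phase,
    downsample_to_coverage,
    haplotag_reads,
    intersect_hets,
    mark_duplicates,
    partition_reads,
    read_base_at,
    recruit_reads,
    rescue_supplementary,
)
from targhap.simulate import HiFiConfig, simulate_hifi


def _aln(rid_contig, ts, length, strand="+"):
    return AlignmentBlock(
        rid_contig, 0, length, "ref", ts, ts + length, strand, (("M", length),)
    )


class TestMarkDuplicates:
    def test_identical_reads(self):
        seqs = {"a": "ACGT" * 100, "b": "ACGT" * 100}
        alns = {"a": _aln("a", 0, 400), "b": _aln("b", 0, 400)}
        primary, dups = mark_duplicates(seqs, alns)
        assert primary == {"a"} and dups == {"b"}

    def test_one_mismatch_in_long_read_is_duplicate(self):
        s = "A" * 10_000
        seqs = {"a": s, "b": s[:5000] + "C" + s[5001:]}
        alns = {"a": _aln("a", 0, 10_000), "b": _aln("b", 0, 10_000)}
        _, dups = mark_duplicates(seqs, alns)
        assert dups == {"b"}

    def test_different_placement_not_duplicate(self):
        seqs = {"a": "ACGT" * 100, "b": "ACGT" * 100}
        alns = {"a": _aln("a", 0, 400), "b": _aln("b", 10, 400)}
        _, dups = mark_duplicates(seqs, alns)
        assert dups == set()

    def test_planted_duplicates_recovered(self, truth_small):
        sim = simulate_hifi(
            truth_small, HiFiConfig(coverage=10, duplicate_fraction=0.1)
        )
        planted = {r.read_id for r in sim.reads if r.read_id.endswith("_dup")}
        assert planted
        _, flagged = mark_duplicates(sim.sequences, sim.ref_alignments)
        # a duplicate group flags all but one member; either the copy or
        # its original may be retained
        caught = sum(
            1
            for d in planted
            if d in flagged or d[: -len("_dup")] in flagged
        )
        assert caught / len(planted) >= 0.95


class TestRecruit:
    def test_overlap_rules(self):
        target = GenomicInterval("ref", 1000, 2000)
        alns = {
            "inside": _aln("inside", 1200, 100),
            "touch_end": _aln("touch_end", 900, 100),   # ends at 1000: no
            "one_bp": _aln("one_bp", 999, 2),           # overlaps [999,1001)
            "outside": _aln("outside", 5000, 100),
        }
        assert recruit_reads(alns, target) == {"inside", "one_bp"}

    def test_matches_bruteforce(self, truth_small):
        sim = simulate_hifi(truth_small, HiFiConfig(coverage=5))
        target = GenomicInterval("ref", 20_000, 30_000)
        got = recruit_reads(sim.ref_alignments, target)
        expected = {
            rid
            for rid, b in sim.ref_alignments.items()
            if b.target_start < 30_000 and b.target_end > 20_000
        }
        assert got == expected


class TestDownsample:
    def test_rule_trace(self):
        lengths = {"a": 12_000, "b": 9_000, "c": 8_000}
        starts = {"a": 0, "b": 10, "c": 20}
        kept = downsample_to_coverage(lengths, starts, target_cov=2.0)
        assert kept == {"a"}

    def test_under_target_unchanged(self):
        lengths = {"a": 5_000, "b": 5_000}
        starts = {"a": 0, "b": 10}
        kept = downsample_to_coverage(lengths, starts, target_cov=2.0)
        assert kept == {"a", "b"}

    def test_cap_and_shortest_property(self, truth_small):
        sim = simulate_hifi(truth_small, HiFiConfig(coverage=100))
        lengths = {r: len(s) for r, s in sim.sequences.items()}
        starts = {r: b.target_start for r, b in sim.ref_alignments.items()}
        kept = downsample_to_coverage(lengths, starts, target_cov=60.0)
        removed = set(lengths) - kept
        bins = {}
        for rid in lengths:
            bins.setdefault(starts[rid] // 10_000, []).append(rid)
        for b, ids in bins.items():
            total = sum(lengths[r] for r in ids if r in kept)
            assert total <= 60.0 * 10_000 or len([r for r in ids if r in kept]) == 0
            # removed reads are each bin's shortest
            kept_in_bin = [lengths[r] for r in ids if r in kept]
            removed_in_bin = [lengths[r] for r in ids if r in removed]
            if removed_in_bin and kept_in_bin:
                assert max(removed_in_bin) <= min(kept_in_bin)


class TestReliableHets:
    V1 = PhasedVariant("ref", 10, "A", "G", "0/1")
    V2 = PhasedVariant("ref", 20, "C", "T", "0/1")
    V3 = PhasedVariant("ref", 30, "G", "A", "1/1")

    def test_intersection(self):
        out = intersect_hets([self.V1, self.V2, self.V3], [self.V1, self.V3])
        assert [v.key for v in out] == [self.V1.key]

    def test_different_alt_excluded(self):
        other = PhasedVariant("ref", 10, "A", "C", "0/1")
        assert intersect_hets([self.V1], [other]) == []

    def test_attach_phase_copies_orientation(self):
        phased = [PhasedVariant("ref", 10, "A", "G", "1|0", phase_block="ps7")]
        out = attach_phase([self.V1, self.V2], phased)
        assert len(out.variants) == 1
        assert out.variants[0].genotype == "1|0"
        assert out.variants[0].phase_block == "ps7"
        assert out.n_dropped_unphased == 1

    def test_reliable_set_rejects_unphased(self):
        with pytest.raises(ValueError):
            ReliableHetSet([self.V1], provenance={})


class TestHaplotag:
    def _hets(self):
        return ReliableHetSet(
            [
                PhasedVariant("ref", 100, "A", "G", "1|0"),
                PhasedVariant("ref", 200, "C", "T", "1|0"),
                PhasedVariant("ref", 300, "G", "A", "0|1"),
            ],
            provenance={},
        )

    def test_majority_rule(self):
        # read carries hap1 alleles at 100 and 200, hap2 allele at 300
        seq = ["A"] * 400
        seq[100], seq[200], seq[300] = "G", "T", "A"
        reads = {"r": "".join(seq)}
        alns = {"r": _aln("r", 0, 400)}
        (t,) = haplotag_reads(reads, alns, self._hets())
        assert t.haplotype_tag == "H1"
        assert (t.n_support_h1, t.n_support_h2) == (2, 1)

    def test_no_informative_sites_untagged(self):
        reads = {"r": "A" * 50}
        alns = {"r": _aln("r", 1000, 50)}
        (t,) = haplotag_reads(reads, alns, self._hets())
        assert t.haplotype_tag == "untagged"

    def test_unaligned_read_untagged(self):
        (t,) = haplotag_reads({"r": "ACGT"}, {}, self._hets())
        assert t.haplotype_tag == "untagged"

    def test_deletion_spanning_het_uninformative(self):
        # read deletes reference [150,250) where the 200 het lives
        block = AlignmentBlock(
            "r", 0, 300, "ref", 0, 400, "+",
            (("M", 150), ("D", 100), ("M", 150)),
        )
        assert read_base_at(block, "A" * 300, 200) is None


class TestPartition:
    def test_untagged_in_both(self):
        from targhap.core import TaggedRead

        tagged = [
            TaggedRead("a", "H1", 100),
            TaggedRead("b", "H2", 100),
            TaggedRead("c", "untagged", 100),
        ]
        h1, h2 = partition_reads(tagged)
        assert h1 == {"a", "c"} and h2 == {"b", "c"}
        assert len(h1) + len(h2) == 1 + 1 + 2


class TestRescue:
    def test_rescued_disjoint_from_recruited(self):
        alns = {"a": [_aln("a", 0, 100)], "b": [_aln("b", 0, 100)], "c": []}
        out = rescue_supplementary(alns, initially_recruited={"a"})
        assert out == {"b"}
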