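"""CpG classification, quantification, smoothing and DMR calling."""

import numpy as np
import pandas as pd
import pytest

from targhap.core import AlignmentBlock, MethylationEvidence
from targhap.liftover import build_map
from targhap.methylation import (
    SmoothingParams,
    build_site_table,
    classify_cpgs,
    dmr_call,
    epic_beta,
    filter_cpgs_for_dmr,
    find_cpgs,
    methylation_levels,
    percent,
    probe_stratified_correlation,
    smooth_levels,
)


def _identity_map(name, n):
    return build_map(
        [AlignmentBlock(name, 0, n, "ref", 0, n, "+", (("M", n),))]
    )


class TestFindCpgs:
    def test_examples(self):
        assert find_cpgs("CGCG") == [0, 2]
        assert find_cpgs("CCGG") == [1]
        assert find_cpgs("AAAA") == []

    def test_matches_regex_oracle(self, truth_small):
        import re

        seq = truth_small.reference[:5000]
        assert find_cpgs(seq) == [m.start() for m in re.finditer("CG", seq)]


class TestPercent:
    def test_paper_style_rounding(self):
        assert percent(1355, 57010) == "2.38"
        assert percent(1191, 55659) == "2.14"
        assert percent(2291, 58570) == "3.91"

    def test_half_up(self):
        assert percent(25, 1000) == "2.50"
        assert percent(1, 16000) == "0.01"  # 0.00625 -> 0.01


class TestClassify:
    def test_identical_genomes_all_shared(self):
        seq = "AACGTTACGTT" * 40
        n = len(seq)
        cls = classify_cpgs(
            seq, seq, seq, _identity_map("hap1", n), _identity_map("hap2", n)
        )
        assert cls.n_hap1_specific == 0
        assert cls.n_hap2_specific == 0
        assert cls.n_reference_only == 0

    def test_cg_to_tg_loss(self):
        ref = "AAACGAAA" + "ACGT" * 30
        hap2 = "AAATGAAA" + "ACGT" * 30
        n = len(ref)
        cls = classify_cpgs(
            ref, hap2, ref, _identity_map("hap1", n), _identity_map("hap2", n)
        )
        # the hap1 CpG at 3 is hap1-specific; reference CpG not
        # reference_only because hap1 still carries it
        assert cls.n_hap1_specific == 1
        assert cls.n_reference_only == 0

    def test_homozygous_loss_is_reference_only(self):
        ref = "AAACGAAA" + "ACGT" * 30
        hap = "AAATGAAA" + "ACGT" * 30
        n = len(ref)
        cls = classify_cpgs(
            hap, hap, ref, _identity_map("hap1", n), _identity_map("hap2", n)
        )
        assert cls.n_reference_only == 1

    def test_fraction_conservation(self, truth_small):
        cls = classify_cpgs(
            truth_small.hap1,
            truth_small.hap2,
            truth_small.reference,
            truth_small.truth_maps[1],
            truth_small.truth_maps[2],
        )
        shared1 = sum(1 for s in cls.hap1_sites if s.cpg_class == "shared")
        assert shared1 + cls.n_hap1_specific == len(cls.hap1_sites)


class TestLevels:
    def test_levels(self):
        ev = [
            MethylationEvidence("hap1", 10, 1, 10, 0),
            MethylationEvidence("hap1", 20, 1, 0, 10),
            MethylationEvidence("hap1", 30, 1, 3, 1),
            MethylationEvidence("hap1", 40, 1, 0, 0),
        ]
        df = methylation_levels(ev)
        by_pos = df.set_index("position").level
        assert by_pos[10] == 1.0 and by_pos[20] == 0.0 and by_pos[30] == 0.75
        assert np.isnan(by_pos[40])


class TestEpicBeta:
    def test_examples(self):
        assert epic_beta(100, 0) == 0.5
        assert epic_beta(0, 0) == 0.0
        assert epic_beta(900, 0) == 0.9

    def test_bounded_and_monotone(self):
        assert epic_beta(10**9, 0) < 1.0
        assert epic_beta(200, 50) > epic_beta(100, 50)


class TestProbeStratified:
    def test_perfect_correlation(self):
        arr = {i * 100: i / 10 for i in range(10)}
        seq = dict(arr)
        out = probe_stratified_correlation(arr, seq, variant_positions=[102, 203])
        assert out["with_snp"] == pytest.approx(1.0)
        assert out["without_snp"] == pytest.approx(1.0)

    def test_degenerate_reports_none(self):
        arr = {i: 0.5 for i in range(5)}
        seq = {i: i / 10 for i in range(5)}
        out = probe_stratified_correlation(arr, seq, variant_positions=[])
        assert out["without_snp"] is None
        assert out["with_snp"] is None

    def test_hand_computed_pearson(self):
        x = {0: 1.0, 1: 2.0, 2: 3.0, 3: 4.0, 4: 5.0}
        y = {0: 2.0, 1: 1.0, 2: 4.0, 3: 3.0, 4: 5.0}
        out = probe_stratified_correlation(x, y, variant_positions=[])
        r = np.corrcoef(list(x.values()), list(y.values()))[0, 1]
        assert out["without_snp"] == pytest.approx(r * r)

    def test_window_boundary(self):
        arr = {100: 0.1, 200: 0.5, 300: 0.9, 400: 0.2}
        seq = {100: 0.2, 200: 0.4, 300: 0.8, 400: 0.3}
        out = probe_stratified_correlation(arr, seq, variant_positions=[105, 306])
        # 100 is within 5 bp of 105; 300 is 6 bp from 306 -> without
        assert out["with_snp"] is None  # only one site in stratum
        assert out["without_snp"] is not None


class TestSmoothing:
    def test_idempotent_on_constants(self):
        pos = np.arange(0, 5000, 50)
        levels = np.full(len(pos), 0.7)
        cov = np.full(len(pos), 30.0)
        out = smooth_levels(pos, levels, cov)
        assert np.allclose(out, 0.7)

    def test_single_site_raw(self):
        out = smooth_levels(np.array([100]), np.array([0.3]), np.array([10.0]))
        assert out[0] == pytest.approx(0.3)

    def test_step_monotone(self):
        pos = np.arange(0, 10_000, 50)
        levels = (pos >= 5_000).astype(float)
        cov = np.full(len(pos), 30.0)
        out = smooth_levels(pos, levels, cov)
        assert (np.diff(out) >= -1e-12).all()

    def test_bounded(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(100_000, 500, replace=False))
        levels = rng.random(500)
        cov = rng.poisson(20, 500).astype(float)
        out = smooth_levels(pos, levels, cov)
        ok = np.isfinite(out)
        assert (out[ok] >= 0).all() and (out[ok] <= 1).all()

    def test_max_gap_splits_clusters(self):
        pos = np.array([0, 100, 200, 10_000_000, 10_000_100])
        levels = np.array([0.0, 0.0, 0.0, 1.0, 1.0])
        cov = np.full(5, 30.0)
        out = smooth_levels(
            pos, levels, cov, SmoothingParams(ns=50, h=800, max_gap=1_000_000)
        )
        assert np.allclose(out[:3], 0.0)
        assert np.allclose(out[3:], 1.0)


class TestDmrCall:
    def test_identical_groups_no_dmrs(self):
        pos = np.arange(0, 1000, 10)
        s = np.tile(np.linspace(0.2, 0.8, len(pos))[:, None], (1, 3))
        assert dmr_call(pos, s, s, np.zeros(len(pos))) == []

    def test_short_run_rejected(self):
        pos = np.array([0, 10, 500, 510])
        s1 = np.full((4, 3), 0.2)
        s2 = np.full((4, 3), 0.2)
        s2[:2] = 0.8  # only 2 consecutive high-|t| sites
        raw = np.array([0.6, 0.6, 0.0, 0.0])
        assert dmr_call(pos, s1, s2, raw) == []

    def test_min_diff_filter(self):
        pos = np.arange(0, 100, 10)
        s1 = np.full((10, 3), 0.50)
        s2 = np.full((10, 3), 0.55)  # strongly significant via var floor
        raw = np.full(10, 0.05)  # but below the 10% difference bar
        assert dmr_call(pos, s1, s2, raw) == []

    def test_clean_dmr_called(self):
        pos = np.arange(0, 300, 10)
        rng = np.random.default_rng(1)
        s1 = 0.5 + rng.normal(0, 0.01, (30, 3))
        s2 = s1.copy()
        s2[10:20] += 0.4
        raw = np.zeros(30)
        raw[10:20] = 0.4
        dmrs = dmr_call(pos, s1, s2, raw)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper_hap2"
        assert d.n_cpgs >= 10
        assert d.interval.start <= pos[10] and d.interval.end >= pos[19]

    def test_requires_replicates(self):
        pos = np.arange(3)
        with pytest.raises(ValueError):
            dmr_call(pos, np.zeros((3, 1)), np.zeros((3, 1)), np.zeros(3))


class TestSiteTable:
    def _evidence(self):
        ev = []
        for h in (1, 2):
            for rep in (1, 2, 3):
                for p in (100, 200, 300):
                    ev.append(
                        MethylationEvidence(f"hap{h}", p, rep, 5, 5)
                    )
        return ev

    def test_union_on_reference_coordinates(self):
        table = build_site_table(
            self._evidence(),
            _identity_map("hap1", 1000),
            _identity_map("hap2", 1000),
        )
        assert list(table.index) == [100, 200, 300]

    def test_shared_only_coverage_filter(self):
        ev = self._evidence()
        # site 200 covered in only one hap1 replicate
        ev = [
            e
            for e in ev
            if not (e.genome == "hap1" and e.position == 200 and e.replicate > 1)
        ]
        table = build_site_table(
            ev, _identity_map("hap1", 1000), _identity_map("hap2", 1000)
        )
        kept = filter_cpgs_for_dmr(table, mode="shared_only")
        assert 200 not in kept.index
        assert {100, 300} <= set(kept.index)
        all_sites = filter_cpgs_for_dmr(table, mode="with_specific")
        assert 200 in all_sites.index
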