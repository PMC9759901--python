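"""Site calling and DMR detection against enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

import methmirnet as mm
from methmirnet.errors import ParameterError, ZeroCoverageError

from conftest import make_cpg_table
from oracles import binom_upper_tail, fisher_two_sided


class TestSiteCalling:
    def test_undercovered_site_never_called(self):
        call = mm.call_site(2, 2, p0=0.05, depth_min=5)
        assert not call.is_called  # coverage 4 < 5 regardless of p

    def test_zero_methylated_reads_give_p_one(self):
        call = mm.call_site(0, 10, p0=0.3)
        assert call.p_value == 1.0
        assert not call.is_called
        assert call.methylation_level == 0.0

    def test_known_upper_tail_value(self):
        # enumeration: sum of Binomial(10, 0.05) pmf for k=3..10
        call = mm.call_site(3, 7, p0=0.05)
        assert call.p_value == pytest.approx(0.0115036, abs=1e-4)
        assert call.p_value == pytest.approx(binom_upper_tail(3, 10, 0.05), rel=1e-12)
        assert call.is_called  # coverage 10 >= 5 and p <= 0.05

    @pytest.mark.parametrize("p0", [0.005, 0.05, 0.5])
    def test_tail_matches_enumeration_all_n_up_to_50(self, p0):
        for n in range(1, 51):
            for m in {0, 1, n // 2, n}:
                got = mm.methylation.binomial_upper_tail(m, n, p0)
                want = binom_upper_tail(m, n, p0)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_invalid_p0_rejected(self):
        with pytest.raises(ParameterError):
            mm.call_site(3, 7, p0=1.5)

    def test_vectorized_calls_match_scalar(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 20, 50)
        u = rng.integers(0, 20, 50)
        table = make_cpg_table("chr1", np.arange(50) * 10, m, u, samples=("s",))
        calls = mm.call_sites(table, "s", p0=0.05)
        for i in range(50):
            ref = mm.call_site(int(m[i]), int(u[i]), p0=0.05)
            assert calls["p_value"].iloc[i] == pytest.approx(ref.p_value, rel=1e-12)
            assert bool(calls["is_called"].iloc[i]) == ref.is_called


class TestMethylationLevel:
    @pytest.mark.parametrize("m,u,want", [(5, 5, 0.5), (0, 8, 0.0), (7, 3, 0.7)])
    def test_level(self, m, u, want):
        assert mm.methylation_level(m, u) == pytest.approx(want)

    def test_zero_coverage_raises(self):
        with pytest.raises(ZeroCoverageError):
            mm.methylation_level(0, 0)


class TestClassify:
    def test_signs_and_tie(self):
        assert mm.classify_dmr(0.2) == "hyper"
        assert mm.classify_dmr(-0.2) == "hypo"
        assert mm.classify_dmr(0.0) is None


def _planted_tables(n_null=40, n_sig=10, cov=50):
    """One strongly differential CpG cluster on an otherwise-null chromosome."""
    rng = np.random.default_rng(3)
    pos_null = np.arange(n_null) * 700  # sparse: <3 CpGs per 1 kb window
    pos_sig = 50_000 + np.arange(n_sig) * 100
    positions = np.concatenate([pos_null, pos_sig])

    def counts(level_sig):
        m = np.concatenate([
            rng.binomial(cov, 0.4, n_null), rng.binomial(cov, level_sig, n_sig)
        ])
        return m, np.full(len(positions), cov) - m

    m_case, u_case = counts(0.8)
    m_ctrl, u_ctrl = counts(0.3)
    case = make_cpg_table("chr1", positions, m_case, u_case, samples=("a1",))
    ctrl = make_cpg_table("chr1", positions, m_ctrl, u_ctrl, samples=("n1",))
    return case, ctrl, (int(pos_sig[0]), int(pos_sig[-1]) + 1)


class TestDMRDetection:
    def test_identical_tables_yield_no_dmrs(self):
        case, _, _ = _planted_tables()
        ctrl = case.rename(columns={"m_a1": "m_x", "u_a1": "u_x"})
        assert mm.detect_dmrs(case, ctrl) == []

    def test_planted_window_found_with_fisher_oracle_p(self):
        case, ctrl, span = _planted_tables()
        dmrs = mm.detect_dmrs(case, ctrl)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert d.start <= span[0] and d.end >= span[1]  # covers the cluster
        # re-test one window of the scan against hypergeometric enumeration
        win = mm.scan_windows(case, ctrl)
        row = win.loc[win["p_value"].idxmin()]
        want = fisher_two_sided(
            int(row.m_case), int(row.u_case), int(row.m_ctrl), int(row.u_ctrl)
        )
        assert row.p_value == pytest.approx(want, rel=1e-6)

    def test_overlapping_significant_windows_merge_to_union(self):
        case, ctrl, span = _planted_tables(n_sig=15)
        win = mm.scan_windows(case, ctrl)
        sig = win[win.p_value <= 1e-6]
        assert len(sig) > 1  # several overlapping windows over the cluster
        dmrs = mm.detect_dmrs(case, ctrl)
        assert len(dmrs) == 1
        assert dmrs[0].start == sig.start.min()
        assert dmrs[0].end == sig.end.max()

    def test_group_swap_flips_direction_and_preserves_p(self):
        case, ctrl, _ = _planted_tables()
        fwd = mm.detect_dmrs(case, ctrl)
        rev = mm.detect_dmrs(ctrl, case)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].direction == "hyper" and rev[0].direction == "hypo"
        assert fwd[0].p_value == pytest.approx(rev[0].p_value, rel=1e-9)
        assert fwd[0].mean_diff == pytest.approx(-rev[0].mean_diff, rel=1e-9)

    def test_outputs_sorted_disjoint_and_within_thresholds(self, small_planted_bundle):
        b = small_planted_bundle
        dmrs = mm.detect_dmrs(
            b.cpg_group_table("case"), b.cpg_group_table("control")
        )
        assert dmrs, "planted cohort should yield DMRs"
        for prev, cur in zip(dmrs, dmrs[1:]):
            if prev.chrom == cur.chrom:
                assert prev.end <= cur.start
        for d in dmrs:
            assert d.start < d.end
            assert d.p_value <= 0.05 and d.q_value <= 0.05
            assert d.q_value >= d.p_value
            assert abs(d.mean_diff) >= 0.1
            assert d.direction == ("hyper" if d.mean_diff > 0 else "hypo")

    def test_min_cpgs_below_one_rejected(self):
        case, ctrl, _ = _planted_tables()
        with pytest.raises(ParameterError):
            mm.detect_dmrs(case, ctrl, min_cpgs=0)

    def test_empty_input_yields_empty_list(self):
        a = make_cpg_table("chr1", [], [], [], samples=("a",))
        b = make_cpg_table("chr1", [], [], [], samples=("n",))
        assert mm.detect_dmrs(a, b) == []

    def test_null_window_rejection_near_nominal(self):
        """On null data ~5% of testable windows reach p <= 0.05."""
        cfg = mm.SynthConfig(seed=0, n_triplets=0, n_mirnas=300, n_mrnas=4,
                             n_chroms=10, chrom_length_bp=400_000,
                             n_cpg_per_promoter=6, meth_base=0.5,
                             bb_overdispersion=0.0, coverage_mean=30)
        b = mm.generate_cohort(cfg)
        win = mm.scan_windows(
            b.cpg_group_table("case"), b.cpg_group_table("control")
        )
        assert len(win) >= 2000
        rate = float((win["p_value"] <= 0.05).mean())
        band = 2 * np.sqrt(0.05 * 0.95 / len(win))
        assert abs(rate - 0.05) <= band

    def test_ttest_mode_finds_planted_region(self, small_planted_bundle):
        b = small_planted_bundle
        dmrs = mm.detect_dmrs(
            b.cpg_group_table("case"), b.cpg_group_table("control"), test="ttest"
        )
        planted = {(t.dmr_chrom, t.meth_direction) for t in b.truth.triplets}
        found = {(d.chrom, d.direction) for d in dmrs}
        assert planted <= found


class TestDMRSerialization:
    def test_bed_round_trip(self, small_planted_bundle, tmp_path):
        b = small_planted_bundle
        dmrs = mm.detect_dmrs(
            b.cpg_group_table("case"), b.cpg_group_table("control")
        )
        path = tmp_path / "dmrs.bed"
        mm.methylation.write_dmrs(dmrs, path)
        back = mm.methylation.read_dmrs(path)
        assert [(d.chrom, d.start, d.end, d.direction) for d in back] == [
            (d.chrom, d.start, d.end, d.direction) for d in dmrs
        ]

    def test_dmr_levels_are_coverage_weighted(self):
        table = make_cpg_table(
            "chr1", [10, 20],
            {"s": [8, 1]}, {"s": [2, 19]},
        )
        d = mm.DMR("chr1", 0, 30, 2, 0.1, 0.01, 0.01, "hyper")
        lv = mm.dmr_methylation_levels([d], table, ["s"])
        # pooled counts m=9 of 30 -> 0.30, not the unweighted mean 0.425
        assert lv.loc["chr1:0-30", "s"] == pytest.approx(9 / 30)
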