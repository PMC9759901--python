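"""Correlation, edge retention, triplet assembly and export round-trips."""

import numpy as np
import pandas as pd
import pytest

import methmirnet as mm
from methmirnet.errors import ParameterError, UndefinedCorrelationError
from methmirnet.methylation import DMR
from methmirnet.regulatory_map import TargetPair

from oracles import pearson_r


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = mm.correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, _ = mm.correlate(x, -2 * x + 3)
        assert r == pytest.approx(-1.0)

    def test_five_point_hand_value(self):
        # hand computation: centred cross-products 10, variances 10 and 14.8
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
        r, p = mm.correlate(x, y)
        assert r == pytest.approx(10 / np.sqrt(10 * 14.8), abs=1e-12)
        assert r == pytest.approx(pearson_r(x, y), abs=1e-12)
        # p from the t transform, t = r * sqrt((n-2)/(1-r^2))
        from scipy.stats import t as tdist
        t = r * np.sqrt(3 / (1 - r**2))
        assert p == pytest.approx(2 * tdist.sf(abs(t), 3), rel=1e-9)

    def test_spearman_uses_ranks(self):
        x = [1, 2, 3, 4, 5]
        y = [10, 100, 1000, 10000, 100000]  # monotone, nonlinear
        r, _ = mm.correlate(x, y, method="spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_signalled(self):
        with pytest.raises(UndefinedCorrelationError):
            mm.correlate([1, 1, 1, 1], [1, 2, 3, 4])

    def test_short_input_rejected(self):
        with pytest.raises(ParameterError):
            mm.correlate([1, 2], [3, 4])


def _toy_inputs(r_sign=-1.0):
    """One DMR-miRNA-mRNA chain with controllable correlation sign."""
    samples = [f"A{i}" for i in range(5)] + [f"N{i}" for i in range(5)]
    dmr = DMR("chr1", 100, 600, 5, -0.4, 1e-6, 1e-5, "hypo")
    meth = np.array([0.1, 0.12, 0.11, 0.09, 0.1, 0.5, 0.52, 0.48, 0.5, 0.51])
    mirna = np.array([400, 410, 395, 405, 399, 100, 104, 98, 101, 103], float)
    mrna = r_sign * mirna + 1000  # anti- or positively correlated with miRNA
    de_mirna = pd.DataFrame({"status": ["up"]}, index=["mir1"])
    de_mrna = pd.DataFrame({"status": ["down"]}, index=["g1"])
    levels = pd.DataFrame([meth], index=["chr1:100-600"], columns=samples)
    mirna_norm = pd.DataFrame([mirna], index=["mir1"], columns=samples)
    mrna_norm = pd.DataFrame([mrna], index=["g1"], columns=samples)
    ppairs = [(dmr, "mir1")]
    tpairs = [TargetPair("mir1", "g1", 1, "seed_match")]
    return dmr, de_mirna, de_mrna, ppairs, tpairs, levels, mirna_norm, mrna_norm


class TestBuildNetwork:
    def test_all_ns_tables_give_empty_network(self):
        dmr, de_mi, de_g, pp, tp, lv, mi, g = _toy_inputs()
        de_mi["status"] = "ns"
        de_g["status"] = "ns"
        net = mm.build_network([dmr], de_mi, de_g, pp, tp, lv, mi, g)
        assert len(net.graph) == 0
        assert net.triplets == []

    def test_consistent_triplet_retained(self):
        dmr, de_mi, de_g, pp, tp, lv, mi, g = _toy_inputs(r_sign=-1.0)
        net = mm.build_network([dmr], de_mi, de_g, pp, tp, lv, mi, g, strict=True)
        assert net.triplets == [("chr1:100-600", "mir1", "g1")]
        for e in net.retained_edges:
            assert e.r < 0 and abs(e.r) >= 0.7 and e.p_value <= 0.05

    def test_positive_r_rejected_in_strict_mode(self):
        dmr, de_mi, de_g, pp, tp, lv, mi, g = _toy_inputs(r_sign=+1.0)
        net = mm.build_network([dmr], de_mi, de_g, pp, tp, lv, mi, g, strict=True)
        kinds = {e.kind: e for e in net.edges}
        assert not kinds["mirna_mrna"].retained  # r = +1 violates sign rule
        permissive = mm.build_network(
            [dmr], de_mi, de_g, pp, tp, lv, mi, g, strict=False
        )
        assert {e.kind for e in permissive.retained_edges} == {
            "meth_mirna", "mirna_mrna"
        }

    def test_strict_mode_enforces_direction_pattern(self):
        dmr, de_mi, de_g, pp, tp, lv, mi, g = _toy_inputs()
        de_g["status"] = "up"  # up-miRNA with up-target: inconsistent chain
        net = mm.build_network([dmr], de_mi, de_g, pp, tp, lv, mi, g, strict=True)
        assert net.triplets == []

    def test_monotonicity_in_thresholds(self, small_planted_bundle):
        b = small_planted_bundle
        dmrs = mm.detect_dmrs(b.cpg_group_table("case"), b.cpg_group_table("control"))
        rpm = mm.rpm_normalize(b.mirna_counts)
        lengths = b.mrna_annotation.set_index("mrna_id")["exon_length_bp"]
        rpkm = mm.rpkm_normalize(b.mrna_counts, lengths)
        de_mi = mm.de_screen(rpm, b.groups, **mm.DE_PRESETS["mirna"])
        de_g = mm.de_screen(rpkm, b.groups, **mm.DE_PRESETS["mrna"])
        proms = mm.promoters_from_annotation(b.mirna_annotation, b.chrom_lengths)
        pp = mm.overlap_dmr_promoters(dmrs, proms)
        tp = mm.predict_targets(b.mirna_sequences, b.utr_sequences)
        lv = mm.dmr_methylation_levels(dmrs, b.cpg, list(b.samples.sample_id))

        def edge_set(r_min, p_max):
            net = mm.build_network(dmrs, de_mi, de_g, pp, tp, lv, rpm, rpkm,
                                   r_min=r_min, p_max=p_max)
            return {(e.kind, e.source, e.target) for e in net.retained_edges}

        base = edge_set(0.5, 0.05)
        assert edge_set(0.8, 0.05) <= base   # raising r_min never adds edges
        assert edge_set(0.5, 0.01) <= base   # lowering p_max never adds edges

    def test_misaligned_samples_rejected(self):
        dmr, de_mi, de_g, pp, tp, lv, mi, g = _toy_inputs()
        g2 = g.rename(columns={"A0": "weird"})
        with pytest.raises(mm.errors.AlignmentError):
            mm.build_network([dmr], de_mi, de_g, pp, tp, lv, mi, g2)


class TestSummaryAndExport:
    def test_empty_network_all_zero_summary(self):
        s = mm.summarize_network(mm.RegulatoryNetwork())
        assert s["n_triplets"] == 0
        assert all(v["total"] == 0 for v in s["nodes"].values())

    def test_single_triplet_summary(self):
        dmr, de_mi, de_g, pp, tp, lv, mi, g = _toy_inputs()
        net = mm.build_network([dmr], de_mi, de_g, pp, tp, lv, mi, g)
        s = mm.summarize_network(net)
        assert s == {
            "nodes": {
                "dmr": {"total": 1, "hyper": 0, "hypo": 1},
                "mirna": {"total": 1, "up": 1, "down": 0},
                "mrna": {"total": 1, "up": 0, "down": 1},
            },
            "edges": {"meth_mirna": 1, "mirna_mrna": 1},
            "n_triplets": 1,
        }

    def test_direction_subtotals_sum_to_totals(self, small_planted_bundle):
        b = small_planted_bundle
        dmrs = mm.detect_dmrs(b.cpg_group_table("case"), b.cpg_group_table("control"))
        rpm = mm.rpm_normalize(b.mirna_counts)
        lengths = b.mrna_annotation.set_index("mrna_id")["exon_length_bp"]
        rpkm = mm.rpkm_normalize(b.mrna_counts, lengths)
        de_mi = mm.de_screen(rpm, b.groups, **mm.DE_PRESETS["mirna"])
        de_g = mm.de_screen(rpkm, b.groups, **mm.DE_PRESETS["mrna"])
        proms = mm.promoters_from_annotation(b.mirna_annotation, b.chrom_lengths)
        net = mm.build_network(
            dmrs, de_mi, de_g, mm.overlap_dmr_promoters(dmrs, proms),
            mm.predict_targets(b.mirna_sequences, b.utr_sequences),
            mm.dmr_methylation_levels(dmrs, b.cpg, list(b.samples.sample_id)),
            rpm, rpkm,
        )
        s = mm.summarize_network(net)
        assert s["nodes"]["dmr"]["total"] == s["nodes"]["dmr"]["hyper"] + s["nodes"]["dmr"]["hypo"]
        assert s["nodes"]["mirna"]["total"] == s["nodes"]["mirna"]["up"] + s["nodes"]["mirna"]["down"]
        assert s["nodes"]["mrna"]["total"] == s["nodes"]["mrna"]["up"] + s["nodes"]["mrna"]["down"]

    def test_graphml_round_trip_isomorphic(self, tmp_path):
        dmr, de_mi, de_g, pp, tp, lv, mi, g = _toy_inputs()
        net = mm.build_network([dmr], de_mi, de_g, pp, tp, lv, mi, g)
        mm.export_network(net, tmp_path, formats=("graphml",))
        back = mm.read_graphml(tmp_path / "network.graphml")
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(back.graph.edges) == set(net.graph.edges)
        assert back.triplets == net.triplets

    def test_tsv_edge_count_matches(self, tmp_path):
        dmr, de_mi, de_g, pp, tp, lv, mi, g = _toy_inputs()
        net = mm.build_network([dmr], de_mi, de_g, pp, tp, lv, mi, g)
        mm.export_network(net, tmp_path, formats=("tsv",))
        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert len(edges) == net.graph.number_of_edges()

    def test_empty_network_header_only_tsv(self, tmp_path):
        mm.export_network(mm.RegulatoryNetwork(), tmp_path, formats=("tsv",))
        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert len(edges) == 0
        assert list(edges.columns) == ["source", "target", "kind", "r", "p_value"]
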