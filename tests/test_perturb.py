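"""Perturb-seq processing: guide calling, QC, normalization, ANOVA/LSD,
control-referenced log2FC, heuristic regulatee scoring."""

import numpy as np
import pandas as pd
import pytest

from tfatlas import simulate
from tfatlas.experiments import qc_toy_bundle
from tfatlas.grn import RegulatoryNetwork
from tfatlas.perturb import (anova_lsd, assign_guides, cluster_fractions,
                             heuristic_scores, log2fc_table,
                             log2fc_vs_control, lognormalize, qc_filter)


def _bundle(guide_umi, counts=None, targets=None):
    cells = list(guide_umi.columns)
    genes = [f"g{i}" for i in range(5)] if counts is None else list(counts.index)
    if counts is None:
        counts = pd.DataFrame(1, index=genes, columns=cells)
    flags = pd.DataFrame(False, index=genes, columns=["mito", "ribo"])
    return simulate.PerturbBundle(
        counts=counts, guide_umi=guide_umi,
        guide_to_target=pd.Series(targets or
                                  {g: g.split("_")[0].lstrip("g")
                                   for g in guide_umi.index}),
        hashtag=pd.Series("rep1", index=cells),
        gene_flags=flags, truth={})


class TestAssignGuides:
    def test_single_guide_single_target(self):
        umi = pd.DataFrame({"c1": [10, 0]}, index=["gA_1", "gB_1"])
        ga = assign_guides(_bundle(umi, targets={"gA_1": "A", "gB_1": "B"}))
        assert ga.table.loc["c1", "targets"] == ("A",)
        assert not ga.table.loc["c1", "multi_target"]

    def test_two_distinct_targets_flagged(self):
        umi = pd.DataFrame({"c1": [10, 7]}, index=["gA_1", "gB_1"])
        ga = assign_guides(_bundle(umi, targets={"gA_1": "A", "gB_1": "B"}))
        assert ga.table.loc["c1", "multi_target"]

    def test_below_threshold_not_called(self):
        umi = pd.DataFrame({"c1": [2, 10]}, index=["gA_1", "gB_1"])
        ga = assign_guides(_bundle(umi, targets={"gA_1": "A", "gB_1": "B"}),
                           umi_threshold=3)
        assert ga.table.loc["c1", "targets"] == ("B",)

    def test_scramble_only_cell(self):
        umi = pd.DataFrame({"c1": [10, 0]}, index=["gScr_1", "gA_1"])
        ga = assign_guides(_bundle(umi, targets={"gScr_1": "scramble",
                                                 "gA_1": "A"}))
        assert ga.table.loc["c1", "targets"] == ("scramble",)

    def test_called_cells_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        umi = pd.DataFrame(rng.poisson(3, size=(4, 50)),
                           index=["gA_1", "gA_2", "gB_1", "gScr_1"],
                           columns=[f"c{i}" for i in range(50)])
        pb = _bundle(umi, targets={"gA_1": "A", "gA_2": "A", "gB_1": "B",
                                   "gScr_1": "scramble"})
        counts = []
        for thr in (1, 2, 3, 5, 8):
            ga = assign_guides(pb, umi_threshold=thr)
            counts.append(int((ga.table["n_called"] > 0).sum()))
        assert counts == sorted(counts, reverse=True)


class TestQcFilter:
    def test_toy_keeps_exactly_seven(self):
        pb, ga = qc_toy_bundle()
        qc = qc_filter(pb, ga)
        assert len(qc.kept_cells) == 7

    def test_low_gene_cell_reason(self):
        pb, ga = qc_toy_bundle()
        qc = qc_filter(pb, ga)
        # the two 150-detected-gene cells fail the "fewer than 200" rule
        assert qc.table.loc["c00", "n_genes_detected"] == 150
        assert qc.table.loc["c00", "reason"] == "min_genes"
        assert qc.table.loc["c02", "reason"] == "max_mito"
        assert qc.table.loc["c03", "reason"] == "min_ribo"
        assert qc.table.loc["c04", "reason"] == "multi_target"

    def test_all_clean_cells_kept(self):
        pb, ga = qc_toy_bundle()
        clean = pb.counts[[f"c{i:02d}" for i in range(5, 12)]]
        pb2 = simulate.PerturbBundle(
            counts=clean, guide_umi=pb.guide_umi[clean.columns],
            guide_to_target=pb.guide_to_target,
            hashtag=pb.hashtag[clean.columns],
            gene_flags=pb.gene_flags, truth={})
        ga2 = assign_guides(pb2)
        qc = qc_filter(pb2, ga2)
        assert qc.table["kept"].all()


class TestLognormalize:
    def test_zero_count_stays_zero(self):
        counts = pd.DataFrame({"c1": [0, 10]}, index=["g1", "g2"])
        norm = lognormalize(counts)
        assert norm.loc["g1", "c1"] == 0.0

    def test_full_column_closed_form(self):
        counts = pd.DataFrame({"c1": [7, 0]}, index=["g1", "g2"])
        norm = lognormalize(counts, scale=10_000)
        assert norm.loc["g1", "c1"] == pytest.approx(np.log(10_001))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(5, size=(6, 4)))
        norm = lognormalize(counts, scale=1e4)
        total = counts.sum(axis=0).to_numpy()
        expected = np.log1p(1e4 * counts.to_numpy() / total)
        np.testing.assert_allclose(norm.to_numpy(), expected)

    def test_zero_total_cell_rejected(self):
        counts = pd.DataFrame({"c1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="zero-total"):
            lognormalize(counts)


class TestClusterFractions:
    def _ga(self, mapping):
        umi = pd.DataFrame(0, index=["gA_1", "gB_1", "gScr_1"],
                           columns=list(mapping))
        targets = {"gA_1": "A", "gB_1": "B", "gScr_1": "scramble"}
        for cell, t in mapping.items():
            guide = {"A": "gA_1", "B": "gB_1",
                     "scramble": "gScr_1"}[t]
            umi.loc[guide, cell] = 10
        return assign_guides(_bundle(umi, targets=targets))

    def test_single_cluster_is_hundred_percent(self):
        cells = [f"c{i}" for i in range(4)]
        ga = self._ga({c: "A" for c in cells})
        fr, missing = cluster_fractions(
            cells, pd.Series("K", index=cells), ga,
            pd.Series("rep1", index=cells))
        assert fr.loc[("rep1", "A"), "K"] == pytest.approx(100.0)

    def test_seventy_thirty_split(self):
        cells = [f"c{i}" for i in range(10)]
        ga = self._ga({c: "A" for c in cells})
        labels = pd.Series(["K1"] * 7 + ["K2"] * 3, index=cells)
        fr, _ = cluster_fractions(cells, labels, ga,
                                  pd.Series("rep1", index=cells))
        assert fr.loc[("rep1", "A"), "K1"] == pytest.approx(70.0)
        assert fr.loc[("rep1", "A"), "K2"] == pytest.approx(30.0)

    def test_rows_sum_to_hundred_and_match_crosstab(self):
        rng = np.random.default_rng(2)
        cells = [f"c{i}" for i in range(60)]
        targets = rng.choice(["A", "B", "scramble"], size=60)
        ga = self._ga(dict(zip(cells, targets)))
        labels = pd.Series(rng.choice(["K1", "K2", "K3"], size=60),
                           index=cells)
        reps = pd.Series(rng.choice(["rep1", "rep2"], size=60), index=cells)
        fr, missing = cluster_fractions(cells, labels, ga, reps)
        np.testing.assert_allclose(fr.sum(axis=1), 100.0, atol=1e-9)
        df = pd.DataFrame({"t": targets, "k": labels.to_numpy(),
                           "r": reps.to_numpy()})
        for (r, t), sub in df.groupby(["r", "t"]):
            for k, cnt in sub["k"].value_counts().items():
                assert fr.loc[(r, t), k] == pytest.approx(
                    100.0 * cnt / len(sub))


class TestAnovaLsd:
    def _fractions(self, table):
        """table: replicate x target DataFrame of one cluster's values."""
        stacked = table.stack().rename("clusterX")
        stacked.index.names = ["replicate", "target"]
        return stacked.to_frame()

    def test_identical_targets_give_null_result(self):
        y = pd.DataFrame({"scramble": [40.0, 42, 38],
                          "tfA": [40.0, 42, 38],
                          "tfB": [40.0, 42, 38]},
                         index=["r1", "r2", "r3"])
        lsd, anova = anova_lsd(self._fractions(y), "clusterX")
        assert anova["F_target"] == pytest.approx(0.0, abs=1e-20)
        assert (lsd["p_value"] > 0.999).all()

    def test_matches_textbook_two_way_anova(self):
        """3 targets x 2 replicates toy table checked against the
        closed-form additive two-way decomposition done by hand."""
        y = pd.DataFrame({"scramble": [10.0, 12.0],
                          "tfA": [20.0, 26.0],
                          "tfB": [14.0, 18.0]}, index=["r1", "r2"])
        lsd, anova = anova_lsd(self._fractions(y), "clusterX")
        # hand computation: grand = 100/6; target means 11, 23, 16;
        # replicate means 44/3, 56/3; SS_total = 520/3
        # SS_target = 2*((11-50/3)^2+(23-50/3)^2+(16-50/3)^2) = 436/3
        # SS_rep = 3*((44/3-50/3)^2+(56/3-50/3)^2) = 24
        # SS_res = 520/3 - 436/3 - 24 = 4
        assert anova["ss_target"] == pytest.approx(436 / 3, abs=1e-9)
        assert anova["ss_replicate"] == pytest.approx(24.0, abs=1e-9)
        assert anova["ss_residual"] == pytest.approx(4.0, abs=1e-9)
        assert anova["df_residual"] == 2
        # F = (436/6) / (4/2) = 109/3
        assert anova["F_target"] == pytest.approx(109 / 3, abs=1e-9)
        # LSD for tfA vs scramble: diff 12, se = sqrt(2*2/2) = sqrt(2)
        row = lsd.set_index("target").loc["tfA"]
        assert row["t"] == pytest.approx(12 / np.sqrt(2.0), abs=1e-9)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(3)
        y = pd.DataFrame(rng.normal(40, 5, size=(4, 5)),
                         index=[f"r{i}" for i in range(4)],
                         columns=["scramble", "a", "b", "c", "d"])
        lsd, anova = anova_lsd(self._fractions(y), "clusterX")
        long = y.stack().rename("y").reset_index()
        long.columns = ["rep", "target", "y"]
        fit = smf.ols("y ~ C(target) + C(rep)", data=long).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert anova["F_target"] == pytest.approx(
            float(tab.loc["C(target)", "F"]))
        assert anova["ms_residual"] == pytest.approx(
            float(tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]))

    def test_planted_drop_detected(self):
        from tfatlas.experiments import anova_planted_shift
        out = anova_planted_shift(seed=1)
        assert out["p_value"] < 0.01

    def test_single_replicate_rejected(self):
        y = pd.DataFrame({"scramble": [40.0], "tfA": [30.0]}, index=["r1"])
        with pytest.raises(ValueError, match="replicates"):
            anova_lsd(self._fractions(y), "clusterX")


class TestLog2fc:
    def test_identical_groups_zero(self):
        norm = pd.DataFrame(np.log1p([[3.0, 3.0, 3.0, 3.0]]), index=["g1"],
                            columns=["k1", "k2", "s1", "s2"])
        assert log2fc_vs_control(norm, ["k1", "k2"], ["s1", "s2"],
                                 "g1") == pytest.approx(0.0)

    def test_closed_form_example(self):
        # de-logged KO mean 3, scramble mean 1, pseudo 1 -> log2(4/2) = 1
        norm = pd.DataFrame(np.log1p([[3.0, 3.0, 1.0, 1.0]]), index=["g1"],
                            columns=["k1", "k2", "s1", "s2"])
        assert log2fc_vs_control(norm, ["k1", "k2"], ["s1", "s2"],
                                 "g1") == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        norm = pd.DataFrame(np.log1p([[1.0]]), index=["g1"], columns=["c"])
        with pytest.raises(ValueError, match="nonempty"):
            log2fc_vs_control(norm, [], ["c"], "g1")

    def test_table_matches_scalar_function(self):
        rng = np.random.default_rng(4)
        cells = [f"c{i}" for i in range(8)]
        norm = pd.DataFrame(rng.uniform(0, 2, size=(3, 8)),
                            index=["g1", "g2", "g3"], columns=cells)
        umi = pd.DataFrame(0, index=["gA_1", "gScr_1"], columns=cells)
        umi.loc["gA_1", cells[:4]] = 10
        umi.loc["gScr_1", cells[4:]] = 10
        pb = _bundle(umi, counts=pd.DataFrame(1, index=["g1", "g2", "g3"],
                                              columns=cells),
                     targets={"gA_1": "A", "gScr_1": "scramble"})
        ga = assign_guides(pb)
        table = log2fc_table(norm, ga, cells, ["A"])
        for g in ["g1", "g2", "g3"]:
            assert table.loc[g, "A"] == pytest.approx(
                log2fc_vs_control(norm, cells[:4], cells[4:], g))


class TestHeuristicScores:
    def _network(self):
        edges = pd.DataFrame({
            "tf": ["TfA"] * 4,
            "gene": ["g1", "g2", "g3", "g4"],
            "w": [0.8, 0.5, 0.3, 0.1],
        })
        return RegulatoryNetwork(sample=None,
                                 node_weight=pd.Series(1.0,
                                                       index=["TfA", "g1",
                                                              "g2", "g3",
                                                              "g4"]),
                                 edges=edges)

    def test_zero_lfc_scores_zero(self):
        lfc = pd.DataFrame({"TfA": [0.0, 0.0, 0.0, 0.0]},
                           index=["g1", "g2", "g3", "g4"])
        out = heuristic_scores(self._network(), lfc)
        assert (out["score"] == 0.0).all()
        assert not out["high_confidence"].any()

    def test_threshold_equals_1_5_fold(self):
        assert 2 ** 0.58 == pytest.approx(1.5, abs=0.01)
        assert round(2 ** 0.58, 1) == 1.5

    def test_rule_application(self):
        # w=0.8 is the top quartile of TfA's weights; log2FC=-1 clears 0.58
        lfc = pd.DataFrame({"TfA": [-1.0, -1.0, -0.2, -1.0]},
                           index=["g1", "g2", "g3", "g4"])
        out = heuristic_scores(self._network(), lfc).set_index("gene")
        g1 = out.loc["g1"]
        assert g1["score"] == pytest.approx(-0.8)
        assert bool(g1["high_confidence"])
        assert g1["mode"] == "activated"
        # g2 clears the fold-change bar but w=0.5 is below the quartile
        assert not bool(out.loc["g2", "high_confidence"])
        # g3 has top-half weight but tiny fold change
        assert not bool(out.loc["g3", "high_confidence"])

    def test_positive_lfc_is_repressed_mode(self):
        lfc = pd.DataFrame({"TfA": [1.0, 0.0, 0.0, 0.0]},
                           index=["g1", "g2", "g3", "g4"])
        out = heuristic_scores(self._network(), lfc).set_index("gene")
        assert out.loc["g1", "mode"] == "repressed"

    def test_missing_tf_rejected(self):
        lfc = pd.DataFrame({"TfZ": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="absent"):
            heuristic_scores(self._network(), lfc)
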