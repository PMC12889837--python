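import math

import numpy as np
import pandas as pd
import pytest

from gps_periscan.expression_analysis import (
    GroupAssignment,
    QpcrRecord,
    combined_gene_score,
    ddct_fold_change,
    differential_expression,
    gps_score,
    integrate_and_sort,
    mrsp,
    select_groups,
)
from gps_periscan.synthetic_data import C19MC_MEMBERS


class TestMrsp:
    def test_max_semantics(self):
        assert mrsp([0, 3, 17, 9]) == 17
        assert mrsp([9, 17]) == 17  # two local maxima: larger wins

    def test_all_zero(self):
        assert mrsp([0, 0, 0]) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mrsp([])

    def test_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(1)
        depths = rng.integers(0, 50, 100)
        assert mrsp(depths) == mrsp(rng.permutation(depths))
        assert mrsp(depths + 1) >= mrsp(depths)

    def test_ledger_coverage_recovery(self, dataset):
        truth = dataset.ledger.expression["coverage_mrsp"]
        for line, track in dataset.coverage.items():
            for orf in dataset.ledger.pericentromeric_orfs():
                assert track.max_over(orf.interval) == truth[line][orf.gene]


@pytest.fixture
def toy_matrix():
    return pd.DataFrame(
        {"l1": [1, 5, 0], "l2": [2, 0, 0], "l3": [3, 2, 0]},
        index=["g1", "g2", "g3"],
    )


class TestScores:
    def test_combined_score(self, toy_matrix):
        assert combined_gene_score(toy_matrix, "g1") == 6
        assert combined_gene_score(toy_matrix, "g3") == 0
        with pytest.raises(KeyError):
            combined_gene_score(toy_matrix, "nope")

    def test_gps_score(self, toy_matrix):
        assert gps_score(toy_matrix, "l1") == 6
        assert gps_score(toy_matrix, "l1", family=["g1", "g3"]) == 1
        with pytest.raises(KeyError):
            gps_score(toy_matrix, "nope")

    def test_conservation_identity(self, dataset):
        family = dataset.ledger.expression["gps_genes"]
        sub = dataset.gene_matrix.loc[family]
        total_by_gene = sum(combined_gene_score(sub, g) for g in family)
        total_by_line = sum(gps_score(sub, line) for line in sub.columns)
        assert total_by_gene == total_by_line == sub.to_numpy().sum()

    def test_top2_combined_are_planted_strongest(self, dataset):
        family = dataset.ledger.expression["gps_genes"]
        combined = {g: combined_gene_score(dataset.gene_matrix, g) for g in family}
        top2 = sorted(combined, key=combined.get, reverse=True)[:2]
        assert set(top2) == set(dataset.ledger.expression["top2_combined"])


class TestIntegrateAndSort:
    def test_sorted_by_c19mc_descending(self):
        gps = pd.Series({"l1": 1.0, "l2": 1.0, "l3": 1.0})
        mirna = pd.DataFrame({"l1": [10.0], "l2": [0.0], "l3": [5.0]}, index=["m1"])
        table = integrate_and_sort(gps, mirna, ["m1"])
        assert list(table.index) == ["l1", "l3", "l2"]

    def test_tie_falls_back_to_gps_score(self):
        gps = pd.Series({"l1": 1.0, "l2": 9.0, "l3": 4.0})
        mirna = pd.DataFrame({"l1": [0.0], "l2": [0.0], "l3": [0.0]}, index=["m1"])
        table = integrate_and_sort(gps, mirna, ["m1"])
        assert list(table.index) == ["l2", "l3", "l1"]

    def test_mismatched_lines_rejected(self):
        gps = pd.Series({"l1": 1.0})
        mirna = pd.DataFrame({"l2": [1.0]}, index=["m1"])
        with pytest.raises(ValueError, match="l1"):
            integrate_and_sort(gps, mirna, ["m1"])

    def test_planted_double_positive_block_on_top(self, dataset):
        led = dataset.ledger
        family = led.expression["gps_genes"]
        gps = pd.Series({l: gps_score(dataset.gene_matrix, l, family) for l in dataset.gene_matrix.columns})
        table = integrate_and_sort(gps, dataset.mirna_matrix, C19MC_MEMBERS)
        n = len(led.expression["positive_group"])
        assert sorted(table.index[:n]) == led.expression["positive_group"]


class TestSelectGroups:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["c19mc_cumulative", "gps_score"]).rename_axis("line")

    def test_two_line_toy(self):
        table = pd.DataFrame(
            {"c19mc_cumulative": [10.0, 0.0], "gps_score": [5.0, 0.0]}, index=["pos", "neg"]
        )
        groups = select_groups(table, n=1)
        assert groups.positive == ("pos",) and groups.negative == ("neg",)

    def test_all_positive_is_error(self):
        table = pd.DataFrame(
            {"c19mc_cumulative": [10.0, 9.0], "gps_score": [5.0, 5.0]}, index=["a", "b"]
        )
        with pytest.raises(ValueError, match="insufficient"):
            select_groups(table, n=1)

    def test_planted_memberships_and_stability(self, dataset, config):
        led = dataset.ledger
        family = led.expression["gps_genes"]
        gps = pd.Series({l: gps_score(dataset.gene_matrix, l, family) for l in dataset.gene_matrix.columns})
        table = integrate_and_sort(gps, dataset.mirna_matrix, C19MC_MEMBERS)
        groups = select_groups(table, config.n_per_group)
        assert sorted(groups.positive) == led.expression["positive_group"]
        assert sorted(groups.negative) == led.expression["negative_group"]
        assert select_groups(table, config.n_per_group) == groups  # stable

    def test_groups_disjoint_invariant(self):
        with pytest.raises(ValueError):
            GroupAssignment(positive=("a",), negative=("a",))


class TestDifferentialExpression:
    def _groups(self, matrix, n):
        cols = list(matrix.columns)
        return GroupAssignment(positive=tuple(cols[:n]), negative=tuple(cols[n : 2 * n]))

    def test_label_swap_negates_fc_preserves_p(self, dataset):
        matrix = dataset.gene_matrix
        groups = GroupAssignment(
            positive=tuple(dataset.ledger.expression["positive_group"]),
            negative=tuple(dataset.ledger.expression["negative_group"]),
        )
        swapped = GroupAssignment(positive=groups.negative, negative=groups.positive)
        de1 = {r.gene: r for r in differential_expression(matrix, groups)}
        de2 = {r.gene: r for r in differential_expression(matrix, swapped)}
        for gene in matrix.index:
            assert de1[gene].log2fc == pytest.approx(-de2[gene].log2fc)
            assert de1[gene].p_value == pytest.approx(de2[gene].p_value)

    def test_zero_variance_equal_means_p_one(self):
        matrix = pd.DataFrame({f"l{i}": [4] for i in range(6)}, index=["flat"])
        groups = self._groups(matrix, 3)
        (res,) = differential_expression(matrix, groups)
        assert res.p_value == 1.0 and not res.significant_up

    def test_fold_change_gate_regardless_of_p(self):
        # tiny but extremely consistent difference: significant p, sub-threshold fc
        rng = np.random.default_rng(0)
        pos = 2 ** (5.5 + rng.normal(0, 0.01, 12)) - 1
        neg = 2 ** (5.0 + rng.normal(0, 0.01, 12)) - 1
        matrix = pd.DataFrame([list(pos) + list(neg)], index=["g"],
                              columns=[f"l{i}" for i in range(24)])
        groups = self._groups(matrix, 12)
        (res,) = differential_expression(matrix, groups)
        assert res.p_value < 0.05
        assert not res.significant_up and not res.significant_down

    def test_planted_effects_flagged(self, dataset, config):
        led = dataset.ledger
        groups = GroupAssignment(
            positive=tuple(led.expression["positive_group"]),
            negative=tuple(led.expression["negative_group"]),
        )
        bg = dataset.gene_matrix.loc[list(led.expression["planted_log2fc"])]
        results = {r.gene: r for r in differential_expression(bg, groups)}
        for gene, fc in led.expression["planted_log2fc"].items():
            flagged = results[gene].significant_up or results[gene].significant_down
            if abs(fc) >= 4:
                assert flagged, (gene, fc, results[gene])
                assert results[gene].significant_up == (fc > 0)
            elif fc == 0:
                assert not flagged

    def test_fdr_flag_never_increases_significance(self, dataset):
        led = dataset.ledger
        groups = GroupAssignment(
            positive=tuple(led.expression["positive_group"]),
            negative=tuple(led.expression["negative_group"]),
        )
        raw = differential_expression(dataset.gene_matrix, groups)
        adj = differential_expression(dataset.gene_matrix, groups, fdr=True)
        for r_raw, r_adj in zip(raw, adj):
            assert r_adj.p_value >= r_raw.p_value


class TestDdct:
    def _records(self, control_pairs, treated_pairs, target="miR"):
        recs = []
        for i, (t, n) in enumerate(control_pairs):
            recs.append(QpcrRecord(f"c{i}", target, t, n, "control"))
        for i, (t, n) in enumerate(treated_pairs):
            recs.append(QpcrRecord(f"t{i}", target, t, n, "treated"))
        return recs

    def test_arithmetic_example(self):
        # control ΔCt = 25-20 = 5; treated ΔCt = 22-20 = 2; ΔΔCt = -3 → fold 8
        folds = ddct_fold_change(self._records([(25, 20)], [(22, 20)]))
        assert folds["miR"]["ddct"] == -3
        assert folds["miR"]["fold_change"] == 8
        assert folds["miR"]["control_fold"] == 1.0

    def test_treated_equals_control_fold_one(self):
        folds = ddct_fold_change(self._records([(25, 20)], [(25, 20)]))
        assert folds["miR"]["fold_change"] == 1.0

    def test_hundredfold_closed_form(self):
        ddct = -math.log2(100)
        folds = ddct_fold_change(self._records([(25, 20)], [(25 + ddct, 20)]))
        assert folds["miR"]["fold_change"] == pytest.approx(100.0)

    def test_missing_condition_rejected(self):
        recs = [QpcrRecord("c1", "miR", 25, 20, "control")]
        with pytest.raises(ValueError, match="control and one treated"):
            ddct_fold_change(recs)

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValueError):
            QpcrRecord("s", "miR", -1, 20, "control")
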