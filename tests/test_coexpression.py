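import math

import numpy as np
import pandas as pd
import pytest

from cksr import coexpression as cx


def binary_matrix(values, genes=None):
    arr = np.asarray(values)
    genes = genes or [f"K{i}" for i in range(1, arr.shape[1] + 1)]
    df = pd.DataFrame(arr, columns=genes,
                      index=[f"L{i}" for i in range(1, arr.shape[0] + 1)])
    return cx.BinaryExpressionMatrix(data=df)


class TestLoading:
    def test_ccle_header_cropping(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("cell_line,CDK6 (1021),CDK4 (1019)\nACH-01,3.5,1.0\n")
        m = cx.load_expression_matrix(p, dialect="ccle_csv")
        assert m.genes == ["CDK6", "CDK4"]

    def test_duplicate_symbols_keep_highest_mean(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("cl,AKT1 (1),AKT1 (2)\nA,1.0,5.0\nB,1.0,5.0\n")
        m = cx.load_expression_matrix(p, dialect="ccle_csv")
        assert m.genes == ["AKT1"]
        assert m.n_duplicate_symbols_dropped == 1
        assert m.data["AKT1"].tolist() == [5.0, 5.0]

    def test_values_preserved_exactly(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("cl\tG1\tG2\nA\t0.125\t2.5\nB\t3.75\t0.0\n")
        m = cx.load_expression_matrix(p, dialect="plain_tsv")
        assert m.data.to_numpy().tolist() == [[0.125, 2.5], [3.75, 0.0]]

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("cl,G1 (1)\nA,1.0\nB,oops\n")
        with pytest.raises(cx.MatrixFormatError, match="G1"):
            cx.load_expression_matrix(p, dialect="ccle_csv")


class TestBinarization:
    def test_tpm_cutoff_is_inclusive_in_tpm_space(self):
        # stored log2(TPM+1); TPM >= 10 means stored >= log2(11)
        m = cx.ExpressionMatrix(
            data=pd.DataFrame({"G": [math.log2(11), 3.0, 0.0]}, index=["A", "B", "C"]),
            scale="log2_tpm_plus1",
        )
        b = cx.binarize_expression(m, mode="tpm", tpm_threshold=10)
        assert b.data["G"].tolist() == [1, 0, 0]

    @pytest.mark.parametrize("threshold", [5, 10, 20])
    def test_zero_tpm_never_expressed(self, threshold):
        m = cx.ExpressionMatrix(
            data=pd.DataFrame({"G": [0.0, 0.0]}, index=["A", "B"]), scale="log2_tpm_plus1"
        )
        b = cx.binarize_expression(m, mode="tpm", tpm_threshold=threshold)
        assert not b.data["G"].any()

    def test_median_mode_is_strict(self):
        m = cx.ExpressionMatrix(
            data=pd.DataFrame({"G": [1.0, 2.0, 3.0]}, index=["A", "B", "C"]),
            scale="ms_relative",
        )
        b = cx.binarize_expression(m, mode="median")
        assert b.data["G"].tolist() == [0, 0, 1]  # the median itself is not expressed

    def test_missing_values_not_expressed(self):
        m = cx.ExpressionMatrix(
            data=pd.DataFrame({"G": [1.0, np.nan, 3.0]}, index=["A", "B", "C"]),
            scale="ms_relative",
        )
        b = cx.binarize_expression(m, mode="median")
        assert b.data.loc["B", "G"] == 0

    def test_wrong_scale_mode_pairing_rejected(self):
        m = cx.ExpressionMatrix(
            data=pd.DataFrame({"G": [1.0, 2.0]}, index=["A", "B"]), scale="ms_relative"
        )
        with pytest.raises(ValueError):
            cx.binarize_expression(m, mode="tpm", tpm_threshold=10)

    def test_threshold_spec_recorded(self):
        m = cx.ExpressionMatrix(
            data=pd.DataFrame({"G": [0.0, 4.0]}, index=["A", "B"]), scale="log2_tpm_plus1"
        )
        b = cx.binarize_expression(m, mode="tpm", tpm_threshold=5)
        assert b.threshold_spec["tpm_threshold"] == 5


class TestScoring:
    def test_forty_percent_coexpression(self):
        rows = [[1, 1]] * 4 + [[1, 0], [0, 1], [0, 0]] + [[0, 0]] * 3
        s = cx.coexpression_score("T", {"K1", "K2"}, binary_matrix(rows))
        assert s.score == pytest.approx(40.0)
        assert s.n_lines_coexpressed == 4

    def test_no_overlap_scores_zero(self):
        rows = [[1, 0, 0], [0, 1, 0], [1, 0, 0], [0, 1, 0]]
        s = cx.coexpression_score("T", {"K1", "K2", "K3"}, binary_matrix(rows))
        assert s.score == 0.0

    def test_group_with_one_present_kinase_flagged_unscored(self):
        s = cx.coexpression_score("T", {"K1", "MISSING"}, binary_matrix([[1], [1]], ["K1"]))
        assert not s.scored and s.n_in_matrix == 1

    def test_absent_kinases_do_not_change_score(self):
        rows = [[1, 1], [0, 1], [1, 1]]
        b = binary_matrix(rows)
        s1 = cx.coexpression_score("T", {"K1", "K2"}, b)
        s2 = cx.coexpression_score("T", {"K1", "K2", "GHOST"}, b)
        assert s1.score == s2.score

    def test_adding_a_kinase_never_decreases_score(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, size=(200, 4))
        b = binary_matrix(rows)
        small = cx.coexpression_score("T", {"K1", "K2"}, b).score
        for extra in ("K3", "K4"):
            bigger = cx.coexpression_score("T", {"K1", "K2", extra}, b).score
            assert bigger >= small

    def test_score_invariant_to_cell_line_order(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 2, size=(100, 3))
        b1 = binary_matrix(rows)
        b2 = binary_matrix(rows[::-1])
        g = {"K1", "K2", "K3"}
        assert cx.coexpression_score("T", g, b1).score == cx.coexpression_score("T", g, b2).score

    def test_monotone_in_tpm_threshold(self):
        rng = np.random.default_rng(2)
        stored = np.log2(rng.uniform(0, 40, size=(300, 3)) + 1)
        m = cx.ExpressionMatrix(
            data=pd.DataFrame(stored, columns=["K1", "K2", "K3"],
                              index=[f"L{i}" for i in range(300)]),
            scale="log2_tpm_plus1",
        )
        scores = [
            cx.coexpression_score(
                "T", {"K1", "K2", "K3"},
                cx.binarize_expression(m, mode="tpm", tpm_threshold=t),
            ).score
            for t in (5, 10, 20)
        ]
        assert scores[0] >= scores[1] >= scores[2]


class TestClosedForm:
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_analytic_equals_binomial_tail(self, p, n):
        expected = 1 - (1 - p) ** n - n * p * (1 - p) ** (n - 1)
        assert cx.analytic_coexpression_probability([p] * n) == pytest.approx(expected)

    def test_simulated_score_approaches_analytic(self):
        rng = np.random.default_rng(3)
        p, n = 0.5, 2
        rows = (rng.random((10_000, n)) < p).astype(int)
        s = cx.coexpression_score("T", {"K1", "K2"}, binary_matrix(rows))
        assert s.score == pytest.approx(100 * p * p, abs=2.0)


class TestSummary:
    def _scores(self, values, unscored=0):
        out = [
            cx.CoexpressionScore("T%d" % i, ("A", "B"), 2, 0, 100, v) for i, v in enumerate(values)
        ]
        out += [
            cx.CoexpressionScore("U%d" % i, ("A", "B"), 1, 0, 100, float("nan"), scored=False)
            for i in range(unscored)
        ]
        return out

    def test_median_of_three(self):
        s = cx.score_distribution_summary(self._scores([0.0, 50.0, 100.0]))
        assert s.median == 50.0

    def test_all_high_scores_none_rare(self):
        s = cx.score_distribution_summary(self._scores([100.0] * 5))
        assert s.fraction_below == 0.0

    def test_rarity_cutoff_counts_low_scores(self):
        s = cx.score_distribution_summary(self._scores([1.0, 2.0, 50.0, 99.0]))
        assert s.fraction_below == pytest.approx(50.0)

    def test_unscored_counted_separately(self):
        s = cx.score_distribution_summary(self._scores([10.0], unscored=2))
        assert s.n_scored == 1 and s.n_unscored == 2

    def test_zero_scored_groups_flagged_empty(self):
        s = cx.score_distribution_summary(self._scores([], unscored=1))
        assert s.empty

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 100, size=20).tolist()
        s = cx.score_distribution_summary(self._scores(vals))
        assert s.mean == pytest.approx(sum(vals) / len(vals))
        assert s.fraction_below == pytest.approx(
            100 * sum(1 for v in vals if v < 2.5) / len(vals)
        )
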