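"""CPM normalization, fold-change conventions and the DE test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirhd.de import (
    CountMatrix,
    de_test,
    fold_change,
    log2_transform,
    mean_expression,
    normalize_cpm,
    select_top,
    swap_groups,
    volcano_table,
)
from mirhd.errors import ContractError, NormalizationError, StatisticsError
from mirhd.simulate import SimConfig, gen_counts


def matrix_from(values, n_ctrl, n_dis, index=None):
    values = np.asarray(values)
    cols = [f"c{i}" for i in range(n_ctrl)] + [f"d{i}" for i in range(n_dis)]
    counts = pd.DataFrame(values, columns=cols, index=index)
    groups = pd.Series(["control"] * n_ctrl + ["disease"] * n_dis, index=cols)
    return CountMatrix(counts, groups)


class TestNormalizeCPM:
    def test_single_mirna_column(self):
        m = matrix_from([[10, 10, 10, 10]], 2, 2)
        norm = normalize_cpm(m)
        assert (norm.counts.values == 1_000_000).all()

    def test_proportions(self):
        m = matrix_from([[1, 1], [1, 1], [2, 2]], 1, 1)
        norm = normalize_cpm(m)
        np.testing.assert_allclose(
            norm.counts.iloc[:, 0], [250_000, 250_000, 500_000]
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_sum_to_1e6(self, seed):
        rng = np.random.default_rng(seed)
        m = matrix_from(rng.integers(1, 1000, size=(30, 6)), 3, 3)
        norm = normalize_cpm(m)
        np.testing.assert_allclose(norm.counts.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_column_names_sample(self):
        m = matrix_from([[0, 5], [0, 5]], 1, 1)
        with pytest.raises(NormalizationError, match="c0"):
            normalize_cpm(m)

    def test_double_normalization_rejected(self):
        m = normalize_cpm(matrix_from([[1, 1]], 1, 1))
        with pytest.raises(ContractError):
            normalize_cpm(m)


class TestLog2:
    def test_zero_entry_with_unit_pseudocount(self):
        m = CountMatrix(
            pd.DataFrame([[0.0, 4.0]], columns=["a", "b"]),
            pd.Series(["control", "disease"], index=["a", "b"]),
            normalized=True,
        )
        assert log2_transform(m, pseudocount=1.0).iloc[0, 0] == pytest.approx(0.0)

    def test_value_1024_pc0(self):
        m = CountMatrix(
            pd.DataFrame([[1024.0, 1024.0]], columns=["a", "b"]),
            pd.Series(["control", "disease"], index=["a", "b"]),
            normalized=True,
        )
        assert log2_transform(m, 0.0).iloc[0, 0] == pytest.approx(10.0)

    def test_zero_with_zero_pseudocount_rejected(self):
        m = CountMatrix(
            pd.DataFrame([[0.0, 1.0]], columns=["a", "b"]),
            pd.Series(["control", "disease"], index=["a", "b"]),
            normalized=True,
        )
        with pytest.raises(ContractError):
            log2_transform(m, 0.0)

    def test_monotone(self):
        assert np.log2(3 + 1) < np.log2(7 + 1)


class TestFoldChange:
    @pytest.mark.parametrize(
        "mc, md, expected",
        [
            (10_239, 40_520, 3.96),  # worked example, 2-dp presentation
            (100.0, 100.0, 1.00),
            (100.0, 25.0, -4.00),
        ],
    )
    def test_convention(self, mc, md, expected):
        assert round(fold_change(mc, md), 2) == pytest.approx(expected)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ContractError):
            fold_change(0, 10)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.5, 1e5, allow_nan=False), st.floats(0.5, 1e5, allow_nan=False)
    )
    def test_antisymmetry(self, a, b):
        """Swapping group roles flips the sign and keeps the magnitude."""
        f, g = fold_change(a, b), fold_change(b, a)
        if a != b:
            assert f == pytest.approx(-g)
        assert abs(f) >= 1.0


class TestMeanExpression:
    @pytest.mark.parametrize(
        "mc, md, expected",
        [(10_239, 40_520, 14.63), (46, 3, 4.61), (1, 1, 0.0)],
    )
    def test_examples(self, mc, md, expected):
        assert round(mean_expression(mc, md), 2) == pytest.approx(expected)

    def test_symmetric_in_groups(self):
        assert mean_expression(46, 3) == mean_expression(3, 46)

    def test_nonpositive_rejected(self):
        with pytest.raises(ContractError):
            mean_expression(-1, 5)


class TestDETest:
    def test_identical_groups_yield_zero_de_calls(self):
        m = normalize_cpm(matrix_from(np.full((10, 8), 7), 4, 4))
        res = de_test(m)
        assert res.n_de == 0
        assert (res.records["p_raw"] == 1.0).all()

    def test_bh_step_up_hand_example(self):
        """BH on p=[0.01,0.02,0.03] with m=3 gives [0.03,0.03,0.03]."""
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_p_adj_never_below_p_raw(self, small_matrix):
        res = de_test(normalize_cpm(small_matrix))
        assert (res.records["p_adj"] >= res.records["p_raw"] - 1e-12).all()

    def test_fewer_than_two_replicates_rejected(self):
        m = normalize_cpm(matrix_from([[1, 2, 3]], 1, 2))
        with pytest.raises(StatisticsError):
            de_test(m)

    def test_planted_direction_matches_truth_at_strong_fc(self):
        """Significant calls on planted |FC| ≥ 4 miRNAs never flip sign."""
        cfg = SimConfig(
            seed=42, n_mirna=400, n_per_group=4,
            frac_up=0.063, frac_down=0.114, fc_range=(4.0, 18.0), dispersion=0.1,
        )
        raw, truth = gen_counts(cfg)
        res = de_test(normalize_cpm(raw))
        merged = res.records.merge(truth.mirna, on="mirna_id")
        planted_sig = merged[
            (merged["direction_y"] != "null") & (merged["direction_x"] != "null")
        ]
        assert len(planted_sig) > 0
        assert (planted_sig["direction_x"] == planted_sig["direction_y"]).all()

    def test_group_swap_flips_fold_change_sign(self, small_matrix):
        norm = normalize_cpm(small_matrix)
        a = de_test(norm).records
        b = de_test(swap_groups(norm)).records
        np.testing.assert_allclose(a["fold_change"], -b["fold_change"])
        np.testing.assert_allclose(a["mean_expression"], b["mean_expression"])
        np.testing.assert_allclose(a["p_raw"], b["p_raw"])

    def test_scaling_one_sample_leaves_statistics_unchanged(self, small_matrix):
        """CPM absorbs per-sample scale factors, so DE is equivariant."""
        scaled = small_matrix.counts.copy()
        scaled["s0"] = scaled["s0"] * 17
        m2 = CountMatrix(scaled, small_matrix.groups.copy())
        a = de_test(normalize_cpm(small_matrix)).records
        b = de_test(normalize_cpm(m2)).records
        pd.testing.assert_frame_equal(a, b)


class TestSelectTop:
    def _records(self, n_up, n_down, n_null):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(n_up + n_down + n_null):
            direction = "up" if i < n_up else "down" if i < n_up + n_down else "null"
            fc = 2.0 if direction == "up" else -3.0 if direction == "down" else 1.0
            rows.append(
                {
                    "mirna_id": f"m{i:03d}",
                    "fold_change": fc + rng.uniform(0, 1),
                    "p_adj": float(rng.uniform(0, 0.04 if direction != "null" else 1)),
                    "direction": direction,
                }
            )
        return pd.DataFrame(rows)

    def test_top_8_plus_10_gives_18(self):
        recs = self._records(126, 228, 0)
        top = select_top(recs, 8, 10)
        assert len(top) == 18
        assert list(top["direction"]) == ["up"] * 8 + ["down"] * 10
        up = top[top["direction"] == "up"]
        assert up["p_adj"].is_monotonic_increasing

    def test_k_up_zero_gives_only_down(self):
        top = select_top(self._records(5, 5, 5), 0, 3)
        assert set(top["direction"]) == {"down"}

    def test_all_null_selection_empty_with_warning(self):
        with pytest.warns(UserWarning):
            top = select_top(self._records(0, 0, 5), 8, 10)
        assert top.empty


class TestVolcano:
    def test_examples_and_row_count(self):
        recs = pd.DataFrame(
            {
                "mirna_id": ["a", "b"],
                "fold_change": [2.0, -4.0],
                "p_adj": [0.01, 0.0001],
                "direction": ["up", "down"],
            }
        )
        v = volcano_table(recs)
        assert len(v) == len(recs)
        assert v.loc[0, "log2_fold_change"] == pytest.approx(1.0)
        assert v.loc[0, "neg_log10_p_adj"] == pytest.approx(2.0)
        assert v.loc[1, "log2_fold_change"] == pytest.approx(-2.0)
        assert v.loc[1, "neg_log10_p_adj"] == pytest.approx(4.0)
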