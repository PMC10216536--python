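"""The fixed conditioning chain: QC, imputation, log, batch scale, winsorize."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_

from ctcmorph import preprocess as pp


def frame(data, columns=None):
    return pd.DataFrame(data, columns=columns)


class TestQC:
    def test_all_missing_row_dropped(self):
        df = frame(np.ones((10, 4)))
        df.iloc[3] = np.nan
        out, report = pp.qc_filter(df)
        assert len(out) == 9
        assert report.n_cells_dropped == 1
        assert 3 not in out.index

    def test_no_missing_is_identity(self):
        df = frame(np.arange(12.0).reshape(4, 3))
        out, report = pp.qc_filter(df)
        assert out.equals(df)
        assert report.n_cells_dropped == report.n_features_dropped == 0

    def test_all_missing_column_dropped(self):
        df = frame(np.ones((5, 3)), columns=list("abc"))
        df["b"] = np.nan
        out, report = pp.qc_filter(df)
        assert list(out.columns) == ["a", "c"]
        assert report.n_features_dropped == 1

    def test_nothing_survives_is_hard_error(self):
        df = frame(np.full((3, 3), np.nan))
        with pytest.raises(ValueError, match="no cells survive"):
            pp.qc_filter(df)

    def test_report_conserves_cells(self):
        df = frame(np.ones((8, 3)))
        df.iloc[[1, 5]] = np.nan
        out, report = pp.qc_filter(df)
        assert report.n_cells_in == len(out) + report.n_cells_dropped


class TestImpute:
    def test_mean_of_observed(self):
        df = frame({"f": [1.0, 2.0, np.nan]})
        out, n = pp.impute_mean(df)
        assert out["f"].tolist() == [1.0, 2.0, 1.5]
        assert n == 1

    def test_no_missing_identity(self):
        df = frame({"f": [1.0, 2.0]})
        out, n = pp.impute_mean(df)
        assert out.equals(df) and n == 0

    def test_single_observed_value_broadcast(self):
        df = frame({"f": [5.0, np.nan, np.nan]})
        out, _ = pp.impute_mean(df)
        assert out["f"].tolist() == [5.0, 5.0, 5.0]

    def test_all_missing_column_is_error(self):
        df = frame({"f": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="qc_filter"):
            pp.impute_mean(df)


class TestLogTransform:
    def test_fixed_points(self):
        df = frame({"f": [0.0, np.e - 1, -(np.e - 1)]})
        out = pp.log_transform(df)
        assert out["f"].tolist() == pytest.approx([0.0, 1.0, -1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st_.floats(-1e6, 1e6), st_.floats(-1e6, 1e6))
    def test_strictly_monotone(self, x, y):
        if x == y:
            return
        lo, hi = sorted([x, y])
        out = pp.log_transform(frame({"f": [lo, hi]}))
        assert out["f"].iloc[0] < out["f"].iloc[1]


class TestBatchScale:
    def test_per_batch_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        df = frame(rng.normal(5, 3, size=(40, 6)))
        batches = pd.Series([0] * 25 + [1] * 15, index=df.index)
        out, constant = pp.batch_scale(df, batches)
        for _, sub in out.groupby(batches):
            assert np.abs(sub.mean()).max() < 1e-9
            assert sub.std(ddof=1).values == pytest.approx(np.ones(6))
        assert constant == {}

    def test_single_batch_equals_global_zscore(self):
        rng = np.random.default_rng(1)
        df = frame(rng.normal(size=(12, 3)))
        out, _ = pp.batch_scale(df, pd.Series(0, index=df.index))
        expected = (df - df.mean()) / df.std(ddof=1)
        pd.testing.assert_frame_equal(out, expected)

    def test_additive_batch_shift_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=30)
        df = frame({"f": np.concatenate([base, base + 7.0])})
        batches = pd.Series([0] * 30 + [1] * 30)
        out, _ = pp.batch_scale(df, batches)
        means = out.groupby(batches)["f"].mean()
        assert np.abs(means).max() < 1e-9

    def test_constant_feature_flagged_and_zeroed(self):
        df = frame({"f": [1.0, 1.0, 1.0, 2.0, 3.0, 4.0]})
        batches = pd.Series([0, 0, 0, 1, 1, 1])
        out, constant = pp.batch_scale(df, batches)
        assert (out.loc[batches == 0, "f"] == 0.0).all()
        assert constant == {0: ["f"]}

    def test_singleton_batch_is_error(self):
        df = frame(np.ones((3, 2)))
        with pytest.raises(ValueError, match="size < 2"):
            pp.batch_scale(df, pd.Series([0, 0, 1]))


class TestWinsorize:
    def test_hand_computed_upper_outlier(self):
        """Values 1..9 plus 100: q1=3.25, q3=7.75, IQR=4.5, upper fence
        21.25 — only the 100 is replaced, by q3."""
        df = frame({"f": [1, 2, 3, 4, 5, 6, 7, 8, 9, 100.0]})
        params = pp.WinsorizeParams.from_table(df)
        assert params.q1["f"] == pytest.approx(3.25)
        assert params.q3["f"] == pytest.approx(7.75)
        out, n_low, n_high = pp.winsorize_iqr(df, params)
        assert out["f"].tolist() == [1, 2, 3, 4, 5, 6, 7, 8, 9, 7.75]
        assert (n_low, n_high) == (0, 1)

    def test_constant_feature_untouched(self):
        df = frame({"f": [3.0] * 8})
        out, n_low, n_high = pp.winsorize_iqr(
            df, pp.WinsorizeParams.from_table(df))
        assert out.equals(df) and n_low == 0 and n_high == 0

    def test_literal_fence_flags_bulk_as_low(self):
        """The printed lower-fence formula (q1 + 3·IQR) marks most of the
        distribution as lower outliers; the corrected fence flags only the
        extreme point."""
        df = frame({"f": [-100, 1, 2, 3, 4, 5, 6, 7, 8, 9.0]})
        lit = pp.WinsorizeParams.from_table(df, fence_mode="literal")
        _, n_low_lit, _ = pp.winsorize_iqr(df, lit)
        cor = pp.WinsorizeParams.from_table(df, fence_mode="corrected")
        _, n_low_cor, _ = pp.winsorize_iqr(df, cor)
        assert n_low_lit > len(df) / 2
        assert n_low_cor == 1

    def test_unknown_fence_mode_raises(self):
        df = frame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError, match="fence_mode"):
            pp.WinsorizeParams.from_table(df, fence_mode="bogus")

    @settings(derandomize=True, max_examples=30)
    @given(st_.lists(st_.floats(-1e4, 1e4), min_size=5, max_size=40))
    def test_output_bounded_by_fences_and_quartiles(self, values):
        df = frame({"f": values})
        params = pp.WinsorizeParams.from_table(df)
        lower, upper = params.fences()
        out, _, _ = pp.winsorize_iqr(df, params)
        assert (out["f"] >= min(lower["f"], params.q1["f"]) - 1e-9).all()
        assert (out["f"] <= max(upper["f"], params.q3["f"]) + 1e-9).all()

    def test_idempotent_on_reapplication(self):
        rng = np.random.default_rng(3)
        df = frame({"f": np.concatenate([rng.normal(size=50), [40.0, -35.0]])})
        params = pp.WinsorizeParams.from_table(df)
        once, n_low1, n_high1 = pp.winsorize_iqr(df, params)
        twice, n_low2, n_high2 = pp.winsorize_iqr(
            once, pp.WinsorizeParams.from_table(once))
        assert n_low2 + n_high2 <= n_low1 + n_high1
        pd.testing.assert_frame_equal(twice, once)


class TestPipelineOrder:
    def test_out_of_order_call_raises(self):
        df = frame(np.ones((4, 2)))
        proc = pp.Preprocessor()
        with pytest.raises(RuntimeError, match="out of order"):
            proc.impute(df)

    def test_full_chain_report(self):
        rng = np.random.default_rng(4)
        df = frame(rng.normal(10, 2, size=(20, 5)))
        df.iloc[0] = np.nan           # dropped cell
        df.iloc[5, 2] = np.nan        # imputed entry
        batches = pd.Series([0] * 10 + [1] * 10, index=df.index)
        clean, report = pp.preprocess_table(df, batches)
        assert report.n_cells_in == 20
        assert report.n_cells_out == len(clean) == 19
        assert report.n_cells_dropped == 1
        assert report.n_imputed == 1
        assert report.n_cells_in == report.n_cells_out + report.n_cells_dropped
        # post-scaling, pre-winsorize means are 0 per batch; winsorization
        # with multiplier 3 rarely moves anything on Gaussian data
        assert np.abs(clean.to_numpy()).max() < 10
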