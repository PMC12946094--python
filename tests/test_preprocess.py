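"""Readers, epoch cleaning, std-resampling and merging."""

import io

import numpy as np
import pandas as pd
import pytest

from glycograd import (clean_epochs, merge_streams, read_actigraphy, read_cgm,
                       resample_activity, resample_glucose)
from glycograd.errors import ConfigurationError, ParseError


def _acti_csv(rows):
    return io.StringIO("timestamp,activity_count,interval_status\n"
                       + "\n".join(rows) + "\n")


def _cgm_csv(rows):
    return io.StringIO("timestamp,glucose_mmol_l\n" + "\n".join(rows) + "\n")


class TestReaders:
    def test_actigraphy_row_parsed(self):
        df = read_actigraphy(_acti_csv(["2024-03-04T10:00:30,45,ACTIVE"]))
        assert df.loc[0, "timestamp"] == pd.Timestamp("2024-03-04 10:00:30")
        assert df.loc[0, "activity_count"] == 45
        assert df.loc[0, "interval_status"] == "ACTIVE"

    def test_empty_file_gives_empty_stream(self):
        assert read_actigraphy(io.StringIO("")).empty

    def test_out_of_order_rows_resorted(self):
        df = read_actigraphy(_acti_csv(["2024-03-04T10:00:30,1,REST",
                                        "2024-03-04T10:00:15,2,REST"]))
        assert df["timestamp"].is_monotonic_increasing

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            read_actigraphy(_acti_csv(["2024-03-04T10:00:15,1,REST",
                                       "2024-03-04T10:00:15,2,REST"]))

    def test_negative_count_rejected_with_line_number(self):
        with pytest.raises(ParseError, match="line 3"):
            read_actigraphy(_acti_csv(["2024-03-04T10:00:15,1,REST",
                                       "2024-03-04T10:00:30,-4,REST"]))

    def test_malformed_timestamp_rejected(self):
        with pytest.raises(ParseError, match="timestamp"):
            read_actigraphy(_acti_csv(["not-a-time,1,REST"]))

    def test_cgm_row_parsed(self):
        df = read_cgm(_cgm_csv(["2024-03-04T10:00:00,7.0"]))
        assert df.loc[0, "glucose_mmol_l"] == 7.0

    @pytest.mark.parametrize("value", ["0", "35"])
    def test_cgm_out_of_range_rejected(self, value):
        with pytest.raises(ParseError, match="out of range"):
            read_cgm(_cgm_csv([f"2024-03-04T10:00:00,{value}"]))

    def test_mgdl_magnitude_hint(self):
        with pytest.raises(ParseError, match="mg/dL"):
            read_cgm(_cgm_csv(["2024-03-04T10:00:00,170"]))

    def test_column_mapping_for_vendor_export(self):
        src = io.StringIO("Time,Counts,Status\n2024-03-04T10:00:15,5,REST\n")
        df = read_actigraphy(src, column_map={"Time": "timestamp",
                                              "Counts": "activity_count",
                                              "Status": "interval_status"})
        assert df.loc[0, "activity_count"] == 5


class TestCleanEpochs:
    @staticmethod
    def _frame(statuses):
        return pd.DataFrame({
            "timestamp": pd.date_range("2024-03-04 10:00:15", periods=len(statuses),
                                       freq="15s"),
            "activity_count": np.arange(len(statuses), dtype=float),
            "interval_status": statuses,
        })

    def test_sleep_and_excluded_dropped_rest_normalised(self):
        out = clean_epochs(self._frame(["ACTIVE", "REST-S", "R", "EXCLUDED", "ACTIVE"]))
        assert list(out["interval_status"]) == ["ACTIVE", "REST", "ACTIVE"]

    def test_all_sleep_gives_empty_stream(self):
        assert clean_epochs(self._frame(["REST-S"] * 4)).empty

    def test_substring_rule_on_novel_label(self):
        out = clean_epochs(self._frame(["ACTIVE-X"]))
        assert list(out["interval_status"]) == ["ACTIVE"]

    def test_cleaning_is_idempotent(self):
        once = clean_epochs(self._frame(["ACTIVE", "R", "REST-S", "ACTIVE"]))
        twice = clean_epochs(once)
        pd.testing.assert_frame_equal(once, twice)


class TestResample:
    @staticmethod
    def _epochs(counts, statuses=None, start="2024-03-04 10:00:15"):
        n = len(counts)
        return pd.DataFrame({
            "timestamp": pd.date_range(start, periods=n, freq="15s"),
            "activity_count": np.asarray(counts, dtype=float),
            "interval_status": statuses or ["REST"] * n,
        })

    def test_sample_std_oracle(self):
        out = resample_activity(self._epochs([18, 45, 62, 38]), 20)
        assert out.loc[0, "activity_std"] == pytest.approx(18.2094, abs=1e-4)

    def test_constant_counts_zero_std(self):
        out = resample_activity(self._epochs([10, 10, 10, 10]), 20)
        assert out.loc[0, "activity_std"] == 0.0

    def test_any_active_epoch_makes_window_active_and_right_labelled(self):
        out = resample_activity(
            self._epochs([1, 2, 3, 4], ["REST", "ACTIVE", "ACTIVE", "REST"]), 20)
        assert out.loc[0, "status"] == "ACTIVE"
        assert out.loc[0, "window_end"] == pd.Timestamp("2024-03-04 10:20:00")

    def test_window_is_half_open_right(self):
        # an epoch exactly at the boundary belongs to the earlier window
        epochs = self._epochs([5, 7], start="2024-03-04 10:19:45")
        out = resample_activity(epochs, 20)
        assert list(out["window_end"]) == [pd.Timestamp("2024-03-04 10:20:00")]
        assert list(out["n_activity"]) == [2]

    def test_nonstandard_width_needs_override(self):
        with pytest.raises(ConfigurationError):
            resample_activity(self._epochs([1, 2]), 30)
        out = resample_activity(self._epochs([1, 2]), 30,
                                allow_nonstandard_width=True)
        assert not out.empty

    def test_no_samples_invented(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, 500)
        out = resample_activity(self._epochs(counts), 20)
        assert out["n_activity"].sum() <= len(counts)

    def test_windowed_std_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = int(rng.integers(10, 300))
            counts = rng.gamma(2.0, 20.0, n)
            epochs = self._epochs(counts)
            out = resample_activity(epochs, 20).set_index("window_end")
            # brute force: assign each epoch to its half-open window
            ends = epochs["timestamp"].dt.ceil("20min")
            for end, group in epochs.groupby(ends):
                expected = group["activity_count"].std(ddof=1)
                got = out.loc[end, "activity_std"]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)

    def test_population_std_flag(self):
        out = resample_activity(self._epochs([18, 45, 62, 38]), 20, ddof=0)
        assert out.loc[0, "activity_std"] == pytest.approx(
            np.std([18, 45, 62, 38]), abs=1e-9)

    def test_glucose_level_is_last_in_window(self):
        cgm = pd.DataFrame({
            "timestamp": pd.date_range("2024-03-04 10:05", periods=4, freq="5min"),
            "glucose_mmol_l": [7.0, 7.2, 7.1, 6.9],
        })
        out = resample_glucose(cgm, 20)
        assert out.loc[0, "glucose_level"] == 6.9
        assert out.loc[0, "n_glucose"] == 4


class TestMerge:
    @staticmethod
    def _pa(ends, width=20, std=1.0):
        return pd.DataFrame({"window_end": pd.to_datetime(ends),
                             "width_minutes": width, "activity_std": std,
                             "status": "REST", "n_activity": 4})

    @staticmethod
    def _bg(ends, width=20, std=0.1, level=7.0):
        return pd.DataFrame({"window_end": pd.to_datetime(ends),
                             "width_minutes": width, "glucose_std": std,
                             "glucose_level": level, "n_glucose": 4})

    def test_inner_join_on_window_end(self):
        merged = merge_streams(self._pa(["2024-03-04 10:20", "2024-03-04 10:40"]),
                               self._bg(["2024-03-04 10:40", "2024-03-04 11:00"]))
        assert list(merged["window_end"]) == [pd.Timestamp("2024-03-04 10:40")]

    def test_identical_keys_all_retained(self):
        ends = ["2024-03-04 10:20", "2024-03-04 10:40"]
        assert len(merge_streams(self._pa(ends), self._bg(ends))) == 2

    def test_null_summary_window_dropped(self):
        bg = self._bg(["2024-03-04 10:20", "2024-03-04 10:40"])
        bg.loc[0, "glucose_std"] = np.nan
        merged = merge_streams(self._pa(["2024-03-04 10:20", "2024-03-04 10:40"]), bg)
        assert list(merged["window_end"]) == [pd.Timestamp("2024-03-04 10:40")]

    def test_mismatched_widths_rejected(self):
        with pytest.raises(ConfigurationError, match="width"):
            merge_streams(self._pa(["2024-03-04 10:20"], width=20),
                          self._bg(["2024-03-04 10:20"], width=40))
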