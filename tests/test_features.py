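"""Beat features, standardization and sequence assembly."""

import numpy as np
import pandas as pd
import pytest

from bpbeat import features as ft
from bpbeat import preprocess as pp
from bpbeat.protocols import events_from_truth


def two_beat_events():
    return pp.BeatEvents(
        r_times=np.array([1000.0, 1800.0]),
        i_times=np.array([np.nan, 1940.0]),
        j_times=np.array([np.nan, 1960.0]),
        dppg_times=np.array([np.nan, 2050.0]),
        r_amp=np.array([1.0, 1.1]), j_amp=np.array([np.nan, 0.9]),
        dppg_amp=np.array([np.nan, 5.0]),
        valid_r=np.array([True, True]), valid_i=np.array([False, True]),
        valid_j=np.array([False, True]), valid_dppg=np.array([False, True]))


class TestExtract:
    def test_interval_arithmetic(self):
        """R at 1000/1800, I 1940, J 1960, dPPG 2050 -> RRI 800, RJI 160,
        IPI 110, PTT 250."""
        ev = two_beat_events()
        rows = ft.extract_beat_features(ev, np.array([1000.0, 1800.0]),
                                        np.array([110.0, 112.0]),
                                        np.array([70.0, 71.0]))
        assert len(rows) == 1
        r = rows.iloc[0]
        assert r["rri"] == 800.0 and r["rji"] == 160.0
        assert r["ipi"] == 110.0 and r["ptt"] == 250.0
        assert r["ref_sbp"] == 112.0 and bool(r["valid"])

    def test_missing_j_keeps_partial_intervals(self):
        ev = two_beat_events()
        ev.j_times[1] = np.nan
        ev.valid_j[1] = False
        rows = ft.extract_beat_features(ev, np.array([1000.0, 1800.0]),
                                        np.array([110.0, 112.0]),
                                        np.array([70.0, 71.0]))
        r = rows.iloc[0]
        assert not r["valid"]
        assert r["rri"] == 800.0 and r["ptt"] == 250.0
        assert np.isnan(r["rji"])

    def test_fewer_than_two_beats_empty(self):
        ev = two_beat_events()
        ev.valid_r[0] = False
        rows = ft.extract_beat_features(ev, np.array([1800.0]),
                                        np.array([112.0]), np.array([71.0]))
        assert len(rows) == 0

    def test_brute_force_oracle_equivalence(self, clean_record):
        """Rows from truth events must equal a plain-Python recomputation of
        the interval definitions, exactly."""
        tr = clean_record.truth_events
        ev = events_from_truth(tr)
        rows = ft.extract_beat_features(ev, clean_record.beat_times,
                                        clean_record.ref_sbp,
                                        clean_record.ref_dbp)
        r_ms = tr["r_ms"].to_numpy()
        for _, row in rows.iterrows():
            i = int(row["beat"])
            assert row["rri"] == r_ms[i] - r_ms[i - 1]
            assert row["ptt"] == tr["dppg_ms"].iloc[i] - r_ms[i]
            assert row["rji"] == tr["j_ms"].iloc[i] - r_ms[i]
            assert row["ipi"] == tr["dppg_ms"].iloc[i] - tr["i_ms"].iloc[i]
            assert row["ref_sbp"] == clean_record.ref_sbp[i]

    def test_detected_rows_match_truth_rows_within_one_sample(self, clean_record):
        """On noiseless data the detected-event features agree with the
        truth-event features to the sample grid (1 ms at 1 kHz)."""
        det = pp.detect_beat_events(clean_record.ecg, clean_record.bcg,
                                    clean_record.ppg, clean_record.fs)
        rows_det = ft.extract_beat_features(det, clean_record.beat_times,
                                            clean_record.ref_sbp,
                                            clean_record.ref_dbp)
        rows_tru = ft.extract_beat_features(events_from_truth(clean_record.truth_events),
                                            clean_record.beat_times,
                                            clean_record.ref_sbp,
                                            clean_record.ref_dbp)
        n = min(len(rows_det), len(rows_tru))
        both = rows_det["valid"].to_numpy()[:n] & rows_tru["valid"].to_numpy()[:n]
        assert both.mean() > 0.98
        for col, tol in (("rri", 2.0), ("ptt", 2.0), ("rji", 2.0), ("ipi", 2.0)):
            d = (rows_det[col].to_numpy()[:n] - rows_tru[col].to_numpy()[:n])[both]
            assert np.max(np.abs(d)) <= tol   # two fiducials, 1 sample each


class TestStandardization:
    def make_rows(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, 7)), columns=ft.FEATURE_COLUMNS)
        df["valid"] = True
        return df

    def test_constant_feature_rejected_by_name(self):
        rows = self.make_rows()
        rows["rji"] = 5.0
        with pytest.raises(ValueError, match="rji"):
            ft.fit_standardization(rows)

    def test_roundtrip_inverse(self):
        rows = self.make_rows()
        stats = ft.fit_standardization(rows)
        back = ft.invert_standardization(ft.apply_standardization(rows, stats), stats)
        np.testing.assert_allclose(back[ft.FEATURE_COLUMNS].to_numpy(),
                                   rows[ft.FEATURE_COLUMNS].to_numpy(), atol=1e-12)

    def test_training_rows_become_zero_mean_unit_sd(self):
        rows = self.make_rows(200, seed=1)
        stats = ft.fit_standardization(rows)
        out = ft.apply_standardization(rows, stats)
        assert np.all(np.abs(out[ft.FEATURE_COLUMNS].mean()) < 1e-10)
        assert np.all(np.abs(out[ft.FEATURE_COLUMNS].std(ddof=0) - 1) < 1e-10)

    def test_stats_ignore_nontraining_rows(self):
        """Leakage guard: statistics fitted on a training subset are
        unaffected by arbitrary changes to other rows."""
        rows = self.make_rows(100, seed=2)
        train = rows.iloc[:60]
        stats_a = ft.fit_standardization(train)
        perturbed = rows.copy()
        perturbed.iloc[60:, :7] = 999.0
        stats_b = ft.fit_standardization(perturbed.iloc[:60])
        pd.testing.assert_series_equal(stats_a.mean, stats_b.mean)

    def test_array_input(self):
        X = np.random.default_rng(3).normal(size=(40, 10, 7))
        stats = ft.fit_standardization(X)
        Xs = ft.apply_standardization(X, stats)
        flat = Xs.reshape(-1, 7)
        assert np.all(np.abs(flat.mean(axis=0)) < 1e-10)


def make_row_frame(n=12, all_valid=True):
    df = pd.DataFrame({
        "beat": np.arange(1, n + 1),
        "beat_time": 1000.0 + 800.0 * np.arange(n),
        "ref_sbp": 110.0 + np.arange(n), "ref_dbp": 70.0 + np.arange(n),
        "valid": all_valid,
    })
    for i, f in enumerate(ft.FEATURE_COLUMNS):
        df[f] = np.arange(n, dtype=float) + 10.0 * i
    return df


class TestSequences:
    def test_count_all_valid(self):
        X, y, meta = ft.assemble_sequences(make_row_frame(12), L=10)
        assert X.shape == (3, 10, 7)
        assert y.shape == (3, 2)

    def test_single_invalid_row_blocks_every_window(self):
        rows = make_row_frame(12)
        rows.loc[5, "valid"] = False   # row index 5 = 6th row
        X, _, _ = ft.assemble_sequences(rows, L=10)
        assert len(X) == 0

    def test_feature_subset_shapes(self):
        X, _, _ = ft.assemble_sequences(make_row_frame(12), L=10, feature_set="ecg")
        assert X.shape == (3, 10, 2)
        X, _, _ = ft.assemble_sequences(make_row_frame(12), L=10,
                                        feature_set="ecg+bcg")
        assert X.shape[2] == 4

    def test_label_is_final_beat_reference(self):
        rows = make_row_frame(12)
        _, y, meta = ft.assemble_sequences(rows, L=10)
        # first window ends at row index 9 -> its reference BP
        assert y[0, 0] == rows.loc[9, "ref_sbp"]
        assert y[-1, 0] == rows.loc[11, "ref_sbp"]

    def test_gap_splits_windows(self):
        rows = make_row_frame(20)
        rows.loc[10, "beat_time"] += 5000.0   # > 3 s gap
        rows.loc[11:, "beat_time"] += 5000.0
        X, _, meta = ft.assemble_sequences(rows, L=10)
        # only the windows entirely on one side of the gap survive:
        # rows 0-9 (end 9) and rows 10-19 (end 19)
        assert sorted(meta["end_index"]) == [9, 19]

    def test_invalid_L(self):
        with pytest.raises(ValueError):
            ft.assemble_sequences(make_row_frame(12), L=0)


class TestCoverage:
    def test_all_valid_closed_form(self):
        rows = make_row_frame(40)
        for L in (1, 5, 10):
            assert ft.compute_coverage(rows, L) == pytest.approx((40 - L + 1) / 40)

    def test_nonincreasing_in_length(self):
        rng = np.random.default_rng(4)
        rows = make_row_frame(120)
        rows["valid"] = rng.random(120) > 0.1
        cov = [ft.compute_coverage(rows, L) for L in range(1, 31)]
        assert all(a >= b for a, b in zip(cov, cov[1:]))

    def test_invalid_fraction_drives_L1_coverage(self):
        rows = make_row_frame(400)
        rng = np.random.default_rng(5)
        rows["valid"] = rng.random(400) > 0.19
        cov1 = ft.compute_coverage(rows, 1)
        assert cov1 == pytest.approx(rows["valid"].mean())
        assert abs(cov1 - 0.81) < 0.06

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            ft.compute_coverage(make_row_frame(0), 1)
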