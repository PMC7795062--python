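"""Filtering and fiducial detection."""

import numpy as np
import pytest

from bpbeat import preprocess as pp

FS = 1000.0


def sine(freq, dur=10.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def rms(x):
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


class TestBandpass:
    def test_powerline_attenuation_matches_designed_response(self):
        """50 Hz through the 0.5-35 Hz ECG band is attenuated exactly as the
        designed zero-phase Butterworth's frequency response predicts
        (|H(50)|^2 for the forward-backward pass, about 0.22)."""
        from scipy import signal as sps

        spec = pp.DEFAULT_BANDS["ecg"]
        sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz],
                         btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[50.0], fs=FS)
        expected_gain = float(np.abs(h[0]) ** 2)   # filtfilt squares |H|
        x = sine(50.0, dur=30.0)
        out = pp.bandpass(x, spec, FS)
        core = slice(5000, -5000)   # drop filter edge transients
        assert rms(out[core]) / rms(x[core]) == pytest.approx(expected_gain, rel=0.05)
        assert expected_gain < 0.3

    def test_dc_removed(self):
        out = pp.bandpass(np.full(5000, 3.7), pp.DEFAULT_BANDS["ppg"], FS)
        assert np.max(np.abs(out)) < 1e-6 * 3.7

    def test_inband_tone_preserved_by_bcg_band(self):
        x = sine(10.0)
        out = pp.bandpass(x, pp.DEFAULT_BANDS["bcg"], FS)
        assert abs(rms(out) - rms(x)) < 0.2 * rms(x)

    def test_length_preserved(self):
        x = np.random.default_rng(0).standard_normal(4321)
        assert len(pp.bandpass(x, pp.DEFAULT_BANDS["ecg"], FS)) == 4321

    def test_near_idempotent_for_inband_content(self):
        x = sine(10.0)
        once = pp.bandpass(x, pp.DEFAULT_BANDS["bcg"], FS)
        twice = pp.bandpass(once, pp.DEFAULT_BANDS["bcg"], FS)
        assert abs(rms(twice) - rms(once)) < 0.25 * rms(once)

    @pytest.mark.parametrize("low,high", [(0.0, 10.0), (10.0, 5.0), (1.0, 600.0)])
    def test_invalid_band_rejected(self, low, high):
        with pytest.raises(ValueError):
            pp.bandpass(np.zeros(1000), pp.FilterSpec("x", low, high), FS)


class TestRPeaks:
    def test_clean_record_sensitivity(self, clean_record):
        ecg = pp.bandpass(clean_record.ecg, pp.DEFAULT_BANDS["ecg"], FS)
        r = pp.detect_r_peaks(ecg, FS)
        truth = clean_record.truth_events["r_ms"].to_numpy()
        sens, fp, _ = pp.match_event_times(r, truth, 10.0)
        assert sens >= 0.99
        assert fp <= 0.01

    def test_noisy_record_sensitivity(self, noisy_record):
        ecg = pp.bandpass(noisy_record.ecg, pp.DEFAULT_BANDS["ecg"], FS)
        r = pp.detect_r_peaks(ecg, FS)
        truth = noisy_record.truth_events["r_ms"].to_numpy()
        sens, _, _ = pp.match_event_times(r, truth, 10.0)
        assert sens >= 0.95

    def test_flat_signal_yields_empty(self):
        assert len(pp.detect_r_peaks(np.zeros(int(10 * FS)), FS)) == 0

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            pp.detect_r_peaks(np.zeros(100), FS)


class TestJPeaks:
    def test_impulse_in_window(self):
        bcg = np.zeros(2000)
        bcg[1180] = 1.0   # R at 1000 ms -> J expected at R+180
        t, a, v = pp.detect_j_peaks(bcg, np.array([1000.0]), FS)
        assert v[0] and t[0] == pytest.approx(1180.0)
        assert a[0] == pytest.approx(1.0)

    def test_window_excludes_early_maximum(self):
        """A larger peak at R+100 ms lies outside (R+110, R+250] and must be
        ignored in favour of the in-window peak at R+150 ms."""
        bcg = np.zeros(2000)
        bcg[1100] = 2.0
        bcg[1150] = 1.0
        t, _, v = pp.detect_j_peaks(bcg, np.array([1000.0]), FS)
        assert v[0] and t[0] == pytest.approx(1150.0)

    def test_window_truncated_flagged_invalid(self):
        bcg = np.zeros(1100)
        _, _, v = pp.detect_j_peaks(bcg, np.array([1000.0]), FS)
        assert not v[0]

    def test_window_bound_invariant(self, noisy_record):
        bcg = pp.bandpass(noisy_record.bcg, pp.DEFAULT_BANDS["bcg"], FS)
        r = noisy_record.truth_events["r_ms"].to_numpy()
        t, _, v = pp.detect_j_peaks(bcg, r, FS)
        rj = t[v] - r[v]
        assert np.all((rj > 110.0) & (rj <= 250.0))

    def test_clean_cohort_sensitivity(self, clean_record):
        bcg = pp.bandpass(clean_record.bcg, pp.DEFAULT_BANDS["bcg"], FS)
        r = clean_record.truth_events["r_ms"].to_numpy()
        t, _, v = pp.detect_j_peaks(bcg, r, FS)
        sens, _, _ = pp.match_event_times(
            t[v], clean_record.truth_events["j_ms"].to_numpy(), 10.0)
        assert sens >= 0.99


class TestINotches:
    def test_trough_before_peak_found(self):
        bcg = np.zeros(2000)
        t = np.arange(2000)
        # trough at 1140, peak at 1180
        bcg += -np.exp(-0.5 * ((t - 1140) / 10.0) ** 2)
        bcg += np.exp(-0.5 * ((t - 1180) / 10.0) ** 2)
        times, valid = pp.detect_i_notches(bcg, np.array([1180.0]), FS)
        assert valid[0] and times[0] == pytest.approx(1140.0, abs=1.0)

    def test_monotone_rise_flagged_invalid(self):
        bcg = np.linspace(0.0, 1.0, 2000)
        times, valid = pp.detect_i_notches(bcg, np.array([1500.0]), FS)
        assert not valid[0]

    def test_missing_j_propagates(self):
        times, valid = pp.detect_i_notches(np.zeros(1000), np.array([np.nan]), FS)
        assert not valid[0] and np.isnan(times[0])


class TestDPPG:
    def test_ramp_tie_break_earliest(self):
        """Constant-slope ramp: all interior ramp samples tie at the maximal
        derivative, so the earliest sample wins."""
        ppg = np.zeros(3000)
        # binary-exact increments so interior slopes tie bit-for-bit
        ppg[1300:] = np.arange(1700) * 0.015625   # ramp onset at R+300 for R=1000
        t, a, v = pp.detect_dppg_peaks(ppg, np.array([1000.0]), FS)
        assert v[0]
        assert 1299.0 <= t[0] <= 1302.0

    def test_clean_record_sensitivity(self, clean_record):
        ppgf = pp.bandpass(clean_record.ppg, pp.DEFAULT_BANDS["ppg"], FS)
        r = clean_record.truth_events["r_ms"].to_numpy()
        t, _, v = pp.detect_dppg_peaks(ppgf, r, FS)
        sens, _, _ = pp.match_event_times(
            t[v], clean_record.truth_events["dppg_ms"].to_numpy(), 10.0)
        assert sens >= 0.99


def make_events(n=20, rr=800.0, ptt=250.0, rji=160.0, ij=40.0):
    r = 1000.0 + rr * np.arange(n)
    j = r + rji
    return pp.BeatEvents(
        r_times=r, i_times=j - ij, j_times=j, dppg_times=r + ptt,
        r_amp=np.ones(n), j_amp=np.ones(n), dppg_amp=np.ones(n),
        valid_r=np.ones(n, bool), valid_i=np.ones(n, bool),
        valid_j=np.ones(n, bool), valid_dppg=np.ones(n, bool))


class TestPlausibilityFilter:
    def test_clean_events_unchanged(self):
        ev = make_events()
        out = pp.plausibility_filter(ev)
        for f in ("valid_r", "valid_i", "valid_j", "valid_dppg"):
            assert np.array_equal(getattr(out, f), getattr(ev, f))

    def test_short_ptt_invalidated(self):
        ev = make_events()
        ev.dppg_times[7] = ev.r_times[7] + 50.0   # PTT = 50 ms, implausible
        out = pp.plausibility_filter(ev)
        assert not out.valid_dppg[7]
        assert out.valid_dppg.sum() == len(ev) - 1

    def test_rri_bound(self):
        ev = make_events(rr=800.0)
        ev.r_times[5] = ev.r_times[4] + 100.0   # 100 ms RRI
        out = pp.plausibility_filter(ev)
        assert not out.valid_r[5]

    def test_never_revalidates(self):
        rng = np.random.default_rng(0)
        ev = make_events(50)
        for f in ("valid_r", "valid_i", "valid_j", "valid_dppg"):
            getattr(ev, f)[rng.random(50) < 0.3] = False
        out = pp.plausibility_filter(ev)
        for f in ("valid_r", "valid_i", "valid_j", "valid_dppg"):
            assert not np.any(getattr(out, f) & ~getattr(ev, f))

    def test_corrupted_beats_flagged(self):
        """10 amplitude/timing-corrupted beats out of 1000: at least 9
        flagged, at most 2 clean beats lost."""
        rng = np.random.default_rng(1)
        n = 1000
        ev = make_events(n)
        ev.dppg_amp = 1.0 + 0.05 * rng.standard_normal(n)
        bad = rng.choice(n, size=10, replace=False)
        for k, b in enumerate(bad):
            if k % 2:
                ev.dppg_amp[b] = 8.0          # spurious amplitude
            else:
                ev.dppg_times[b] = ev.r_times[b] + 50.0   # implausible PTT
        out = pp.plausibility_filter(ev)
        flagged = np.where(~out.valid_dppg)[0]
        assert len(np.intersect1d(flagged, bad)) >= 9
        assert len(np.setdiff1d(flagged, bad)) <= 2

    def test_exclusion_list(self):
        ev = make_events()
        out = pp.plausibility_filter(ev, exclude_beats=[2, 5])
        for f in ("valid_r", "valid_i", "valid_j", "valid_dppg"):
            assert not getattr(out, f)[2] and not getattr(out, f)[5]


class TestPipeline:
    def test_dropout_beats_flagged_invalid(self, subject):
        from bpbeat import simulate as sim

        traj = sim.simulate_bp_trajectory(subject, 120.0, seed=61)
        noise = sim.NoiseConfig(white_sd=0.0, baseline_wander_amp=0.0,
                                powerline_amp=0.0, dropout_rate=0.1)
        rec = sim.synthesize_record(subject, traj, noise, seed=62)
        ev = pp.detect_beat_events(rec.ecg, rec.bcg, rec.ppg, rec.fs)
        tr = rec.truth_events
        n = min(len(ev), len(tr))
        dropped_ppg = tr["dppg_ms"].isna().to_numpy()[:n]
        # beats with a suppressed PPG pulse must not survive as valid dPPG
        assert np.mean(ev.valid_dppg[:n][dropped_ppg]) < 0.2
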