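"""Simulator: forward physics, trajectory statistics, cohort structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from bpbeat import simulate as sim


def make_subject(**kw) -> sim.SimSubject:
    base = dict(subject_id="T", gender=1, age=40.0, height=175.0, weight=72.0,
                E0=1.4e4, gamma_vessel=0.016, rho=1060.0, h=4.5e-4, d=4.0e-3,
                L_path=0.8, hr_base=70.0, sbp_base=110.0, dbp_base=68.0)
    base.update(kw)
    return sim.SimSubject(**base)


class TestPTTPhysics:
    def test_matches_independent_formula(self):
        """PTT equals a separately hand-coded evaluation of the
        Moens-Korteweg + Hughes + path-length relations to 1e-9."""
        sub = make_subject()
        for p in (60.0, 90.0, 111.2, 150.0, 200.0):
            e = sub.E0 * np.e ** (sub.gamma_vessel * p)
            pwv = (e * sub.h / (sub.rho * sub.d)) ** 0.5
            expected_ms = sub.L_path / pwv * 1e3
            assert sim.ptt_from_bp(p, sub) == pytest.approx(expected_ms, rel=1e-9)

    def test_strictly_decreasing_in_pressure(self):
        sub = make_subject()
        grid = np.linspace(60.0, 200.0, 281)
        ptt = sim.ptt_from_bp(grid, sub)
        assert np.all(np.diff(ptt) < 0)

    def test_quadrupled_modulus_halves_ptt(self):
        """e^(gamma*p) scaling by 4 must exactly halve the transit time
        (square root in the wave-speed law)."""
        sub = make_subject(gamma_vessel=0.02)
        p0 = 100.0
        p1 = p0 + np.log(4.0) / sub.gamma_vessel
        assert sim.ptt_from_bp(p1, sub) == pytest.approx(
            sim.ptt_from_bp(p0, sub) / 2.0, rel=1e-12)

    def test_baseline_ptt_constructor(self):
        sub = sim.SimSubject.from_baseline_ptt(
            230.0, subject_id="T", gender=0, age=30.0, height=160.0,
            weight=55.0, gamma_vessel=0.016, rho=1060.0, h=4.5e-4, d=4.0e-3,
            L_path=0.75, hr_base=65.0, sbp_base=105.0, dbp_base=65.0)
        assert sim.ptt_from_bp(105.0, sub) == pytest.approx(230.0, rel=1e-12)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_subject(sbp_base=60.0, dbp_base=70.0)
        with pytest.raises(ValueError):
            make_subject(gamma_vessel=-0.01)
        assert make_subject(height=180.0, weight=81.0).bmi == pytest.approx(25.0)


class TestTrajectory:
    def test_degenerate_noise_gives_constant_baseline(self):
        sub = make_subject()
        traj = sim.simulate_bp_trajectory(sub, 60.0, seed=0, walk_sd=0.0,
                                          slow_amp=0.0, resp_amp=0.0)
        assert np.allclose(traj.sbp, sub.sbp_base)
        assert np.allclose(traj.dbp, sub.dbp_base)

    def test_same_seed_identical(self):
        sub = make_subject()
        a = sim.simulate_bp_trajectory(sub, 120.0, seed=9)
        b = sim.simulate_bp_trajectory(sub, 120.0, seed=9)
        assert np.array_equal(a.beat_times, b.beat_times)
        assert np.array_equal(a.sbp, b.sbp)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_bp_trajectory(make_subject(), 0.0, seed=0)

    def test_invariants(self):
        traj = sim.simulate_bp_trajectory(make_subject(), 300.0, seed=3)
        assert np.all(np.diff(traj.beat_times) > 0)
        assert np.all(traj.sbp > traj.dbp)
        assert np.all((traj.dbp >= 40.0) & (traj.sbp <= 220.0))

    def test_cohort_bp_means_near_target(self):
        """Pooled SBP/DBP means of an 18-subject cohort should sit near the
        cohort the generator emulates (111.2 / 67.7 mmHg, within 5)."""
        rng = np.random.default_rng(77)
        sbp, dbp = [], []
        for i in range(18):
            sub = sim.sample_subject(f"C{i}", rng)
            traj = sim.simulate_bp_trajectory(sub, 300.0, seed=200 + i)
            sbp.append(traj.sbp)
            dbp.append(traj.dbp)
        assert abs(np.mean(np.concatenate(sbp)) - 111.2) < 5.0
        assert abs(np.mean(np.concatenate(dbp)) - 67.7) < 5.0


class TestRecordSynthesis:
    def test_truth_event_ordering_and_windows(self, clean_record):
        tr = clean_record.truth_events
        assert np.all(tr["r_ms"] < tr["i_ms"])
        assert np.all(tr["i_ms"] < tr["j_ms"])
        rj = tr["j_ms"] - tr["r_ms"]
        assert np.all((rj > 110.0) & (rj <= 250.0))
        assert np.all(tr["dppg_ms"] > tr["r_ms"])

    def test_noiseless_truth_complete(self, clean_record):
        tr = clean_record.truth_events
        assert tr[["r_ms", "i_ms", "j_ms", "dppg_ms"]].notna().all().all()
        assert len(tr) == len(clean_record.beat_times)

    def test_bp_raise_shortens_mean_ptt(self, subject):
        traj = sim.simulate_bp_trajectory(subject, 90.0, seed=21)
        lo = sim.synthesize_record(subject, traj, sim.NoiseConfig.none(), seed=22)
        hi = sim.synthesize_record(subject, traj.shifted(30.0),
                                   sim.NoiseConfig.none(), seed=22)
        ptt = lambda r: (r.truth_events["dppg_ms"] - r.truth_events["r_ms"]).mean()
        assert ptt(hi) < ptt(lo)

    def test_dropout_rate_realized(self, subject):
        traj = sim.simulate_bp_trajectory(subject, 300.0, seed=31)
        noise = sim.NoiseConfig(white_sd=0.0, baseline_wander_amp=0.0,
                                powerline_amp=0.0, dropout_rate=0.1)
        rec = sim.synthesize_record(subject, traj, noise, seed=32)
        tr = rec.truth_events
        dropped = (tr["j_ms"].isna() | tr["dppg_ms"].isna()).mean()
        n = len(tr)
        tol = 3.0 * np.sqrt(0.1 * 0.9 / n)
        assert abs(dropped - 0.1) < tol

    def test_same_seed_bitwise_identical(self, subject):
        traj = sim.simulate_bp_trajectory(subject, 30.0, seed=41)
        a = sim.synthesize_record(subject, traj, sim.NoiseConfig(), seed=42)
        b = sim.synthesize_record(subject, traj, sim.NoiseConfig(), seed=42)
        assert np.array_equal(a.ecg, b.ecg)
        assert np.array_equal(a.bcg, b.bcg)
        assert np.array_equal(a.ppg, b.ppg)

    def test_too_short_beat_interval_rejected(self, subject):
        traj = sim.BPTrajectory(np.array([500.0, 700.0]),
                                np.array([110.0, 111.0]),
                                np.array([70.0, 70.0]))
        with pytest.raises(ValueError, match="template"):
            sim.synthesize_record(subject, traj, sim.NoiseConfig.none(), seed=0)

    def test_empty_trajectory_rejected(self, subject):
        traj = sim.BPTrajectory(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            sim.synthesize_record(subject, traj, sim.NoiseConfig.none(), seed=0)


class TestCohort:
    def test_record_count_with_revisits(self):
        cfg = sim.CohortConfig(duration_s=40.0, noise=sim.NoiseConfig.none())
        recs = sim.generate_cohort(18, 15, cfg, seed=1)
        assert len(recs) == 33
        assert sum(r.visit == 2 for r in recs) == 15
        # revisits share physiology identifiers with visit 1
        by_id = {}
        for r in recs:
            by_id.setdefault(r.subject.subject_id, []).append(r)
        assert sum(len(v) == 2 for v in by_id.values()) == 15

    def test_no_revisit(self):
        cfg = sim.CohortConfig(duration_s=40.0, noise=sim.NoiseConfig.none())
        recs = sim.generate_cohort(4, 0, cfg, seed=2)
        assert len(recs) == 4
        assert all(r.visit == 1 for r in recs)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sim.generate_cohort(0, 0, seed=0)
        with pytest.raises(ValueError):
            sim.generate_cohort(3, 4, seed=0)

    def test_zero_drift_visits_statistically_match(self):
        """With drift off the two visits share identical physiology, and
        their BP/PTT samples come from the same generating process.

        Beatwise BP is strongly autocorrelated (slow random walk), so the
        two-sample KS test is run on beats thinned far beyond the walk's
        decorrelation time; the subject's visit-2 vascular constants must be
        bit-identical.
        """
        cfg = sim.CohortConfig(duration_s=120.0, drift=sim.DriftConfig.none(),
                               noise=sim.NoiseConfig.none())
        v1, v2 = sim.generate_cohort(1, 1, cfg, seed=3)
        for attr in ("E0", "gamma_vessel", "sbp_base", "dbp_base", "L_path"):
            assert getattr(v2.subject, attr) == pytest.approx(
                getattr(v1.subject, attr), rel=1e-9)
        # long trajectories (no waveforms needed), thinned to ~independence
        t1 = sim.simulate_bp_trajectory(v1.subject, 1800.0, seed=300)
        t2 = sim.simulate_bp_trajectory(v2.subject, 1800.0, seed=301)
        thin = slice(None, None, 40)
        for a, b in ((t1.sbp[thin], t2.sbp[thin]),
                     (sim.ptt_from_bp(t1.sbp, v1.subject)[thin],
                      sim.ptt_from_bp(t2.sbp, v2.subject)[thin])):
            assert sstats.ks_2samp(a, b).pvalue > 0.01

    def test_cohort_determinism(self):
        cfg = sim.CohortConfig(duration_s=30.0)
        a = sim.generate_cohort(2, 1, cfg, seed=9)
        b = sim.generate_cohort(2, 1, cfg, seed=9)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.ecg, rb.ecg)
            assert np.array_equal(ra.ref_sbp, rb.ref_sbp)


class TestRecordIO:
    def test_roundtrip(self, tmp_path, subject):
        traj = sim.simulate_bp_trajectory(subject, 20.0, seed=51)
        rec = sim.synthesize_record(subject, traj, sim.NoiseConfig(), seed=52)
        sidecar = sim.write_record(rec, tmp_path)
        back = sim.read_record(sidecar)
        assert back.record_id == rec.record_id
        assert back.fs == rec.fs
        np.testing.assert_allclose(back.ref_sbp, rec.ref_sbp, rtol=1e-5)
        np.testing.assert_allclose(back.ecg, rec.ecg, rtol=1e-4, atol=1e-5)
        np.testing.assert_allclose(back.truth_events["r_ms"].to_numpy(),
                                   rec.truth_events["r_ms"].to_numpy(),
                                   rtol=1e-6)
        assert back.subject.gamma_vessel == pytest.approx(subject.gamma_vessel)
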