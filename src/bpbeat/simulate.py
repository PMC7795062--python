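"""Physiologically structured synthetic cohorts of ECG/BCG/PPG recordings.

The simulator produces multi-channel recordings whose pulse-transit timing is
coupled to blood pressure through arterial-wall physics: the pulse wave
velocity follows the Moens-Korteweg relation with a pressure-dependent elastic
modulus (Hughes exponential law),

    PWV = sqrt(E0 * exp(gamma * P) * h / (rho * d)),    PTT = L / PWV,

so that higher pressure stiffens the vessel, speeds the pulse, and shortens
the transit time.  Each record carries ground-truth fiducial times (ECG
R-peak, BCG I-notch and J-peak, dPPG peak) recorded before noise is added,
which downstream detector and feature tests use as an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimSubject",
    "BPTrajectory",
    "NoiseConfig",
    "DriftConfig",
    "CohortConfig",
    "WaveformRecord",
    "ptt_from_bp",
    "simulate_bp_trajectory",
    "synthesize_record",
    "generate_cohort",
    "sample_subject",
    "write_record",
    "read_record",
]

MMHG_TO_PA = 133.322


@dataclass
class SimSubject:
    """One simulated subject's demographics and vascular physiology.

    Physical constants feed the Moens-Korteweg / Hughes forward model; the
    timing baselines (``ptt_base``, ``rji_base``, ``i_offset``) position the
    BCG/PPG fiducials inside the detection windows used downstream.
    """

    subject_id: str
    gender: int            # 0 = female, 1 = male
    age: float             # years
    height: float          # cm
    weight: float          # kg
    E0: float              # elastic modulus at zero pressure, Pa
    gamma_vessel: float    # vessel coefficient, 1/mmHg
    rho: float             # blood density, kg/m^3
    h: float               # wall thickness, m
    d: float               # vessel radius, m
    L_path: float          # heart-to-finger path length, m
    hr_base: float         # beats/min
    sbp_base: float        # mmHg
    dbp_base: float        # mmHg
    rji_base: float = 165.0    # ms, R-peak to BCG J-peak at baseline BP
    i_offset: float = 40.0     # ms, J-peak minus I-notch
    ptt_jitter_sd: float = 3.0  # ms, beat-to-beat timing noise on the dPPG fiducial
    rji_jitter_sd: float = 2.0  # ms, same for the J-peak

    def __post_init__(self) -> None:
        if self.sbp_base <= self.dbp_base or self.dbp_base <= 0:
            raise ValueError("require sbp_base > dbp_base > 0")
        if self.gamma_vessel <= 0:
            raise ValueError("gamma_vessel must be > 0")
        for name in ("E0", "rho", "h", "d", "L_path", "hr_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2

    @property
    def demographics(self) -> dict:
        return {
            "gender": self.gender,
            "age": self.age,
            "height": self.height,
            "weight": self.weight,
            "bmi": self.bmi,
        }

    @classmethod
    def from_baseline_ptt(cls, ptt_base_ms: float, **kwargs) -> "SimSubject":
        """Construct a subject whose baseline PTT (at ``sbp_base``) is given.

        Solves the Hughes law for E0 so that ``ptt_from_bp(sbp_base)`` equals
        ``ptt_base_ms`` exactly.
        """
        tmp = cls(E0=1.0, **kwargs)
        pwv = tmp.L_path / (ptt_base_ms / 1000.0)
        e_at_p = pwv**2 * tmp.rho * tmp.d / tmp.h
        e0 = e_at_p / np.exp(tmp.gamma_vessel * tmp.sbp_base)
        return replace(tmp, E0=e0)


@dataclass
class BPTrajectory:
    """Beatwise blood-pressure series: beat times (ms) with SBP/DBP (mmHg)."""

    beat_times: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if not (len(self.beat_times) == len(self.sbp) == len(self.dbp)):
            raise ValueError("beat_times, sbp, dbp must be equally long")
        if len(self.beat_times) and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.sbp <= self.dbp):
            raise ValueError("require sbp > dbp per beat")

    def __len__(self) -> int:
        return len(self.beat_times)

    def shifted(self, delta_mmhg: float) -> "BPTrajectory":
        """Return a copy with the whole trajectory raised by ``delta_mmhg``."""
        return BPTrajectory(self.beat_times.copy(), self.sbp + delta_mmhg, self.dbp + delta_mmhg)


@dataclass
class NoiseConfig:
    """Additive artifact model: white noise, baseline wander, power-line hum,
    and per-beat pulse dropout (a missing BCG or PPG pulse)."""

    white_sd: Mapping[str, float] = field(
        default_factory=lambda: {"ecg": 0.03, "bcg": 0.06, "ppg": 0.015}
    )
    baseline_wander_amp: float = 0.15
    baseline_wander_freq: float = 0.3   # Hz
    powerline_amp: float = 0.05
    powerline_freq: float = 50.0        # Hz
    dropout_rate: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.white_sd, (int, float)):
            self.white_sd = {"ecg": float(self.white_sd),
                             "bcg": float(self.white_sd),
                             "ppg": float(self.white_sd)}
        if any(v < 0 for v in self.white_sd.values()):
            raise ValueError("white noise SDs must be >= 0")
        if self.baseline_wander_amp < 0 or self.powerline_amp < 0:
            raise ValueError("amplitudes must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(white_sd=0.0, baseline_wander_amp=0.0, powerline_amp=0.0,
                   dropout_rate=0.0)


@dataclass
class DriftConfig:
    """Inter-day (visit 1 -> visit 2) drift applied to a revisiting subject:
    an additive baseline-BP shift, a multiplicative amplitude rescale, and a
    PTT calibration offset (a shift of the baseline transit time)."""

    bp_shift_sd: float = 5.0       # mmHg
    amp_scale_sd: float = 0.10     # multiplicative, lognormal-ish
    ptt_offset_sd: float = 10.0    # ms

    @classmethod
    def none(cls) -> "DriftConfig":
        return cls(0.0, 0.0, 0.0)


@dataclass
class WaveformRecord:
    """One subject-visit's synchronized channels plus beatwise references and
    pre-noise ground-truth event times (NaN where a pulse was dropped)."""

    subject: SimSubject
    visit: int
    fs: float
    ecg: np.ndarray
    bcg: np.ndarray
    ppg: np.ndarray
    beat_times: np.ndarray   # ms
    ref_sbp: np.ndarray      # mmHg, aligned to beat_times
    ref_dbp: np.ndarray
    truth_events: pd.DataFrame | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.ecg)
        if not (len(self.bcg) == n == len(self.ppg)):
            raise ValueError("all channels must have equal length")

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.ecg)) / self.fs * 1000.0


def ptt_from_bp(p: float | np.ndarray, subject: SimSubject) -> float | np.ndarray:
    """Pulse transit time (ms) at pressure ``p`` (mmHg).

    PWV = sqrt(E0 * exp(gamma*p) * h / (rho * d)) with E in Pa; PTT = L/PWV.
    Strictly decreasing in p for gamma > 0.
    """
    p = np.asarray(p, dtype=float)
    e = subject.E0 * np.exp(subject.gamma_vessel * p)
    pwv = np.sqrt(e * subject.h / (subject.rho * subject.d))
    ptt_s = subject.L_path / pwv
    out = ptt_s * 1000.0
    return float(out) if out.ndim == 0 else out


def simulate_bp_trajectory(
    subject: SimSubject,
    duration: float,
    seed: int,
    walk_sd: float = 0.8,
    walk_rho: float = 0.98,
    walk_clip: float = 15.0,
    slow_amp: float = 4.0,
    slow_freq: float = 0.03,
    resp_amp: float = 1.5,
    resp_freq: float = 0.25,
    rr_jitter: float = 0.03,
) -> BPTrajectory:
    """Beatwise SBP/DBP over ``duration`` seconds.

    The systolic series is the subject baseline plus a bounded AR(1) random
    walk plus slow vasomotor and respiratory sinusoids; pulse pressure tracks
    the walk weakly, giving a correlated but not degenerate DBP.  Beat
    intervals jitter around 60000/hr_base ms.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    rr_mean = 60000.0 / subject.hr_base
    n_max = int(duration * 1000.0 / rr_mean * 1.3) + 3

    rrs = rr_mean * (1.0 + rr_jitter * rng.standard_normal(n_max))
    rrs = np.clip(rrs, 0.6 * rr_mean, 1.5 * rr_mean)
    beat_times = 300.0 + np.cumsum(rrs)
    beat_times = beat_times[beat_times < duration * 1000.0 - 700.0]
    n = len(beat_times)
    if n == 0:
        raise ValueError("duration too short for a single beat")

    walk = np.zeros(n)
    steps = rng.standard_normal(n) * walk_sd
    for i in range(1, n):
        walk[i] = np.clip(walk_rho * walk[i - 1] + steps[i], -walk_clip, walk_clip)
    t_s = beat_times / 1000.0
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    slow = slow_amp * np.sin(2 * np.pi * slow_freq * t_s + phase1)
    resp = resp_amp * np.sin(2 * np.pi * resp_freq * t_s + phase2)

    sbp = subject.sbp_base + walk + slow + resp
    pp_base = subject.sbp_base - subject.dbp_base
    pp = pp_base + 0.3 * walk + 0.2 * slow
    pp = np.maximum(pp, 15.0)
    dbp = sbp - pp
    sbp = np.clip(sbp, 45.0, 220.0)
    dbp = np.clip(dbp, 40.0, sbp - 10.0)
    return BPTrajectory(beat_times, sbp, dbp)


def _add_gauss(sig: np.ndarray, fs: float, t_ms: float, amp: float, sd_ms: float) -> None:
    """Add a Gaussian bump centred at t_ms (in place), truncated at 4 SD."""
    sd = sd_ms / 1000.0 * fs
    c = t_ms / 1000.0 * fs
    lo = max(int(c - 4 * sd), 0)
    hi = min(int(c + 4 * sd) + 1, len(sig))
    if hi <= lo:
        return
    idx = np.arange(lo, hi)
    sig[lo:hi] += amp * np.exp(-0.5 * ((idx - c) / sd) ** 2)


def _add_damped_sine(sig: np.ndarray, fs: float, i_ms: float, j_ms: float,
                     amp: float) -> None:
    """Add a Gaussian-windowed sinusoid whose principal trough/peak fall at
    i_ms / j_ms (the BCG I-notch and J-peak), in place."""
    half = (j_ms - i_ms) / 2.0
    tm = (i_ms + j_ms) / 2.0
    tau = 0.9 * (j_ms - i_ms)
    c = tm / 1000.0 * fs
    span = 2.5 * tau / 1000.0 * fs
    lo = max(int(c - span), 0)
    hi = min(int(c + span) + 1, len(sig))
    if hi <= lo:
        return
    t_rel = (np.arange(lo, hi) - c) / fs * 1000.0   # ms relative to midpoint
    env = np.exp(-0.5 * (t_rel / tau) ** 2)
    sig[lo:hi] += amp * env * np.sin(np.pi * t_rel / (2.0 * half))


def _add_smooth_step(sig: np.ndarray, fs: float, t_ms: float, amp: float, sd_ms: float) -> None:
    """Add amp * Phi((t - t_ms)/sd): a smooth upstroke whose steepest slope
    sits exactly at t_ms (in place)."""
    from scipy.special import ndtr

    sd = sd_ms / 1000.0 * fs
    c = t_ms / 1000.0 * fs
    lo = max(int(c - 5 * sd), 0)
    hi = min(int(c + 5 * sd) + 1, len(sig))
    if lo < len(sig):
        idx = np.arange(lo, hi)
        sig[lo:hi] += amp * ndtr((idx - c) / sd)
        if hi < len(sig):
            sig[hi:] += amp


def synthesize_record(
    subject: SimSubject,
    traj: BPTrajectory,
    noise: NoiseConfig,
    seed: int,
    fs: float = 1000.0,
    visit: int = 1,
    record_id: str = "",
) -> WaveformRecord:
    """Render the three channels for a BP trajectory and record truth events.

    Per beat: an ECG PQRST complex with the R-peak at the beat time; a BCG
    H-I-J-K complex whose J-peak sits at R + RJI (weakly BP-coupled, kept
    inside the 110-250 ms detection window); a PPG pulse whose steepest
    upstroke (dPPG peak) sits at R + PTT(SBP).  Truth events are recorded
    before noise; dropped pulses (per ``noise.dropout_rate``) get NaN truth.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    rng = np.random.default_rng(seed)
    n_beats = len(traj)
    rr_min = np.min(np.diff(traj.beat_times)) if n_beats > 1 else np.inf
    if rr_min < 330.0:
        raise ValueError("beat interval shorter than waveform template support")

    dur_ms = traj.beat_times[-1] + 700.0
    n_samp = int(np.ceil(dur_ms / 1000.0 * fs)) + 1
    ecg = np.zeros(n_samp)
    bcg = np.zeros(n_samp)
    ppg = np.full(n_samp, 1.0)   # positive DC level so raw PPG peak/valley ratios are defined

    dt = 1000.0 / fs  # ms per sample

    def snap(t_ms: float) -> float:
        return np.round(t_ms / dt) * dt

    sbp, dbp = traj.sbp, traj.dbp
    pp = sbp - dbp
    pp_base = subject.sbp_base - subject.dbp_base

    # per-beat fiducial times (ms), snapped to the sample grid
    r_t = np.array([snap(t) for t in traj.beat_times])
    ptt = ptt_from_bp(sbp, subject) + subject.ptt_jitter_sd * rng.standard_normal(n_beats)
    ptt = np.clip(ptt, 120.0, 580.0)
    rji = subject.rji_base - 0.6 * (sbp - subject.sbp_base) \
        + subject.rji_jitter_sd * rng.standard_normal(n_beats)
    rji = np.clip(rji, 112.0, 248.0)
    j_t = np.array([snap(t) for t in r_t + rji])
    ij_gap = np.clip(subject.i_offset + 1.5 * rng.standard_normal(n_beats), 30.0, 60.0)
    i_t = np.array([snap(t) for t in j_t - ij_gap])
    dppg_t = np.array([snap(t) for t in r_t + ptt])

    # per-beat amplitudes; BCG/PPG amplitudes carry a pulse-pressure signal
    ecg_amp = 1.0 * (1.0 + 0.05 * rng.standard_normal(n_beats))
    bcg_amp = 1.0 * (1.0 + 0.010 * (pp - pp_base) + 0.05 * rng.standard_normal(n_beats))
    ppg_amp = 0.8 * (1.0 - 0.004 * (dbp - subject.dbp_base) + 0.03 * rng.standard_normal(n_beats))
    bcg_amp = np.maximum(bcg_amp, 0.2)
    ppg_amp = np.maximum(ppg_amp, 0.1)

    drop_mask = rng.random(n_beats) < noise.dropout_rate
    drop_chan = rng.random(n_beats) < 0.5   # True -> BCG dropped, else PPG

    for k in range(n_beats):
        r = r_t[k]
        # ECG: P, Q, R, S, T
        _add_gauss(ecg, fs, r - 180.0, 0.15 * ecg_amp[k], 25.0)
        _add_gauss(ecg, fs, r - 35.0, -0.12 * ecg_amp[k], 8.0)
        _add_gauss(ecg, fs, r, ecg_amp[k], 12.0)
        _add_gauss(ecg, fs, r + 32.0, -0.22 * ecg_amp[k], 9.0)
        _add_gauss(ecg, fs, r + 250.0, 0.28 * ecg_amp[k], 50.0)
        # BCG: damped-sinusoid I-J complex (Gaussian-windowed tone whose
        # half-period equals the I-J spacing; symmetric about the I-J midpoint
        # so zero-phase filtering does not move the extrema)
        if not (drop_mask[k] and drop_chan[k]):
            _add_damped_sine(bcg, fs, i_t[k], j_t[k], bcg_amp[k])
        # PPG: smooth upstroke (max slope at dppg_t) + slower downstroke
        if not (drop_mask[k] and not drop_chan[k]):
            _add_smooth_step(ppg, fs, dppg_t[k], ppg_amp[k], 16.0)
            _add_smooth_step(ppg, fs, dppg_t[k] + 160.0, -ppg_amp[k], 65.0)

    truth = pd.DataFrame({
        "beat": np.arange(n_beats),
        "r_ms": r_t,
        "i_ms": np.where(drop_mask & drop_chan, np.nan, i_t),
        "j_ms": np.where(drop_mask & drop_chan, np.nan, j_t),
        "dppg_ms": np.where(drop_mask & ~drop_chan, np.nan, dppg_t),
        "ecg_amp": ecg_amp,
        "bcg_amp": np.where(drop_mask & drop_chan, np.nan, bcg_amp),
        "ppg_amp": np.where(drop_mask & ~drop_chan, np.nan, ppg_amp),
    })

    t_s = np.arange(n_samp) / fs
    for sig, name in ((ecg, "ecg"), (bcg, "bcg"), (ppg, "ppg")):
        sd = noise.white_sd[name]
        if sd > 0:
            sig += sd * rng.standard_normal(n_samp)
        if noise.baseline_wander_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig += noise.baseline_wander_amp * np.sin(
                2 * np.pi * noise.baseline_wander_freq * t_s + phase)
        if noise.powerline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig += noise.powerline_amp * np.sin(
                2 * np.pi * noise.powerline_freq * t_s + phase)

    return WaveformRecord(
        subject=subject, visit=visit, fs=fs, ecg=ecg, bcg=bcg, ppg=ppg,
        beat_times=r_t.copy(), ref_sbp=sbp.copy(), ref_dbp=dbp.copy(),
        truth_events=truth, record_id=record_id or f"{subject.subject_id}_v{visit}",
    )


def sample_subject(subject_id: str, rng: np.random.Generator) -> SimSubject:
    """Draw one subject from plausible adult ranges.

    Demographics influence baseline BP through a simple linear rule so that
    demographic inputs to the general model are informative; the cohort-level
    SBP/DBP means land near 111/68 mmHg.
    """
    gender = int(rng.random() < 8.0 / 18.0)  # cohort had 8 male / 10 female
    age = float(rng.uniform(20, 60))
    height = float(rng.normal(174.0 if gender else 161.0, 6.0))
    bmi = float(np.clip(rng.normal(23.0, 2.5), 17.5, 32.0))
    weight = bmi * (height / 100.0) ** 2
    sbp_base = 102.0 + 0.18 * age + 4.0 * gender + 0.35 * (bmi - 23.0) + rng.normal(0, 5.0)
    dbp_base = 61.0 + 0.12 * age + 2.0 * gender + 0.25 * (bmi - 23.0) + rng.normal(0, 3.5)
    sbp_base = float(np.clip(sbp_base, 90.0, 150.0))
    dbp_base = float(np.clip(dbp_base, 50.0, min(95.0, sbp_base - 25.0)))
    return SimSubject.from_baseline_ptt(
        ptt_base_ms=float(np.clip(rng.normal(225.0, 15.0), 190.0, 260.0)),
        subject_id=subject_id,
        gender=gender,
        age=age,
        height=height,
        weight=weight,
        gamma_vessel=float(np.clip(rng.normal(0.016, 0.002), 0.010, 0.022)),
        rho=1060.0,
        h=4.5e-4,
        d=4.0e-3,
        L_path=0.0047 * height,
        hr_base=float(rng.uniform(58.0, 85.0)),
        sbp_base=sbp_base,
        dbp_base=dbp_base,
        rji_base=float(np.clip(rng.normal(165.0, 12.0), 128.0, 232.0)),
        i_offset=float(np.clip(rng.normal(42.0, 5.0), 34.0, 55.0)),
    )


@dataclass
class CohortConfig:
    """Study-level configuration for :func:`generate_cohort`."""

    duration_s: float = 1800.0
    fs: float = 1000.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)


def generate_cohort(
    n_subjects: int,
    n_revisit: int,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> list[WaveformRecord]:
    """Simulate a cohort: ``n_subjects`` first visits plus ``n_revisit``
    second visits with inter-day drift (the first ``n_revisit`` subjects
    revisit).  All randomness flows from ``seed`` via spawned child seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not (0 <= n_revisit <= n_subjects):
        raise ValueError("require 0 <= n_revisit <= n_subjects")
    config = config or CohortConfig()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    records: list[WaveformRecord] = []
    for i in range(n_subjects):
        sub_ss = children[i]
        s1, s2, s3, s4, s5 = [int(c.generate_state(1)[0] % (2**31)) for c in sub_ss.spawn(5)]
        rng = np.random.default_rng(s1)
        subject = sample_subject(f"S{i + 1:02d}", rng)

        traj1 = simulate_bp_trajectory(subject, config.duration_s, seed=s2)
        records.append(synthesize_record(subject, traj1, config.noise, seed=s3,
                                         fs=config.fs, visit=1))
        if i < n_revisit:
            drift = config.drift
            bp_shift = float(rng.normal(0, drift.bp_shift_sd))
            amp_scale = float(np.exp(rng.normal(0, drift.amp_scale_sd)))
            ptt_off = float(rng.normal(0, drift.ptt_offset_sd))
            ptt2 = float(np.clip(
                ptt_from_bp(subject.sbp_base, subject) + ptt_off, 150.0, 300.0))
            sub2 = SimSubject.from_baseline_ptt(
                ptt_base_ms=ptt2,
                subject_id=subject.subject_id,
                gender=subject.gender, age=subject.age,
                height=subject.height, weight=subject.weight,
                gamma_vessel=subject.gamma_vessel, rho=subject.rho,
                h=subject.h, d=subject.d, L_path=subject.L_path,
                hr_base=subject.hr_base,
                sbp_base=subject.sbp_base + bp_shift,
                dbp_base=subject.dbp_base + 0.6 * bp_shift,
                rji_base=subject.rji_base, i_offset=subject.i_offset,
                ptt_jitter_sd=subject.ptt_jitter_sd,
                rji_jitter_sd=subject.rji_jitter_sd,
            )
            traj2 = simulate_bp_trajectory(sub2, config.duration_s, seed=s4)
            rec2 = synthesize_record(sub2, traj2, config.noise, seed=s5,
                                     fs=config.fs, visit=2)
            rec2.ecg *= amp_scale
            rec2.bcg *= amp_scale
            rec2.ppg = 1.0 + amp_scale * (rec2.ppg - 1.0)
            records.append(rec2)
    return records


# ---------------------------------------------------------------------------
# Record I/O: CSV channels + CSV beats + JSON sidecar

def write_record(record: WaveformRecord, out_dir: str | Path) -> Path:
    """Write a record as ``<id>_signals.csv``, ``<id>_beats.csv`` and
    ``<id>_meta.json`` under ``out_dir``; returns the sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rid = record.record_id
    pd.DataFrame({
        "time_ms": record.time_ms, "ecg": record.ecg,
        "bcg": record.bcg, "ppg": record.ppg,
    }).to_csv(out / f"{rid}_signals.csv", index=False, float_format="%.6g")

    beats = pd.DataFrame({
        "beat_time_ms": record.beat_times,
        "sbp": record.ref_sbp, "dbp": record.ref_dbp,
    })
    if record.truth_events is not None:
        beats = pd.concat(
            [beats, record.truth_events.drop(columns="beat").add_prefix("truth_")],
            axis=1)
    beats.to_csv(out / f"{rid}_beats.csv", index=False, float_format="%.6g")

    sub = asdict(record.subject)
    sub["bmi"] = record.subject.bmi
    meta = {"record_id": rid, "visit": record.visit, "fs": record.fs, "subject": sub}
    sidecar = out / f"{rid}_meta.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_record(sidecar: str | Path) -> WaveformRecord:
    """Load a record from its JSON sidecar (inverse of :func:`write_record`)."""
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    rid = meta["record_id"]
    base = sidecar.parent
    sig = pd.read_csv(base / f"{rid}_signals.csv")
    beats = pd.read_csv(base / f"{rid}_beats.csv")
    sub_fields = meta["subject"]
    sub_fields.pop("bmi", None)
    subject = SimSubject(**sub_fields)
    truth_cols = [c for c in beats.columns if c.startswith("truth_")]
    truth = None
    if truth_cols:
        truth = beats[truth_cols].rename(columns=lambda c: c[len("truth_"):])
        truth.insert(0, "beat", np.arange(len(beats)))
    return WaveformRecord(
        subject=subject, visit=int(meta["visit"]), fs=float(meta["fs"]),
        ecg=sig["ecg"].to_numpy(), bcg=sig["bcg"].to_numpy(),
        ppg=sig["ppg"].to_numpy(),
        beat_times=beats["beat_time_ms"].to_numpy(),
        ref_sbp=beats["sbp"].to_numpy(), ref_dbp=beats["dbp"].to_numpy(),
        truth_events=truth, record_id=rid,
    )
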