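"""Channel filtering and characteristic-point detection.

Each channel gets a second-order zero-phase Butterworth band-pass (ECG
0.5-35 Hz, BCG 4-15 Hz, PPG 0.5-8 Hz).  Four fiducials are located per
cardiac cycle: the ECG R-peak (Pan-Tompkins), the BCG J-peak (highest local
maximum 110-250 ms after R), the BCG I-notch (nearest local minimum within
100 ms before J), and the peak of the first PPG derivative (steepest systolic
upstroke).  A plausibility filter replaces manual false-positive editing with
physiologic bounds, rolling-median amplitude checks and an optional
exclusion list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "BeatEvents",
    "DEFAULT_BANDS",
    "bandpass",
    "detect_r_peaks",
    "detect_j_peaks",
    "detect_i_notches",
    "detect_dppg_peaks",
    "plausibility_filter",
    "detect_beat_events",
    "match_event_times",
]


@dataclass(frozen=True)
class FilterSpec:
    channel: str
    low_hz: float
    high_hz: float
    order: int = 2

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise ValueError(
                f"invalid band for {self.channel}: need 0 < {self.low_hz} < "
                f"{self.high_hz} < fs/2 = {fs / 2}")


DEFAULT_BANDS = {
    "ecg": FilterSpec("ecg", 0.5, 35.0),
    "bcg": FilterSpec("bcg", 4.0, 15.0),
    "ppg": FilterSpec("ppg", 0.5, 8.0),
}


def bandpass(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass; length-preserving."""
    spec.validate(fs)
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak times (ms) via the Pan-Tompkins stages.

    Band-pass 5-15 Hz, five-point derivative, squaring, 150 ms moving-window
    integration, adaptive signal/noise thresholds with search-back, then
    refinement to the local ECG maximum within +/-75 ms of each detection.
    Returns an empty array (with a logged warning) when nothing is found.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of signal")

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    # five-point derivative (Pan-Tompkins kernel)
    kern = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    deriv = np.convolve(bp, kern[::-1], mode="same")
    sq = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    # candidate peaks of the integrated signal
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        log.warning("Pan-Tompkins: no candidate peaks found")
        return np.array([])

    # adaptive thresholding with search-back
    spki = float(np.max(mwi[: int(2 * fs)]) * 0.25) if len(mwi) else 0.0
    npki = float(np.mean(mwi[: int(2 * fs)]) * 0.5)
    threshold = npki + 0.25 * (spki - npki)
    qrs: list[int] = []
    recent_rr: list[float] = []

    def accept(idx: int) -> None:
        nonlocal spki, threshold
        spki = 0.125 * mwi[idx] + 0.875 * spki
        threshold = npki + 0.25 * (spki - npki)
        if qrs:
            recent_rr.append(idx - qrs[-1])
            if len(recent_rr) > 8:
                recent_rr.pop(0)
        qrs.append(idx)

    i = 0
    while i < len(cand):
        idx = cand[i]
        if mwi[idx] >= threshold:
            accept(idx)
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki
            threshold = npki + 0.25 * (spki - npki)
            # search-back: missed beat if no QRS for 1.66x the running RR mean
            if recent_rr and qrs and (idx - qrs[-1]) > 1.66 * np.mean(recent_rr):
                seg = [c for c in cand[max(0, i - 8): i + 1]
                       if qrs[-1] + refractory < c <= idx and mwi[c] >= 0.5 * threshold]
                if seg:
                    best = max(seg, key=lambda c: mwi[c])
                    accept(best)
        i += 1

    if not qrs:
        log.warning("Pan-Tompkins: no peaks above threshold")
        return np.array([])

    # refine: local ECG maximum within +/-75 ms of each MWI detection
    half = int(round(0.075 * fs))
    r_idx = []
    for idx in qrs:
        lo, hi = max(idx - half, 0), min(idx + half + 1, len(ecg))
        r_idx.append(lo + int(np.argmax(ecg[lo:hi])))
    r_idx = np.asarray(sorted(set(r_idx)))
    # drop refinements that collapsed within the refractory period
    keep = np.concatenate([[True], np.diff(r_idx) > refractory])
    r_idx = r_idx[keep]
    return r_idx / fs * 1000.0


def _is_local_max(x: np.ndarray, i: int) -> bool:
    if i <= 0 or i >= len(x) - 1:
        return False
    return x[i] >= x[i - 1] and x[i] >= x[i + 1] and (x[i] > x[i - 1] or x[i] > x[i + 1])


def detect_j_peaks(
    bcg: np.ndarray, r_times: np.ndarray, fs: float,
    window_ms: tuple[float, float] = (110.0, 250.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BCG J-peak per R-peak: the highest sample in (R+110, R+250] ms.

    The window is half-open, ties break to the earliest sample, and a beat is
    flagged invalid when the window is truncated by the record edge or the
    window maximum is not a local maximum.  Returns (times_ms, amplitudes,
    valid) aligned with ``r_times``.
    """
    bcg = np.asarray(bcg, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    n = len(r_times)
    times = np.full(n, np.nan)
    amps = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    lo_off, hi_off = window_ms
    for k, r in enumerate(r_times):
        lo = int(np.floor((r + lo_off) / 1000.0 * fs)) + 1   # strictly > R+110
        hi = int(np.floor((r + hi_off) / 1000.0 * fs)) + 1   # inclusive of R+250
        if lo < 0 or hi > len(bcg):
            continue
        seg = bcg[lo:hi]
        if len(seg) == 0:
            continue
        i = lo + int(np.argmax(seg))
        times[k] = i / fs * 1000.0
        amps[k] = bcg[i]
        valid[k] = _is_local_max(bcg, i)
    return times, amps, valid


def detect_i_notches(
    bcg: np.ndarray, j_times: np.ndarray, fs: float, lookback_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """BCG I-notch per beat: nearest local minimum within ``lookback_ms``
    before the J-peak; invalid when no local minimum exists there."""
    bcg = np.asarray(bcg, dtype=float)
    j_times = np.asarray(j_times, dtype=float)
    n = len(j_times)
    times = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for k, j in enumerate(j_times):
        if not np.isfinite(j):
            continue
        j_idx = int(round(j / 1000.0 * fs))
        lo = max(int(np.ceil((j - lookback_ms) / 1000.0 * fs)), 1)
        if j_idx - 1 <= lo:
            continue
        seg = bcg[lo - 1: j_idx + 1]
        # local minima strictly inside the segment, nearest to J first
        minima = [i for i in range(len(seg) - 2, 0, -1)
                  if seg[i] <= seg[i - 1] and seg[i] <= seg[i + 1]
                  and (seg[i] < seg[i - 1] or seg[i] < seg[i + 1])]
        if not minima:
            continue
        i = lo - 1 + minima[0]
        times[k] = i / fs * 1000.0
        valid[k] = True
    return times, valid


def detect_dppg_peaks(
    ppg: np.ndarray, r_times: np.ndarray, fs: float,
    window_ms: tuple[float, float] = (100.0, 600.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """dPPG peak per R-peak: the maximum of the first PPG derivative in
    (R+100, R+600] ms.

    The derivative is a central difference scaled by fs (one-sided at the
    endpoints); ties break to the earliest sample.  Returns (times_ms,
    dppg_amplitudes, valid).
    """
    ppg = np.asarray(ppg, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    dppg = np.gradient(ppg) * fs
    n = len(r_times)
    times = np.full(n, np.nan)
    amps = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    lo_off, hi_off = window_ms
    for k, r in enumerate(r_times):
        lo = int(np.floor((r + lo_off) / 1000.0 * fs)) + 1
        hi = int(np.floor((r + hi_off) / 1000.0 * fs)) + 1
        if lo < 0 or hi > len(dppg):
            continue
        seg = dppg[lo:hi]
        if len(seg) == 0:
            continue
        i = lo + int(np.argmax(seg))   # argmax -> earliest maximal sample
        times[k] = i / fs * 1000.0
        amps[k] = dppg[i]
        valid[k] = True
    return times, amps, valid


@dataclass
class BeatEvents:
    """Index-aligned per-beat fiducials with per-event validity flags."""

    r_times: np.ndarray
    i_times: np.ndarray
    j_times: np.ndarray
    dppg_times: np.ndarray
    r_amp: np.ndarray
    j_amp: np.ndarray
    dppg_amp: np.ndarray
    valid_r: np.ndarray
    valid_i: np.ndarray
    valid_j: np.ndarray
    valid_dppg: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.r_times)
        for name in ("i_times", "j_times", "dppg_times", "r_amp", "j_amp",
                     "dppg_amp", "valid_r", "valid_i", "valid_j", "valid_dppg"):
            if len(getattr(self, name)) != n:
                raise ValueError("BeatEvents arrays must be index-aligned")

    def __len__(self) -> int:
        return len(self.r_times)

    def copy(self) -> "BeatEvents":
        return BeatEvents(**{k: np.array(v, copy=True) for k, v in self.__dict__.items()})


def _rolling_median(x: np.ndarray, window: int = 31, min_periods: int = 5) -> np.ndarray:
    import pandas as pd

    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=min_periods).median().to_numpy()


def plausibility_filter(
    events: BeatEvents,
    exclude_beats: "np.ndarray | list[int] | None" = None,
    rri_bounds: tuple[float, float] = (300.0, 2000.0),
    ptt_bounds: tuple[float, float] = (100.0, 600.0),
    amp_ratio: float = 5.0,
) -> BeatEvents:
    """Automated replacement for manual false-positive exclusion.

    Invalidates (never re-validates) beats violating physiologic bounds:
    RRI outside ``rri_bounds`` ms, PTT (dPPG - R) outside ``ptt_bounds`` ms,
    or an event amplitude more than ``amp_ratio`` times above -- or below --
    its rolling-median amplitude.  ``exclude_beats`` lists beat indices to
    drop wholesale (the file-based analogue of manual editing).
    """
    out = events.copy()
    n = len(out)
    if n == 0:
        return out

    rri = np.diff(out.r_times, prepend=np.nan)
    bad_rri = np.isfinite(rri) & ((rri < rri_bounds[0]) | (rri > rri_bounds[1]))
    out.valid_r &= ~bad_rri

    ptt = out.dppg_times - out.r_times
    bad_ptt = np.isfinite(ptt) & ((ptt < ptt_bounds[0]) | (ptt > ptt_bounds[1]))
    out.valid_dppg &= ~bad_ptt

    for amp, flag in ((out.r_amp, out.valid_r), (out.j_amp, out.valid_j),
                      (out.dppg_amp, out.valid_dppg)):
        med = _rolling_median(np.abs(amp))
        with np.errstate(invalid="ignore"):
            bad = np.isfinite(amp) & np.isfinite(med) & (med > 0) & (
                (np.abs(amp) > amp_ratio * med) | (np.abs(amp) < med / amp_ratio))
        flag &= ~bad

    # events without a detected time are invalid
    out.valid_i &= np.isfinite(out.i_times)
    out.valid_j &= np.isfinite(out.j_times)
    out.valid_dppg &= np.isfinite(out.dppg_times)

    if exclude_beats is not None:
        ex = np.asarray(list(exclude_beats), dtype=int)
        ex = ex[(ex >= 0) & (ex < n)]
        for flag in (out.valid_r, out.valid_i, out.valid_j, out.valid_dppg):
            flag[ex] = False
    return out


def detect_beat_events(
    ecg: np.ndarray, bcg: np.ndarray, ppg: np.ndarray, fs: float,
    bands: dict[str, FilterSpec] | None = None,
    exclude_beats=None,
    prefiltered: bool = False,
) -> BeatEvents:
    """Full per-record detection pipeline: filter each channel, run the four
    detectors, and apply the plausibility filter."""
    bands = bands or DEFAULT_BANDS
    if not prefiltered:
        ecg = bandpass(ecg, bands["ecg"], fs)
        bcg = bandpass(bcg, bands["bcg"], fs)
        ppg = bandpass(ppg, bands["ppg"], fs)
    r_times = detect_r_peaks(ecg, fs)
    r_idx = np.round(r_times / 1000.0 * fs).astype(int)
    r_amp = ecg[np.clip(r_idx, 0, len(ecg) - 1)] if len(r_idx) else np.array([])
    j_times, j_amp, valid_j = detect_j_peaks(bcg, r_times, fs)
    i_times, valid_i = detect_i_notches(bcg, j_times, fs)
    dppg_times, dppg_amp, valid_dppg = detect_dppg_peaks(ppg, r_times, fs)
    events = BeatEvents(
        r_times=r_times, i_times=i_times, j_times=j_times, dppg_times=dppg_times,
        r_amp=r_amp, j_amp=j_amp, dppg_amp=dppg_amp,
        valid_r=np.ones(len(r_times), dtype=bool),
        valid_i=valid_i, valid_j=valid_j, valid_dppg=valid_dppg,
    )
    return plausibility_filter(events, exclude_beats=exclude_beats)


def match_event_times(
    detected: np.ndarray, truth: np.ndarray, tol_ms: float,
) -> tuple[float, float, int]:
    """Greedy one-to-one matching of detected to truth times.

    Returns (sensitivity, false_positive_rate, n_matched) where sensitivity is
    the fraction of finite truth events matched within ``tol_ms`` and the FP
    rate is unmatched detections over total detections.
    """
    truth = np.asarray(truth, dtype=float)
    truth = truth[np.isfinite(truth)]
    detected = np.asarray(detected, dtype=float)
    detected = detected[np.isfinite(detected)]
    if len(truth) == 0:
        return np.nan, (1.0 if len(detected) else 0.0), 0
    used = np.zeros(len(detected), dtype=bool)
    matched = 0
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_ms:
            used[j] = True
            matched += 1
    sens = matched / len(truth)
    fp = (len(detected) - matched) / len(detected) if len(detected) else 0.0
    return sens, fp, matched
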