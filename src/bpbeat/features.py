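"""Per-beat feature vectors and labeled training sequences.

Seven features per cardiac cycle: four intervals between fiducials (RRI,
PTT = R to dPPG peak, RJI = R to BCG J-peak, IPI = BCG I-notch to dPPG peak)
and three amplitudes (ECG R-peak, BCG J-peak, dPPG peak).  Features are
z-scored with statistics fitted on training data only, then grouped into
sliding windows of L consecutive all-valid beats (default L = 10); each
window's label is the reference SBP/DBP at or immediately after its last
R-peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BeatEvents

__all__ = [
    "FEATURE_SETS",
    "FEATURE_COLUMNS",
    "StandardizationStats",
    "extract_beat_features",
    "fit_standardization",
    "apply_standardization",
    "invert_standardization",
    "assemble_sequences",
    "compute_coverage",
]

FEATURE_COLUMNS = ["rri", "ptt", "rji", "ipi", "ecg_amp", "bcg_amp", "ppg_amp"]

FEATURE_SETS = {
    "ecg": ["rri", "ecg_amp"],
    "ecg+bcg": ["rri", "rji", "ecg_amp", "bcg_amp"],
    "ecg+ppg": ["rri", "ptt", "ecg_amp", "ppg_amp"],
    "ecg+ppg+bcg": FEATURE_COLUMNS,
    "full": FEATURE_COLUMNS,
}


def extract_beat_features(
    events: BeatEvents,
    ref_times: np.ndarray,
    ref_sbp: np.ndarray,
    ref_dbp: np.ndarray,
) -> pd.DataFrame:
    """One feature row per beat, starting from the second beat (RRI needs a
    predecessor).

    Rows with any missing constituent event are kept but marked invalid;
    the intervals that are computable are still recorded.  The per-row
    reference BP is the first reference sample at or after the beat's R-peak.
    Returns an empty frame when fewer than two beats carry a valid R-peak.
    """
    n = len(events)
    if int(np.sum(events.valid_r)) < 2:
        return pd.DataFrame(columns=["beat", "beat_time", *FEATURE_COLUMNS,
                                     "ref_sbp", "ref_dbp", "valid"])
    ref_times = np.asarray(ref_times, dtype=float)
    ref_sbp = np.asarray(ref_sbp, dtype=float)
    ref_dbp = np.asarray(ref_dbp, dtype=float)
    order = np.argsort(ref_times)
    ref_times, ref_sbp, ref_dbp = ref_times[order], ref_sbp[order], ref_dbp[order]

    rows = []
    for i in range(1, n):
        r, r_prev = events.r_times[i], events.r_times[i - 1]
        rri = r - r_prev if np.isfinite(r) and np.isfinite(r_prev) else np.nan
        ptt = events.dppg_times[i] - r
        rji = events.j_times[i] - r
        ipi = events.dppg_times[i] - events.i_times[i]
        k = int(np.searchsorted(ref_times, r, side="left"))
        has_ref = k < len(ref_times)
        sbp = ref_sbp[k] if has_ref else np.nan
        dbp = ref_dbp[k] if has_ref else np.nan
        valid = bool(
            events.valid_r[i] and events.valid_r[i - 1]
            and events.valid_i[i] and events.valid_j[i] and events.valid_dppg[i]
            and np.isfinite([rri, ptt, rji, ipi]).all()
            and rri > 0 and ptt > 0 and rji > 0 and ipi > 0
            and has_ref
        )
        rows.append({
            "beat": i, "beat_time": r, "rri": rri, "ptt": ptt, "rji": rji,
            "ipi": ipi, "ecg_amp": events.r_amp[i], "bcg_amp": events.j_amp[i],
            "ppg_amp": events.dppg_amp[i], "ref_sbp": sbp, "ref_dbp": dbp,
            "valid": valid,
        })
    return pd.DataFrame(rows)


@dataclass
class StandardizationStats:
    """Per-feature mean/SD with the scope (e.g. subject-visit id or 'pooled')
    they were fitted on."""

    mean: pd.Series
    sd: pd.Series
    scope: str = ""

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"degenerate (zero-variance) feature(s): {bad}")


def fit_standardization(
    rows: pd.DataFrame | np.ndarray,
    features: list[str] | None = None,
    scope: str = "",
) -> StandardizationStats:
    """Fit per-feature mean/SD on a training subset.

    ``rows`` is either a feature DataFrame (only ``valid`` rows are used) or
    a sequence array of shape (n, L, F) pooled over windows and timesteps.
    Raises naming the offending feature when any SD is zero.
    """
    if isinstance(rows, pd.DataFrame):
        features = features or FEATURE_COLUMNS
        sub = rows.loc[rows["valid"], features] if "valid" in rows else rows[features]
        if len(sub) < 2:
            raise ValueError("need at least 2 valid rows to fit standardization")
        mean = sub.mean()
        sd = sub.std(ddof=0)
    else:
        x = np.asarray(rows, dtype=float)
        if x.ndim == 3:
            x = x.reshape(-1, x.shape[-1])
        if x.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit standardization")
        features = features or [f"f{i}" for i in range(x.shape[1])]
        mean = pd.Series(x.mean(axis=0), index=features)
        sd = pd.Series(x.std(axis=0, ddof=0), index=features)
    return StandardizationStats(mean=mean, sd=sd, scope=scope)


def apply_standardization(rows, stats: StandardizationStats):
    """Z-score features with previously fitted stats (DataFrame or array)."""
    if isinstance(rows, pd.DataFrame):
        out = rows.copy()
        for f in stats.mean.index:
            out[f] = (out[f] - stats.mean[f]) / stats.sd[f]
        return out
    x = np.asarray(rows, dtype=float)
    return (x - stats.mean.to_numpy()) / stats.sd.to_numpy()


def invert_standardization(rows, stats: StandardizationStats):
    """Inverse of :func:`apply_standardization` with the same stats."""
    if isinstance(rows, pd.DataFrame):
        out = rows.copy()
        for f in stats.mean.index:
            out[f] = out[f] * stats.sd[f] + stats.mean[f]
        return out
    x = np.asarray(rows, dtype=float)
    return x * stats.sd.to_numpy() + stats.mean.to_numpy()


def assemble_sequences(
    rows: pd.DataFrame,
    L: int = 10,
    feature_set: str | list[str] = "full",
    max_gap_s: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Sliding stride-1 windows of L consecutive all-valid beats.

    A sequence is emitted for every row index whose previous L rows (itself
    included) are all valid, contiguous in beat index, and free of inter-beat
    gaps longer than ``max_gap_s``.  The label is the row's own reference
    SBP/DBP (the reference at or after the window's final R-peak).

    Returns ``(X, y, meta)`` with X of shape (n_seq, L, F), y of shape
    (n_seq, 2) as (SBP, DBP), and per-sequence metadata.
    """
    if L < 1:
        raise ValueError("sequence length L must be >= 1")
    feats = FEATURE_SETS[feature_set] if isinstance(feature_set, str) else list(feature_set)
    n = len(rows)
    rows = rows.reset_index(drop=True)
    valid = rows["valid"].to_numpy(dtype=bool)
    times = rows["beat_time"].to_numpy(dtype=float)
    beats = rows["beat"].to_numpy() if "beat" in rows else np.arange(n)

    X_list, y_list, meta = [], [], []
    fmat = rows[feats].to_numpy(dtype=float)
    for end in range(L - 1, n):
        w = slice(end - L + 1, end + 1)
        if not valid[w].all():
            continue
        if np.any(np.diff(beats[w]) != 1):
            continue
        if L > 1 and np.any(np.diff(times[w]) > max_gap_s * 1000.0):
            continue
        X_list.append(fmat[w])
        y_list.append((rows.at[end, "ref_sbp"], rows.at[end, "ref_dbp"]))
        meta.append({
            "end_index": end,
            "end_beat_time": times[end],
            "subject": rows.at[end, "subject"] if "subject" in rows else "",
            "visit": rows.at[end, "visit"] if "visit" in rows else 1,
        })
    F = len(feats)
    X = np.array(X_list, dtype=float).reshape(-1, L, F)
    y = np.array(y_list, dtype=float).reshape(-1, 2)
    return X, y, pd.DataFrame(meta, columns=["end_index", "end_beat_time", "subject", "visit"])


def compute_coverage(rows: pd.DataFrame, L: int) -> float:
    """Fraction of beats that terminate a valid L-sequence (in [0, 1])."""
    if len(rows) == 0:
        raise ValueError("rows is empty")
    _, _, meta = assemble_sequences(rows, L=L)
    return len(meta) / len(rows)
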