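"""Classical calibration-based PTT->BP estimators and linear-regression
comparators.

Three published closed-form models, each anchored at a one-point calibration
(subject baseline values, subscript 0):

* Chen:  SBP = SBP0 - 2/(gamma * PTT0) * (PTT - PTT0)
* Poon:  SBP = MBP0 + (2/gamma) ln(PTT0/PTT) + (2/3) PP0 (PTT0/PTT)^2,
         DBP = MBP0 + (2/gamma) ln(PTT0/PTT) - (1/3) PP0 (PTT0/PTT)^2
* Ding:  SBP = DBP0 (PIR0/PIR) + PP0 (PTT0/PTT)^2,  DBP = DBP0 (PIR0/PIR)

plus ordinary-least-squares multiple linear regression on the beat features
(with or without the BCG intervals, optionally stacking the previous N
cardiac cycles), fitted separately for SBP and DBP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationPoint",
    "calibrate",
    "chen_sbp",
    "poon_bp",
    "ding_bp",
    "compute_pir",
    "MLRModel",
    "mlr_fit",
    "mlr_predict",
    "MLR_VARIANTS",
]

MLR_VARIANTS = {"no_bcg": ["ptt", "rri"], "with_bcg": ["ptt", "rri", "rji", "ipi"]}


@dataclass
class CalibrationPoint:
    """Per-subject calibration constants from a reference window."""

    sbp0: float
    dbp0: float
    ptt0: float
    pir0: float
    gamma_cal: float   # 1/mmHg

    def __post_init__(self) -> None:
        if self.ptt0 <= 0 or self.pir0 <= 0:
            raise ValueError("ptt0 and pir0 must be > 0")

    @property
    def pp0(self) -> float:
        return self.sbp0 - self.dbp0

    @property
    def mbp0(self) -> float:
        return self.dbp0 + self.pp0 / 3.0


def calibrate(rows: pd.DataFrame, pir: np.ndarray | None = None,
              min_beats: int = 10) -> CalibrationPoint:
    """One-point calibration over an initial window of valid beats.

    Constants are the window means; the vessel coefficient gamma comes from a
    least-squares fit of ln(PTT) against reference SBP over the window
    (ln PTT = const - gamma/2 * P under the exponential wall-stiffening law,
    so gamma = -2 * slope).
    """
    sub = rows.loc[rows["valid"]] if "valid" in rows else rows
    if len(sub) < min_beats:
        raise ValueError(f"need >= {min_beats} valid calibration beats, have {len(sub)}")
    ptt = sub["ptt"].to_numpy(dtype=float)
    sbp = sub["ref_sbp"].to_numpy(dtype=float)
    slope = np.polyfit(sbp, np.log(ptt), 1)[0] if np.ptp(sbp) > 0 else 0.0
    gamma = max(-2.0 * slope, 1e-4)
    if pir is None:
        pir_arr = sub["pir"].to_numpy(dtype=float) if "pir" in sub else np.array([1.0])
    else:
        pir_arr = np.asarray(pir, dtype=float)[: len(sub)]
    pir_arr = pir_arr[np.isfinite(pir_arr) & (pir_arr > 0)]
    return CalibrationPoint(
        sbp0=float(sub["ref_sbp"].mean()),
        dbp0=float(sub["ref_dbp"].mean()),
        ptt0=float(np.mean(ptt)),
        pir0=float(np.mean(pir_arr)) if len(pir_arr) else 1.0,
        gamma_cal=float(gamma),
    )


def chen_sbp(ptt, calib: CalibrationPoint):
    """Chen linearization: SBP only (no companion DBP model)."""
    ptt = np.asarray(ptt, dtype=float)
    if np.any(ptt <= 0):
        raise ValueError("ptt must be > 0")
    out = calib.sbp0 - 2.0 / (calib.gamma_cal * calib.ptt0) * (ptt - calib.ptt0)
    return float(out) if out.ndim == 0 else out


def poon_bp(ptt, calib: CalibrationPoint):
    """Poon model: logarithmic mean-pressure term plus a quadratic
    pulse-pressure term, so SBP - DBP = PP0 * (PTT0/PTT)^2 identically."""
    ptt = np.asarray(ptt, dtype=float)
    if np.any(ptt <= 0):
        raise ValueError("ptt must be > 0")
    ratio2 = (calib.ptt0 / ptt) ** 2
    mbp = calib.mbp0 + (2.0 / calib.gamma_cal) * np.log(calib.ptt0 / ptt)
    sbp = mbp + (2.0 / 3.0) * calib.pp0 * ratio2
    dbp = mbp - (1.0 / 3.0) * calib.pp0 * ratio2
    if sbp.ndim == 0:
        return float(sbp), float(dbp)
    return sbp, dbp


def ding_bp(ptt, pir, calib: CalibrationPoint):
    """Ding model: DBP scales inversely with the pulse intensity ratio; SBP
    adds the quadratic transit-time pulse-pressure term."""
    ptt = np.asarray(ptt, dtype=float)
    pir = np.asarray(pir, dtype=float)
    if np.any(ptt <= 0) or np.any(pir <= 0):
        raise ValueError("ptt and pir must be > 0")
    dbp = calib.dbp0 * (calib.pir0 / pir)
    sbp = dbp + calib.pp0 * (calib.ptt0 / ptt) ** 2
    if sbp.ndim == 0:
        return float(sbp), float(dbp)
    return sbp, dbp


def compute_pir(ppg: np.ndarray, r_times: np.ndarray, fs: float,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Pulse intensity ratio per beat: maximum over minimum PPG value within
    each R-R interval.

    Requires a positive-baseline PPG (raw sensor level, not the zero-mean
    band-passed trace); beats whose minimum is <= 0 or whose pulse is
    missing are flagged invalid.  Returns (pir, valid) aligned with beats
    (the last beat, lacking a closing R, is invalid).
    """
    ppg = np.asarray(ppg, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    n = len(r_times)
    pir = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for k in range(n - 1):
        lo = int(np.ceil(r_times[k] / 1000.0 * fs))
        hi = int(np.floor(r_times[k + 1] / 1000.0 * fs))
        if hi <= lo or lo < 0 or hi > len(ppg):
            continue
        seg = ppg[lo:hi]
        mx, mn = float(np.max(seg)), float(np.min(seg))
        if mn <= 0:
            continue
        ratio = mx / mn
        if ratio <= 1.0 + 1e-12:   # flat segment: no discernible pulse
            continue
        pir[k] = ratio
        valid[k] = True
    return pir, valid


@dataclass
class MLRModel:
    """Per-target OLS coefficients on (optionally lagged) beat features."""

    features: list[str]
    n_lags: int
    intercept_sbp: float
    coef_sbp: np.ndarray
    intercept_dbp: float
    coef_dbp: np.ndarray

    @property
    def column_names(self) -> list[str]:
        if self.n_lags == 1:
            return list(self.features)
        return [f"{f}_lag{k}" for k in range(self.n_lags) for f in self.features]


def _design(rows: pd.DataFrame, features: list[str], n_lags: int):
    sub = rows.reset_index(drop=True)
    base = sub[features].to_numpy(dtype=float)
    if n_lags == 1:
        X = base
        keep = sub["valid"].to_numpy(dtype=bool) & np.isfinite(X).all(axis=1)
    else:
        n = len(sub)
        cols = []
        for k in range(n_lags):
            shifted = np.full_like(base, np.nan)
            if k == 0:
                shifted = base
            else:
                shifted[k:] = base[:-k]
            cols.append(shifted)
        X = np.concatenate(cols, axis=1)
        vmask = sub["valid"].to_numpy(dtype=bool)
        vlag = np.ones(n, dtype=bool)
        for k in range(n_lags):
            rolled = np.zeros(n, dtype=bool)
            rolled[k:] = vmask[: n - k] if k else vmask
            vlag &= rolled
        keep = vlag & np.isfinite(X).all(axis=1)
    y = sub[["ref_sbp", "ref_dbp"]].to_numpy(dtype=float)
    keep &= np.isfinite(y).all(axis=1)
    return X[keep], y[keep], keep


def mlr_fit(rows: pd.DataFrame, variant: str = "with_bcg", n_lags: int = 1,
            ) -> MLRModel:
    """Fit the MLR baseline by ordinary least squares, SBP and DBP
    separately.

    ``variant`` selects the feature set ('no_bcg' = PTT+RRI, 'with_bcg'
    adds RJI+IPI); ``n_lags`` stacks each feature over the previous n_lags
    cardiac cycles.  Raises on rank-deficient designs, naming the collinear
    columns.
    """
    if variant not in MLR_VARIANTS:
        raise ValueError(f"variant must be one of {sorted(MLR_VARIANTS)}")
    feats = MLR_VARIANTS[variant]
    X, y, _ = _design(rows, feats, n_lags)
    p = X.shape[1] + 1
    if len(X) < 2 * p:
        raise ValueError(f"need >= {2 * p} training rows, have {len(X)}")
    A = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify collinear columns via the QR diagonal
        names = ["intercept"] + MLRModel(feats, n_lags, 0, np.empty(0), 0,
                                         np.empty(0)).column_names
        diag = np.abs(np.diag(np.linalg.qr(A, mode="r")))
        bad = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return MLRModel(feats, n_lags, float(beta[0, 0]), beta[1:, 0].copy(),
                    float(beta[0, 1]), beta[1:, 1].copy())


def mlr_predict(model: MLRModel, rows: pd.DataFrame,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict (sbp, dbp, keep_mask) on feature rows; the mask marks the rows
    with a complete (lagged) design."""
    X, _, keep = _design(rows, model.features, model.n_lags)
    sbp = model.intercept_sbp + X @ model.coef_sbp
    dbp = model.intercept_dbp + X @ model.coef_dbp
    return sbp, dbp, keep
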