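"""Regression metrics and device-standard grading for BP estimators.

Covers the usual agreement metrics (MAE, RMSE, mean error, error SD, Pearson
correlation, R^2), Bland-Altman limits of agreement, the British Hypertension
Society cumulative-error grading (A-D from the percentages of absolute errors
within 5/10/15 mmHg), the AAMI mean-error/SD criterion, and hypertension-class
confusion accuracy.  Sample standard deviations use the n-1 denominator
throughout; all grading thresholds are inclusive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "regression_metrics",
    "bland_altman",
    "bhs_grade",
    "aami_check",
    "classify_hypertension",
    "class_accuracy",
    "EvalReport",
    "paired_subject_test",
    "bland_altman_plot",
    "scatter_plot",
]

def __getattr__(name):
    # the sequence-length sweep trains models, so it lives with the protocols;
    # re-exported here lazily to avoid a circular import
    if name == "sequence_length_sweep":
        from .protocols import sequence_length_sweep
        return sequence_length_sweep
    raise AttributeError(name)


BHS_TABLE = {  # grade -> minimum cumulative % within 5 / 10 / 15 mmHg
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

SBP_CLASS_EDGES = [("Normal", -np.inf, 120.0), ("Prehypertension", 120.0, 130.0),
                   ("Stage 1 Hypertension", 130.0, 140.0),
                   ("Stage 2 Hypertension", 140.0, np.inf)]
DBP_CLASS_EDGES = [("Normal", -np.inf, 80.0), ("Stage 1 Hypertension", 80.0, 90.0),
                   ("Stage 2 Hypertension", 90.0, np.inf)]


def _as_pair(est, ref):
    est = np.asarray(est, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if len(est) != len(ref):
        raise ValueError("est and ref must be equally long")
    return est, ref


def regression_metrics(est, ref) -> dict:
    """MAE, RMSE, ME, STD (of errors, n-1), Pearson CC and R^2.

    CC is NaN (with a warning) when the reference has zero variance.
    """
    est, ref = _as_pair(est, ref)
    if len(est) < 2:
        raise ValueError("need n >= 2")
    err = est - ref
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    me = float(np.mean(err))
    std = float(np.std(err, ddof=1))
    sstot = float(np.sum((ref - ref.mean()) ** 2))
    if sstot == 0 or np.std(est) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        cc = np.nan
    else:
        cc = float(np.corrcoef(est, ref)[0, 1])
    r2 = np.nan if sstot == 0 else float(1.0 - np.sum(err**2) / sstot)
    return {"mae": mae, "rmse": rmse, "me": me, "std": std, "cc": cc,
            "r2": r2, "n": len(est)}


def bland_altman(est, ref) -> tuple[float, float, float]:
    """(bias, lower, upper): mean error +/- 1.96 x sample SD of the errors."""
    est, ref = _as_pair(est, ref)
    if len(est) < 2:
        raise ValueError("need n >= 2")
    err = est - ref
    bias = float(np.mean(err))
    sd = float(np.std(err, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def bhs_grade(abs_errors) -> tuple[float, float, float, str]:
    """Cumulative percentages of |error| <= 5/10/15 mmHg and the BHS grade.

    A grade requires all three of its thresholds to be met simultaneously;
    boundaries are inclusive.
    """
    abs_errors = np.abs(np.asarray(abs_errors, dtype=float).ravel())
    if len(abs_errors) < 1:
        raise ValueError("need n >= 1")
    pct5 = float(np.mean(abs_errors <= 5.0) * 100.0)
    pct10 = float(np.mean(abs_errors <= 10.0) * 100.0)
    pct15 = float(np.mean(abs_errors <= 15.0) * 100.0)
    grade = "D"
    for g in ("C", "B", "A"):
        t5, t10, t15 = BHS_TABLE[g]
        if pct5 >= t5 and pct10 >= t10 and pct15 >= t15:
            grade = g
    return pct5, pct10, pct15, grade


def aami_check(errors, n_required: int = 85) -> dict:
    """AAMI verdict: pass iff |mean error| <= 5 and error SD <= 8 mmHg.

    The 85-subject population requirement is reported as a separate flag and
    does not gate the error verdict.
    """
    errors = np.asarray(errors, dtype=float).ravel()
    if len(errors) < 2:
        raise ValueError("need n >= 2")
    me = float(np.mean(errors))
    std = float(np.std(errors, ddof=1))
    return {"me": me, "std": std, "pass": bool(abs(me) <= 5.0 and std <= 8.0),
            "population_ok": bool(len(errors) >= n_required), "n": len(errors)}


def classify_hypertension(values, target: str = "sbp") -> np.ndarray:
    """Bin pressures into hypertension classes.

    SBP: <120 Normal, [120,130) Prehypertension, [130,140) Stage 1, >=140
    Stage 2.  DBP: <80 Normal, [80,90) Stage 1, >=90 Stage 2 (no
    prehypertension band for DBP).
    """
    edges = SBP_CLASS_EDGES if target.lower() == "sbp" else DBP_CLASS_EDGES
    values = np.asarray(values, dtype=float).ravel()
    out = np.empty(len(values), dtype=object)
    for name, lo, hi in edges:
        out[(values >= lo) & (values < hi)] = name
    return out


def class_accuracy(est_classes, ref_classes) -> dict:
    """Per-reference-class and beat-weighted total classification accuracy."""
    est_classes = np.asarray(est_classes, dtype=object)
    ref_classes = np.asarray(ref_classes, dtype=object)
    if len(est_classes) != len(ref_classes):
        raise ValueError("length mismatch")
    hit = est_classes == ref_classes
    per_class = {}
    for c in pd.unique(ref_classes):
        m = ref_classes == c
        per_class[str(c)] = float(np.mean(hit[m]))
    return {"per_class": per_class, "total": float(np.mean(hit)),
            "n": len(ref_classes)}


@dataclass
class EvalReport:
    """Full evaluation of one set of beatwise (SBP, DBP) estimates."""

    sbp: dict
    dbp: dict
    bland_altman_sbp: tuple
    bland_altman_dbp: tuple
    bhs_sbp: tuple
    bhs_dbp: tuple
    aami_sbp: dict
    aami_dbp: dict
    hypertension_sbp: dict
    hypertension_dbp: dict
    n: int = 0

    @classmethod
    def from_predictions(cls, est_sbp, ref_sbp, est_dbp, ref_dbp) -> "EvalReport":
        est_sbp, ref_sbp = _as_pair(est_sbp, ref_sbp)
        est_dbp, ref_dbp = _as_pair(est_dbp, ref_dbp)
        return cls(
            sbp=regression_metrics(est_sbp, ref_sbp),
            dbp=regression_metrics(est_dbp, ref_dbp),
            bland_altman_sbp=bland_altman(est_sbp, ref_sbp),
            bland_altman_dbp=bland_altman(est_dbp, ref_dbp),
            bhs_sbp=bhs_grade(est_sbp - ref_sbp),
            bhs_dbp=bhs_grade(est_dbp - ref_dbp),
            aami_sbp=aami_check(est_sbp - ref_sbp),
            aami_dbp=aami_check(est_dbp - ref_dbp),
            hypertension_sbp=class_accuracy(
                classify_hypertension(est_sbp, "sbp"),
                classify_hypertension(ref_sbp, "sbp")),
            hypertension_dbp=class_accuracy(
                classify_hypertension(est_dbp, "dbp"),
                classify_hypertension(ref_dbp, "dbp")),
            n=len(est_sbp),
        )

    def summary(self) -> str:
        rows = []
        for name, m, ba, bhs, aami in (
                ("SBP", self.sbp, self.bland_altman_sbp, self.bhs_sbp, self.aami_sbp),
                ("DBP", self.dbp, self.bland_altman_dbp, self.bhs_dbp, self.aami_dbp)):
            rows.append(
                f"{name}: MAE {m['mae']:.2f}  RMSE {m['rmse']:.2f}  CC {m['cc']:.2f}  "
                f"R2 {m['r2']:.2f}  ME {m['me']:.2f}  STD {m['std']:.2f} mmHg\n"
                f"     Bland-Altman [{ba[1]:.2f}, {ba[2]:.2f}]  "
                f"BHS {bhs[3]} ({bhs[0]:.0f}/{bhs[1]:.0f}/{bhs[2]:.0f}%)  "
                f"AAMI {'pass' if aami['pass'] else 'fail'}")
        return f"Evaluation over n={self.n} estimates\n" + "\n".join(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.bool_):
                return bool(o)
            raise TypeError(type(o))
        s = json.dumps(asdict(self), indent=1, default=default)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "EvalReport":
        text = str(source)
        if isinstance(source, Path) or not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        for k in ("bland_altman_sbp", "bland_altman_dbp", "bhs_sbp", "bhs_dbp"):
            d[k] = tuple(d[k])
        return cls(**d)


def paired_subject_test(per_subject_a, per_subject_b, method: str = "wilcoxon"):
    """Paired two-sided comparison of per-subject MAEs (model A vs model B).

    Default is the Wilcoxon signed-rank test; ``method='ttest'`` selects the
    paired t-test.  Returns (statistic, p_value).
    """
    a = np.asarray(per_subject_a, dtype=float)
    b = np.asarray(per_subject_b, dtype=float)
    if method == "wilcoxon":
        res = sstats.wilcoxon(a, b)
    elif method == "ttest":
        res = sstats.ttest_rel(a, b)
    else:
        raise ValueError("method must be 'wilcoxon' or 'ttest'")
    return float(res.statistic), float(res.pvalue)


def bland_altman_plot(est, ref, ax=None, title: str = ""):
    """Difference-vs-mean plot with bias and 95% limits of agreement."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    est, ref = _as_pair(est, ref)
    bias, lo, hi = bland_altman(est, ref)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((est + ref) / 2, est - ref, s=4, alpha=0.4)
    ax.axhline(bias, color="k")
    for y in (lo, hi):
        ax.axhline(y, color="r", linestyle="--")
    ax.set_xlabel("mean of estimate and reference (mmHg)")
    ax.set_ylabel("estimate - reference (mmHg)")
    ax.set_title(title or f"bias {bias:.2f}, LoA [{lo:.2f}, {hi:.2f}]")
    return ax


def scatter_plot(est, ref, ax=None, title: str = ""):
    """Estimate-vs-reference scatter with the identity line and R^2."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    est, ref = _as_pair(est, ref)
    m = regression_metrics(est, ref)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ref, est, s=4, alpha=0.4)
    lims = [min(ref.min(), est.min()), max(ref.max(), est.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("reference BP (mmHg)")
    ax.set_ylabel("estimated BP (mmHg)")
    ax.set_title(title or f"R$^2$ = {m['r2']:.2f}")
    return ax
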