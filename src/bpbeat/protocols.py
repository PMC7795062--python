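"""Training and evaluation protocols for the Bi-LSTM BP model.

Four regimes mirror how person-specific and general cuffless-BP models are
studied:

* personal  -- train and test within one subject-visit (random 60/20/20
  split of that recording's sequences);
* LOSO      -- leave one subject out entirely, train on the pooled others
  (with demographic inputs), evaluate on the excluded subject;
* tuned LOSO -- freeze the recurrent block of a LOSO model and retrain only
  the fully connected head on a small fraction (default 20%) of the excluded
  subject's sequences, disjoint from the test portion;
* multi-day  -- train on one visit, test on the other, in both directions.

All splits and initializations are driven by seeds derived deterministically
from a single protocol seed and the subject id, so the test portions line up
across protocols and the benchmarks are reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .evaluate import EvalReport
from .features import (FEATURE_SETS, assemble_sequences, apply_standardization,
                       compute_coverage, extract_beat_features,
                       fit_standardization)
from .model import (NetSpec, SequenceBPModel, SequenceBPResults, TrainConfig,
                    sequence_fingerprints, train_network)
from .preprocess import BeatEvents, detect_beat_events
from .simulate import WaveformRecord

log = logging.getLogger(__name__)

__all__ = [
    "InsufficientDataError",
    "SubjectData",
    "ProtocolResult",
    "events_from_truth",
    "record_features",
    "build_dataset",
    "run_personal",
    "run_loso",
    "predict_on_subject",
    "fine_tune",
    "run_multi_day",
    "sequence_length_sweep",
    "DEMOGRAPHIC_FIELDS",
]

DEMOGRAPHIC_FIELDS = ["gender", "age", "height", "weight", "bmi"]


class InsufficientDataError(ValueError):
    """Raised when a protocol has too few sequences to run."""


def _stable_seed(*parts) -> int:
    h = 0
    for p in parts:
        h = zlib.crc32(str(p).encode(), h)
    return h % (2**31)


def events_from_truth(truth: pd.DataFrame) -> BeatEvents:
    """Build BeatEvents from a simulator ground-truth table (the oracle
    path: validity is simply event presence)."""
    g = lambda c: truth[c].to_numpy(dtype=float)
    r, i, j, dppg = g("r_ms"), g("i_ms"), g("j_ms"), g("dppg_ms")
    return BeatEvents(
        r_times=r, i_times=i, j_times=j, dppg_times=dppg,
        r_amp=g("ecg_amp"), j_amp=g("bcg_amp"), dppg_amp=g("ppg_amp"),
        valid_r=np.isfinite(r), valid_i=np.isfinite(i),
        valid_j=np.isfinite(j), valid_dppg=np.isfinite(dppg),
    )


def record_features(record: WaveformRecord, source: str = "truth",
                    exclude_beats=None) -> pd.DataFrame:
    """Per-beat feature rows for one record, from ground-truth events
    (``source='truth'``) or from the full detection pipeline
    (``source='detected'``)."""
    if source == "truth":
        if record.truth_events is None:
            raise ValueError("record has no truth events")
        events = events_from_truth(record.truth_events)
    elif source == "detected":
        events = detect_beat_events(record.ecg, record.bcg, record.ppg,
                                    record.fs, exclude_beats=exclude_beats)
    else:
        raise ValueError("source must be 'truth' or 'detected'")
    rows = extract_beat_features(events, record.beat_times,
                                 record.ref_sbp, record.ref_dbp)
    rows["subject"] = record.subject.subject_id
    rows["visit"] = record.visit
    return rows


@dataclass
class SubjectData:
    """Feature rows plus demographics for one subject-visit."""

    subject_id: str
    visit: int
    rows: pd.DataFrame
    demographics: dict

    @property
    def demo_vector(self) -> np.ndarray:
        return np.array([self.demographics[f] for f in DEMOGRAPHIC_FIELDS], dtype=float)


def build_dataset(records: list[WaveformRecord], source: str = "truth") -> list[SubjectData]:
    """One SubjectData per record (= per subject-visit)."""
    return [SubjectData(r.subject.subject_id, r.visit,
                        record_features(r, source=source),
                        dict(r.subject.demographics)) for r in records]


@dataclass
class ProtocolResult:
    """Predictions and provenance from one protocol evaluation."""

    protocol: str
    predictions: pd.DataFrame   # est_sbp, est_dbp, ref_sbp, ref_dbp, subject, visit
    results: SequenceBPResults | None = None
    fingerprints: dict = field(default_factory=dict)

    @property
    def report(self) -> EvalReport:
        p = self.predictions
        return EvalReport.from_predictions(p["est_sbp"], p["ref_sbp"],
                                           p["est_dbp"], p["ref_dbp"])

    def summary(self) -> str:
        return f"[{self.protocol}]\n" + self.report.summary()


def _split_indices(n: int, config: TrainConfig, rng: np.random.Generator):
    order = rng.permutation(n)
    n_test = int(round(config.test_frac * n))
    n_val = int(round(config.val_frac * n))
    test = order[:n_test]
    val = order[n_test: n_test + n_val]
    train = order[n_test + n_val:]
    return train, val, test


def _subject_split(sdata: SubjectData, config: TrainConfig, L, feature_set):
    """Deterministic per-subject sequences + 60/20/20 split, shared across
    protocols so test portions coincide."""
    X, y, meta = assemble_sequences(sdata.rows, L=L, feature_set=feature_set)
    rng = np.random.default_rng(
        _stable_seed("split", config.seed, sdata.subject_id, sdata.visit))
    train, val, test = _split_indices(len(X), config, rng)
    return X, y, meta, train, val, test


def _predictions_frame(est, y, sdata: SubjectData) -> pd.DataFrame:
    return pd.DataFrame({
        "est_sbp": est[:, 0], "est_dbp": est[:, 1],
        "ref_sbp": y[:, 0], "ref_dbp": y[:, 1],
        "subject": sdata.subject_id, "visit": sdata.visit,
    })


def run_personal(
    sdata: SubjectData,
    config: TrainConfig | None = None,
    spec: NetSpec | None = None,
    feature_set: str = "full",
    L: int = 10,
    min_sequences: int = 100,
) -> ProtocolResult:
    """Person-specific model: shuffled 60/20/20 split of one subject-visit's
    sequences, ``n_runs`` averaged networks, no demographic input."""
    config = config or TrainConfig()
    X, y, meta, train, val, test = _subject_split(sdata, config, L, feature_set)
    if len(X) < min_sequences:
        raise InsufficientDataError(
            f"{sdata.subject_id} v{sdata.visit}: {len(X)} sequences "
            f"(< {min_sequences})")
    stats = fit_standardization(X[train], scope=f"{sdata.subject_id}-v{sdata.visit}")
    Xs = apply_standardization(X, stats)
    if spec is None:
        spec = NetSpec(seq_len=L, n_features=X.shape[2])
    model = SequenceBPModel(Xs[train], y[train], Xs[val], y[val], spec=spec)
    run_config = TrainConfig(**{**config.__dict__,
                                "seed": _stable_seed("personal", config.seed,
                                                     sdata.subject_id, sdata.visit)})
    res = model.fit(run_config)
    res.provenance = {"protocol": "personal", "subject": sdata.subject_id,
                      "visit": sdata.visit, "stats": stats}
    est = res.predict(Xs[test])
    return ProtocolResult(
        "personal", _predictions_frame(est, y[test], sdata), res,
        fingerprints={"train": sequence_fingerprints(X[train]),
                      "val": sequence_fingerprints(X[val]),
                      "test": sequence_fingerprints(X[test])})


def _demo_matrix(sdatas, n_per, demo_stats=None):
    rows = np.concatenate([np.tile(sd.demo_vector, (n, 1))
                           for sd, n in zip(sdatas, n_per)]) if sdatas else np.empty((0, 5))
    if demo_stats is None:
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mean[0], sd[0] = 0.0, 1.0   # gender stays 0/1
        demo_stats = (mean, sd)
    mean, sd = demo_stats
    return (rows - mean) / sd, demo_stats


def run_loso(
    dataset: list[SubjectData],
    excluded_subject: str,
    config: TrainConfig | None = None,
    spec: NetSpec | None = None,
    feature_set: str = "full",
    L: int = 10,
) -> SequenceBPResults:
    """Leave-one-subject-out general model.

    Trains on the pooled sequences of every other subject (stratified
    80/20 train/validation within each subject), with demographic inputs;
    the excluded subject's data touches neither training nor the
    standardization statistics.
    """
    config = config or TrainConfig()
    subjects = {sd.subject_id for sd in dataset}
    if excluded_subject not in subjects:
        raise ValueError(f"unknown subject id {excluded_subject!r}")
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    pool = [sd for sd in dataset if sd.subject_id != excluded_subject]

    Xtr, ytr, Xva, yva, tr_sd, tr_n, va_sd, va_n = [], [], [], [], [], [], [], []
    rel_val = config.val_frac / (config.train_frac + config.val_frac)
    for sd in pool:
        X, y, _ = assemble_sequences(sd.rows, L=L, feature_set=feature_set)
        if len(X) == 0:
            continue
        rng = np.random.default_rng(
            _stable_seed("loso-split", config.seed, sd.subject_id, sd.visit))
        order = rng.permutation(len(X))
        n_val = max(int(round(rel_val * len(X))), 1)
        va, tr = order[:n_val], order[n_val:]
        Xtr.append(X[tr]); ytr.append(y[tr]); tr_sd.append(sd); tr_n.append(len(tr))
        Xva.append(X[va]); yva.append(y[va]); va_sd.append(sd); va_n.append(len(va))
    Xtr = np.concatenate(Xtr); ytr = np.concatenate(ytr)
    Xva = np.concatenate(Xva); yva = np.concatenate(yva)

    stats = fit_standardization(Xtr, scope="pooled-loso")
    Xtr_s = apply_standardization(Xtr, stats)
    Xva_s = apply_standardization(Xva, stats)
    demo_tr, demo_stats = _demo_matrix(tr_sd, tr_n)
    demo_va, _ = _demo_matrix(va_sd, va_n, demo_stats)

    if spec is None:
        spec = NetSpec(seq_len=L, n_features=Xtr.shape[2], use_demographics=True)
    model = SequenceBPModel(Xtr_s, ytr, Xva_s, yva, demographics=demo_tr,
                            demographics_val=demo_va, spec=spec)
    run_config = TrainConfig(**{**config.__dict__,
                                "seed": _stable_seed("loso", config.seed,
                                                     excluded_subject)})
    res = model.fit(run_config)
    res.provenance = {
        "protocol": "loso", "excluded_subject": excluded_subject,
        "stats": stats, "demo_stats": demo_stats,
        "feature_set": feature_set, "L": L,
        "train_fingerprints": sequence_fingerprints(Xtr),
        "val_fingerprints": sequence_fingerprints(Xva),
    }
    return res


def _subject_demo(res: SequenceBPResults, sdata: SubjectData, n: int):
    if not res.spec.use_demographics:
        return None
    demo, _ = _demo_matrix([sdata], [n], res.provenance["demo_stats"])
    return demo


def predict_on_subject(
    res: SequenceBPResults, sdata: SubjectData,
    config: TrainConfig | None = None,
    portion: str = "test",
    protocol_name: str = "loso",
) -> ProtocolResult:
    """Evaluate a trained (LOSO or tuned) model on a subject's standard test
    portion (``portion='test'``) or on the whole recording (``'all'``)."""
    config = config or TrainConfig()
    L = res.provenance.get("L", res.spec.seq_len)
    feature_set = res.provenance.get("feature_set", "full")
    X, y, meta, train, val, test = _subject_split(sdata, config, L, feature_set)
    idx = test if portion == "test" else np.arange(len(X))
    Xs = apply_standardization(X[idx], res.provenance["stats"])
    est = res.predict(Xs, _subject_demo(res, sdata, len(idx)))
    return ProtocolResult(
        protocol_name, _predictions_frame(est, y[idx], sdata), res,
        fingerprints={"test": sequence_fingerprints(X[idx]),
                      "train": res.provenance.get("train_fingerprints", set()),
                      "val": res.provenance.get("val_fingerprints", set())})


def fine_tune(
    loso_res: SequenceBPResults,
    sdata: SubjectData,
    fraction: float = 0.2,
    config: TrainConfig | None = None,
    max_epochs: int = 50,
    patience: int = 10,
    tune_val_frac: float = 0.25,
    evaluate_portion: str = "test",
) -> ProtocolResult:
    """Fine-tune the fully connected head of a LOSO model on a random
    ``fraction`` of the excluded subject's sequences.

    The recurrent block is bit-frozen; the tuning subset is drawn from the
    non-test portion, so it is disjoint from the test sequences used for
    evaluation.  A quarter of the tuning subset is held out for early
    stopping.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    config = config or TrainConfig()
    L = loso_res.provenance.get("L", loso_res.spec.seq_len)
    feature_set = loso_res.provenance.get("feature_set", "full")
    X, y, meta, train, val, test = _subject_split(sdata, config, L, feature_set)
    pool = np.concatenate([train, val])
    n_tune = int(round(fraction * len(X)))
    if n_tune < 2 or len(pool) < n_tune:
        raise InsufficientDataError("tuning set empty or too small")
    rng = np.random.default_rng(
        _stable_seed("tune", config.seed, sdata.subject_id, sdata.visit))
    tune_idx = rng.permutation(pool)[:n_tune]
    n_tv = max(int(round(tune_val_frac * n_tune)), 1)
    tv_idx, tt_idx = tune_idx[:n_tv], tune_idx[n_tv:]

    stats = loso_res.provenance["stats"]
    Xs = apply_standardization(X, stats)
    demo_all = _subject_demo(loso_res, sdata, len(X))

    tuned = loso_res.copy()
    new_runs, new_hists = [], []
    for r, params in enumerate(tuned.runs):
        run_rng = np.random.default_rng(
            _stable_seed("tune-run", config.seed, sdata.subject_id, sdata.visit, r))
        p, h = train_network(
            params, tuned.spec, Xs[tt_idx], y[tt_idx], Xs[tv_idx], y[tv_idx],
            config, run_rng,
            demo_train=None if demo_all is None else demo_all[tt_idx],
            demo_val=None if demo_all is None else demo_all[tv_idx],
            trainable_blocks=("fc",), max_epochs=max_epochs, patience=patience,
            init_output_bias=False)
        new_runs.append(p)
        new_hists.append(h)
    tuned.runs = new_runs
    tuned.histories = new_hists
    tuned.provenance = {**loso_res.provenance, "protocol": "tuned_loso",
                        "tuned_subject": sdata.subject_id,
                        "tune_fraction": fraction, "n_tune": n_tune}

    idx = test if evaluate_portion == "test" else np.arange(len(X))
    est = tuned.predict(Xs[idx], None if demo_all is None else demo_all[idx])
    return ProtocolResult(
        "tuned_loso", _predictions_frame(est, y[idx], sdata), tuned,
        fingerprints={"tune": sequence_fingerprints(X[tune_idx]),
                      "test": sequence_fingerprints(X[idx]),
                      "train": loso_res.provenance.get("train_fingerprints", set())})


def run_multi_day(
    dataset: list[SubjectData],
    subject: str,
    protocol: str,
    config: TrainConfig | None = None,
    spec: NetSpec | None = None,
    feature_set: str = "full",
    L: int = 10,
    fraction: float = 0.2,
) -> dict[str, ProtocolResult]:
    """Inter-visit reproducibility: train on one visit, test on the other.

    ``protocol`` is one of 'personal', 'loso', 'tuned_loso'.  Returns results
    per direction ('1->2', '2->1') plus their pooled combination (the pooled
    predictions concatenate both directions, so the pooled report is the
    sample-size-weighted combination).
    """
    if protocol not in ("personal", "loso", "tuned_loso"):
        raise ValueError(f"unknown protocol {protocol!r}")
    config = config or TrainConfig()
    mine = {sd.visit: sd for sd in dataset if sd.subject_id == subject}
    if 1 not in mine or 2 not in mine:
        raise ValueError(f"subject {subject!r} lacks one of the two visits")

    out: dict[str, ProtocolResult] = {}
    for a, b in ((1, 2), (2, 1)):
        sd_a, sd_b = mine[a], mine[b]
        Xb, yb, _ = assemble_sequences(sd_b.rows, L=L, feature_set=feature_set)
        if protocol == "personal":
            pr = run_personal(sd_a, config, spec=spec, feature_set=feature_set,
                              L=L, min_sequences=2)
            res = pr.results
            Xb_s = apply_standardization(Xb, res.provenance["stats"])
            est = res.predict(Xb_s)
            fp = pr.fingerprints
        else:
            # train the general model on the other subjects' training-visit
            # data, falling back to whatever visit a subject has recorded
            others = []
            for oid in sorted({sd.subject_id for sd in dataset} - {subject}):
                theirs = [sd for sd in dataset if sd.subject_id == oid]
                same = [sd for sd in theirs if sd.visit == a]
                others.append(same[0] if same else theirs[0])
            res = run_loso(others + [sd_a], subject, config, spec=spec,
                           feature_set=feature_set, L=L)
            if protocol == "tuned_loso":
                pr = fine_tune(res, sd_a, fraction=fraction, config=config)
                res = pr.results
                fp = pr.fingerprints
            else:
                fp = {"train": res.provenance["train_fingerprints"]}
            Xb_s = apply_standardization(Xb, res.provenance["stats"])
            est = res.predict(Xb_s, _subject_demo(res, sd_b, len(Xb)))
        out[f"{a}->{b}"] = ProtocolResult(
            f"{protocol} {a}->{b}", _predictions_frame(est, yb, sd_b), res,
            fingerprints={**fp, "test": sequence_fingerprints(Xb)})
    pooled = pd.concat([out["1->2"].predictions, out["2->1"].predictions],
                       ignore_index=True)
    out["pooled"] = ProtocolResult(f"{protocol} multi-day pooled", pooled)
    return out


def sequence_length_sweep(
    sdata: SubjectData,
    lengths=range(1, 31),
    config: TrainConfig | None = None,
    spec_for_length=None,
    feature_set: str = "full",
    min_sequences: int = 30,
) -> pd.DataFrame:
    """Personal-model MAE and data coverage as the sequence length varies.

    ``spec_for_length`` maps L to a NetSpec (defaults to the standard
    architecture at each L).  Lengths with too few sequences are skipped with
    a warning.  Returns a frame with L, coverage, mae_sbp, mae_dbp.
    """
    config = config or TrainConfig()
    n_feat = len(FEATURE_SETS[feature_set])
    rows = []
    for L in lengths:
        cov = compute_coverage(sdata.rows, L)
        spec = (spec_for_length(L) if spec_for_length is not None
                else NetSpec(seq_len=L, n_features=n_feat))
        try:
            pr = run_personal(sdata, config, spec=spec, feature_set=feature_set,
                              L=L, min_sequences=min_sequences)
        except InsufficientDataError as e:
            log.warning("sweep: skipping L=%d (%s)", L, e)
            continue
        rep = pr.report
        rows.append({"L": L, "coverage": cov, "mae_sbp": rep.sbp["mae"],
                     "mae_dbp": rep.dbp["mae"], "n_test": rep.n})
    return pd.DataFrame(rows)
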