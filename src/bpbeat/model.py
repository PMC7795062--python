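"""Bi-LSTM blood-pressure regression: model and results objects.

`SequenceBPModel` wraps labeled feature sequences (and optional demographic
inputs) together with an architecture spec; its :meth:`~SequenceBPModel.fit`
trains one or more networks (Adam, MSE on the joint (SBP, DBP) target, early
stopping on a validation split, best-checkpoint restoration) and returns a
:class:`SequenceBPResults` carrying the fitted parameter stores, training
histories and evaluation helpers.  Repeated runs with different
initializations are averaged at prediction time.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn import NetSpec
from .evaluate import EvalReport
from .features import StandardizationStats

__all__ = ["NetSpec", "TrainConfig", "SequenceBPModel", "SequenceBPResults",
           "train_network", "sequence_fingerprints"]


@dataclass
class TrainConfig:
    """Optimization recipe: Adam at 1e-3 on MSE, batches of 64, up to 100
    epochs with early-stopping patience 10, three averaged runs, and a
    60/20/20 train/validation/test split."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    n_runs: int = 3
    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def sequence_fingerprints(X: np.ndarray) -> set[str]:
    """Content hashes of each sequence; used for no-leakage assertions."""
    return {hashlib.sha1(np.ascontiguousarray(X[i], dtype=np.float64).tobytes()).hexdigest()
            for i in range(len(X))}


def train_network(
    params: dict[str, np.ndarray],
    spec: NetSpec,
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
    demo_train: np.ndarray | None = None,
    demo_val: np.ndarray | None = None,
    trainable_blocks: tuple[str, ...] = ("lstm", "fc"),
    max_epochs: int | None = None,
    patience: int | None = None,
    init_output_bias: bool = True,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Train in place-free fashion; returns (best parameters, history).

    Early stopping restores the parameters of the epoch with the lowest
    validation loss.  ``trainable_blocks`` limits Adam updates to the named
    blocks (``lstm`` = recurrent, ``fc`` = fully connected heads); frozen
    blocks are returned bit-identical.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("empty train or validation split")
    params = {k: v.copy() for k, v in params.items()}
    prefixes = ["lstm_" if b == "lstm" else b for b in trainable_blocks]
    trainable = [k for k in params if any(k.startswith(p) for p in prefixes)]
    if init_output_bias and "fc2.b" in trainable:
        params["fc2.b"] = y_train.mean(axis=0).astype(params["fc2.b"].dtype)

    opt = nn.Adam(lr=config.learning_rate)
    max_epochs = config.max_epochs if max_epochs is None else max_epochs
    patience = config.patience if patience is None else patience
    n = len(X_train)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = -1
    wait = 0
    hist = []
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            db = demo_train[idx] if demo_train is not None else None
            masks = nn.make_dropout_masks(spec, len(idx), rng)
            pred, cache = nn.forward(params, spec, xb, db, dropout_masks=masks,
                                     return_cache=True)
            loss, dY = nn.mse_loss(pred, yb)
            grads = nn.backward(params, spec, cache, dY)
            opt.step(params, grads, trainable)
            epoch_loss += loss * len(idx)
        val_pred = nn.forward(params, spec, X_val, demo_val)
        val_loss, _ = nn.mse_loss(val_pred, y_val)
        hist.append({"epoch": epoch, "train_loss": epoch_loss / n, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    history = pd.DataFrame(hist)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_loss"] = best_val
    return best_params, history


def _provenance_to_json(prov: dict) -> dict:
    """JSON-safe provenance: stats objects and fingerprint sets round-trip."""
    out = {}
    for k, v in prov.items():
        if isinstance(v, StandardizationStats):
            out[k] = {"__stats__": {"mean": v.mean.to_dict(),
                                    "sd": v.sd.to_dict(), "scope": v.scope}}
        elif isinstance(v, tuple) and all(isinstance(a, np.ndarray) for a in v):
            out[k] = {"__arrays__": [np.asarray(a).tolist() for a in v]}
        elif isinstance(v, (set, frozenset)):
            out[k] = {"__set__": sorted(v)}
        else:
            out[k] = v
    return out


def _provenance_from_json(prov: dict) -> dict:
    out = {}
    for k, v in prov.items():
        if isinstance(v, dict) and "__stats__" in v:
            s = v["__stats__"]
            out[k] = StandardizationStats(mean=pd.Series(s["mean"]),
                                          sd=pd.Series(s["sd"]),
                                          scope=s.get("scope", ""))
        elif isinstance(v, dict) and "__arrays__" in v:
            out[k] = tuple(np.asarray(a) for a in v["__arrays__"])
        elif isinstance(v, dict) and "__set__" in v:
            out[k] = set(v["__set__"])
        else:
            out[k] = v
    return out


class SequenceBPModel:
    """Bi-LSTM regression of beatwise (SBP, DBP) from feature sequences.

    Parameters
    ----------
    X, y : training sequences (n, L, F) and labels (n, 2) as (SBP, DBP), in
        standardized feature units and mmHg respectively.
    X_val, y_val : validation split for early stopping (disjoint from X).
    demographics, demographics_val : optional (n, 5) demographic inputs
        (gender, age, height, weight, BMI), pre-scaled by the caller.
    spec : architecture; defaults to the 10 x 7 / hidden-128 network.
    """

    def __init__(self, X, y, X_val, y_val, demographics=None,
                 demographics_val=None, spec: NetSpec | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.X_val = np.asarray(X_val, dtype=float)
        self.y_val = np.asarray(y_val, dtype=float)
        self.demographics = None if demographics is None else np.asarray(demographics, float)
        self.demographics_val = (None if demographics_val is None
                                 else np.asarray(demographics_val, float))
        if spec is None:
            spec = NetSpec(seq_len=self.X.shape[1], n_features=self.X.shape[2],
                           use_demographics=self.demographics is not None)
        self.spec = spec

    @classmethod
    def from_arrays(cls, X, y, val_frac: float = 0.25, seed: int = 0, **kw):
        """Split off a validation fraction internally and build the model."""
        rng = np.random.default_rng(seed)
        n = len(X)
        order = rng.permutation(n)
        n_val = max(int(round(val_frac * n)), 1)
        va, tr = order[:n_val], order[n_val:]
        demo = kw.pop("demographics", None)
        return cls(X[tr], y[tr], X[va], y[va],
                   demographics=None if demo is None else demo[tr],
                   demographics_val=None if demo is None else demo[va], **kw)

    def fit(self, config: TrainConfig | None = None,
            trainable_blocks: tuple[str, ...] = ("lstm", "fc"),
            initial_params: dict | None = None,
            max_epochs: int | None = None, patience: int | None = None,
            ) -> "SequenceBPResults":
        """Train ``config.n_runs`` networks from distinct derived seeds and
        return the results object (predictions average over runs)."""
        config = config or TrainConfig()
        dtype = np.dtype(config.dtype)
        runs, histories = [], []
        ss = np.random.SeedSequence(config.seed)
        for child in ss.spawn(config.n_runs):
            run_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(run_seed)
            if initial_params is not None:
                params0 = {k: v.astype(dtype) for k, v in initial_params.items()}
            else:
                params0 = nn.init_params(self.spec, rng, dtype=dtype)
            params, hist = train_network(
                params0, self.spec, self.X, self.y, self.X_val, self.y_val,
                config, rng, demo_train=self.demographics,
                demo_val=self.demographics_val,
                trainable_blocks=trainable_blocks,
                max_epochs=max_epochs, patience=patience,
                init_output_bias=initial_params is None)
            runs.append(params)
            histories.append(hist)
        return SequenceBPResults(self.spec, runs, histories, config)


@dataclass
class SequenceBPResults:
    """Fitted networks plus training diagnostics.

    ``runs`` holds one parameter store per training run; predictions are the
    across-run average, as in the three-run averaging protocol.
    """

    spec: NetSpec
    runs: list[dict]
    histories: list[pd.DataFrame]
    config: TrainConfig
    provenance: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def predict(self, X: np.ndarray, demographics: np.ndarray | None = None,
                batch_size: int = 512) -> np.ndarray:
        """Across-run average prediction, shape (n, 2) = (SBP, DBP) mmHg."""
        X = np.asarray(X, dtype=float)
        out = np.zeros((len(X), self.spec.out_units))
        for params in self.runs:
            for s in range(0, len(X), batch_size):
                sl = slice(s, s + batch_size)
                d = demographics[sl] if demographics is not None else None
                out[sl] += nn.forward(params, self.spec, X[sl], d)
        return out / self.n_runs

    def evaluate(self, X, y, demographics=None) -> EvalReport:
        est = self.predict(X, demographics)
        y = np.asarray(y, dtype=float)
        return EvalReport.from_predictions(est[:, 0], y[:, 0], est[:, 1], y[:, 1])

    def summary(self) -> str:
        lines = [
            "Bi-LSTM blood-pressure regression results",
            "=" * 45,
            f"architecture     : {self.spec.seq_len} x {self.spec.n_features} "
            f"-> BiLSTM({self.spec.lstm_hidden}) -> flatten({self.spec.flattened_width})"
            f" -> FC({self.spec.fc1_units}) -> 2",
            f"demographic input: {self.spec.use_demographics}",
            f"runs averaged    : {self.n_runs}",
        ]
        for i, h in enumerate(self.histories):
            lines.append(
                f"run {i}: {len(h)} epochs, best epoch {h.attrs.get('best_epoch')}, "
                f"best val MSE {h.attrs.get('best_val_loss'):.3f} mmHg^2")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> Path:
        """Checkpoint: JSON spec/config + one .npz parameter file per run."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"spec": asdict(self.spec), "config": asdict(self.config),
                "n_runs": self.n_runs,
                "provenance": _provenance_to_json(self.provenance)}
        (out / "spec.json").write_text(json.dumps(meta, indent=1, default=str))
        for i, params in enumerate(self.runs):
            np.savez(out / f"run{i}.npz", **params)
            self.histories[i].to_csv(out / f"history{i}.csv", index=False)
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "SequenceBPResults":
        d = Path(in_dir)
        meta = json.loads((d / "spec.json").read_text())
        spec = NetSpec(**meta["spec"])
        config = TrainConfig(**meta["config"])
        runs, hists = [], []
        for i in range(meta["n_runs"]):
            with np.load(d / f"run{i}.npz") as z:
                runs.append({k: z[k] for k in z.files})
            hists.append(pd.read_csv(d / f"history{i}.csv"))
        return cls(spec, runs, hists, config,
                   provenance=_provenance_from_json(meta.get("provenance", {})))

    def copy(self) -> "SequenceBPResults":
        return SequenceBPResults(
            self.spec, [ {k: v.copy() for k, v in r.items()} for r in self.runs],
            [h.copy() for h in self.histories], copy.deepcopy(self.config),
            copy.deepcopy(self.provenance))
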