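# bpbeat

Beat-to-beat cuffless blood-pressure estimation from three noninvasive
channels: the electrocardiogram (ECG), the ballistocardiogram (BCG, the
body's recoil to cardiac ejection, measurable from a chair or bed sensor)
and the finger photoplethysmogram (PPG). The package is aimed at
physiological-signal researchers who want a complete, reproducible pipeline:
a physics-driven simulator of synchronized recordings with ground-truth
fiducials, detectors for the per-cycle characteristic points, a
sequence-regression network with person-specific and generalizable training
protocols, classical pulse-transit-time baselines, and grading against the
BHS and AAMI device standards.

## The model

Arterial stiffening with pressure makes the pulse wave travel faster. With
the Moens–Korteweg relation and an exponential pressure law for the elastic
modulus,

    PWV = sqrt(E h / (ρ d)),   E = E₀ e^(γP),   PTT = L / PWV,

the pulse transit time PTT (ECG R-peak → peak of the first PPG derivative)
falls as blood pressure P rises. Seven features are measured per cardiac
cycle — four intervals (RRI, PTT, RJI = R→BCG J-peak, IPI = BCG I-notch →
dPPG peak) and three amplitudes (ECG R, BCG J, dPPG) — z-scored, and grouped
into sequences of L = 10 consecutive cycles. A bidirectional LSTM (128
hidden units per direction; per-timestep width 256; flattened width 2560)
followed by a 64-unit ReLU layer and a 2-unit linear head regresses beatwise
(SBP, DBP) under the MSE loss (Adam, 1e-3, batch 64, early stopping with
patience 10, three averaged runs).

Training protocols:

* **personal** — 60/20/20 split within one subject-visit;
* **LOSO** — leave-one-subject-out with demographic inputs (gender, age,
  height, weight, BMI);
* **tuned LOSO** — the LOSO model with its recurrent block frozen and only
  the fully connected head retrained on 20% of the held-out subject's data;
* **multi-day** — train on one visit, test on the other, both directions.

Baselines: the Chen, Poon and Ding calibration models and multiple linear
regression on the beat features (with/without BCG, optionally lagged over
the previous 10 cycles).

## Worked example

```python
import numpy as np
from bpbeat import simulate as sim, protocols as pt
from bpbeat.model import NetSpec, TrainConfig

records = sim.generate_cohort(6, 6, sim.CohortConfig(duration_s=240.0), seed=7)
dataset = pt.build_dataset(records, source="truth")
day1 = [sd for sd in dataset if sd.visit == 1]

config = TrainConfig(n_runs=1, max_epochs=20, patience=5, seed=3)
spec = NetSpec(seq_len=10, n_features=7, lstm_hidden=24, use_demographics=True)

loso = pt.run_loso(day1, "S01", config, spec=spec)
subject = next(sd for sd in day1 if sd.subject_id == "S01")
tuned = pt.fine_tune(loso, subject, config=config)
print(tuned.summary())
```

```
[tuned_loso]
Evaluation over n=30 estimates
SBP: MAE 1.95  RMSE 2.34  CC 0.81  R2 0.45  ME -0.32  STD 2.36 mmHg
     Bland-Altman [-4.94, 4.30]  BHS A (97/100/100%)  AAMI pass
DBP: MAE 1.90  RMSE 2.37  CC 0.77  R2 0.13  ME -0.53  STD 2.35 mmHg
     Bland-Altman [-5.12, 4.07]  BHS A (97/100/100%)  AAMI pass
```

The MAE rows report the mean absolute error of the beatwise SBP/DBP
estimates on the subject's held-out test portion; Bland–Altman gives the
95% limits of agreement of the errors; BHS is the cumulative-error grade
(A requires ≥60/85/95% of errors within 5/10/15 mmHg) and AAMI passes when
|mean error| ≤ 5 and error SD ≤ 8 mmHg. On the same subject and split the
untuned LOSO model evaluates at 10.48 mmHg SBP MAE and a fully personal
model at 1.45 mmHg — fine-tuning only the head recovers near-personal
accuracy from the general model.

A command-line interface mirrors the pipeline
(`bpbeat simulate | preprocess | features | train | predict | baselines |
evaluate | sweep`); run `bpbeat --help`.

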