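# Methods

## Forward physics of the simulator

Each synthetic subject carries vascular constants (blood density ρ =
1060 kg/m³, wall thickness h = 0.45 mm, vessel radius d = 4 mm, heart-to-
finger path L = 0.0047·height) and a vessel coefficient γ (≈ 0.016 /mmHg,
subject-to-subject SD 0.002). The elastic modulus stiffens exponentially
with pressure, E = E₀·e^(γP), giving a pulse wave velocity
PWV = √(E h / (ρ d)) and a transit time PTT = L/PWV. Rather than drawing E₀
directly, subjects are constructed from a target baseline PTT (N(225, 15) ms
at the subject's baseline systolic pressure) and E₀ is solved from the law;
this keeps every fiducial inside the downstream detection windows. The local
sensitivity is dPTT/dP = −(γ/2)·PTT ≈ −1.8 ms/mmHg, so ordinary BP
excursions of ±10 mmHg move the transit time by ±18 ms — resolvable at the
1 kHz sampling rate and large against the 3 ms beat-to-beat timing jitter
injected on the dPPG fiducial (2 ms on the J-peak, 1.5 ms on the I-notch
spacing). The jitter matters twice: it makes single-beat PTT a noisy BP
proxy (so longer feature sequences genuinely help), and it breaks the exact
linear dependence IPI = PTT − RJI + const that perfectly rigid fiducial
spacing would impose on the regression designs.

Beatwise blood pressure is a baseline plus a bounded AR(1) walk (step SD
0.8 mmHg, persistence 0.98, clipped at ±15) plus slow vasomotor (4 mmHg at
0.03 Hz) and respiratory (1.5 mmHg at 0.25 Hz) sinusoids; pulse pressure
tracks the walk weakly so DBP is correlated with but not parallel to SBP.
Demographics (8:10 male:female ratio, ages 20–60, heights and BMI from
adult ranges) shift the baselines through a small linear rule, putting the
pooled cohort means near 111/68 mmHg — the regime the pipeline is designed
for — and making the demographic inputs of the general model informative.

Waveform morphology is not the target of the emulation, only event timing
and amplitudes: the ECG is a Gaussian PQRST complex with the R-peak at the
beat time; the BCG is a Gaussian-windowed sinusoid whose principal trough
and peak realize the I-notch and J-peak (symmetric about their midpoint, so
zero-phase filtering does not displace the extrema); the PPG is a smooth
error-function upstroke whose steepest-slope instant realizes the dPPG peak,
riding on a positive DC level so raw peak/valley intensity ratios are
well defined. Noise defaults: white noise per channel (3–6% of the pulse
amplitudes), 0.3 Hz baseline wander, 50 Hz power-line hum, and a 5% per-beat
pulse-dropout rate that suppresses a BCG or PPG pulse outright; truth events
are recorded before noise and dropped pulses get NaN truth. What the
simulator does not emulate: sensor transfer functions, motion artifacts with
structure, arrhythmias, pathology, or real BCG/PPG morphology — so passing
tests demonstrate the pipeline's correctness and the protocols' relative
behavior, not clinical accuracy on real recordings.

Inter-day drift for revisiting subjects combines an additive baseline-BP
shift (SD 5 mmHg), a multiplicative amplitude rescale (log-SD 0.10) and a
PTT calibration offset (SD 10 ms, implemented by re-solving E₀ for a shifted
baseline PTT). This reproduces the mechanism by which one-day person-specific
models lose accuracy across days while a general model with a retrained head
does not.

## Detection

Channels are band-passed with second-order zero-phase Butterworth filters
(ECG 0.5–35 Hz, BCG 4–15 Hz, PPG 0.5–8 Hz); the forward–backward pass is
chosen because the features are inter-event intervals and phase distortion
would bias them. R-peaks come from the Pan–Tompkins stages (5–15 Hz
band-pass, five-point derivative, squaring, 150 ms integration, adaptive
dual thresholds with search-back, 200 ms refractory) refined to the local
ECG maximum within ±75 ms. The J-peak is the highest sample in the half-open
window (R+110, R+250] ms that is also a local maximum, ties to the earliest
sample; the I-notch is the nearest local minimum within 100 ms before J; the
dPPG peak is the maximum of the central-difference derivative in (R+100,
R+600] ms. The dPPG window and the I-notch rule are package choices — the
field names these points but not their detectors. A plausibility filter
replaces interactive false-positive editing: RRI outside [300, 2000] ms, PTT
outside [100, 600] ms, or an amplitude more than 5× above or below its
31-beat rolling median invalidates the event (the low side catches
dropout-suppressed pulses); an exclusion-list file allows explicit manual
removals. The filter only ever invalidates.

On noiseless records every detector matches ground truth within ±5 ms, but
not bit-exactly: filtering and sample-grid quantization shift extrema by up
to one sample, which is why the feature-oracle tests assert exact equality
for the interval arithmetic (truth events vs brute-force recomputation) and
one-sample agreement for detected events.

## Features, sequences, standardization

Rows start at the second beat (RRI needs a predecessor); a row is valid only
if both R-peaks and its I/J/dPPG events are valid and all intervals are
positive. Sequences are stride-1 sliding windows of L = 10 consecutive valid
rows that do not straddle gaps > 3 s; the label is the reference SBP/DBP at
or immediately after the window's final R-peak (beatwise references are
aligned to R times, so this is the final beat's reference). Standardization
is per-feature z-scoring fitted strictly on the training portion — per
recording for personal models, pooled over training subjects for LOSO — and
the fitted statistics travel with the trained model. Coverage at length L is
the fraction of beats terminating a valid window; with independent per-beat
validity q it behaves like q^L, which is why the default 5% dropout yields
roughly 95% coverage at L = 1 and 60% at L = 10.

## Network and training

The regressor is implemented directly in NumPy: two LSTM passes (hidden 128,
tanh cell, gate order i/f/g/o, forget-gate bias 1), per-timestep
concatenation (width 256), flattening (2560), optional concatenation of five
demographic inputs (gender 0/1, others z-scored over training subjects), a
64-unit ReLU layer and a 2-unit linear head. Gradients are exact
backpropagation through time, checked against finite differences to 1e-4
relative in the test suite. Dropout (10%) is variational: one input mask and
one recurrent-state mask per direction, fixed across timesteps within a
batch. Training uses Adam (1e-3), batch 64, MSE summed equally over SBP and
DBP, up to 100 epochs with early-stopping patience 10 and best-validation
restoration; the output bias is initialized at the training-label mean so
the head does not spend epochs climbing to ~110 mmHg. Parameters are float32
(Adam moments in float64); runs are reproducible given a seed on a fixed
BLAS configuration. The parameter store is a flat dict partitioned by key
prefix into the recurrent block and the fully connected block; fine-tuning
freezes the former bit-exactly by restricting the optimizer's key set.

Fine-tuning hyperparameters (no published recipe): same optimizer and
learning rate, at most 50 epochs, patience 10, with 25% of the tuning subset
held out for early stopping; the tuning subset is drawn from the subject's
non-test portion so it is disjoint from evaluation data. LOSO validation is
a per-subject stratified 20% of the pooled training subjects. The three-run
average uses distinct derived seeds per run. SBP > DBP is not enforced on
the output — the regression is unconstrained.

## Benchmarks and problem sizes

The protocol benchmark simulates 8 subjects × 2 visits of 4-minute records
and trains reduced networks (hidden 24, one run, ≤25 epochs) so that the
ablation (3 subjects × 3 seeds × 2 feature sets), the personal/LOSO/tuned
comparison (3 seeds), the multi-day comparison (8 subjects × 2 seeds,
pooled over both directions) and a sequence-length sweep all complete in a
few minutes on one core; these sizes are statements about the benchmark, and
the orderings they test are scale-free. The learnability benchmark uses the
full 128-hidden architecture on 2000 sequences carrying a noiseless affine
BP–feature relation, which a correct trainer drives below 3 mmHg test MAE.
Protocol benchmarks read features from simulator ground-truth events (the
detectors are validated separately); the CLI pipeline uses the detected
path end to end.

## Baselines

Calibration uses an initial window of valid beats: constants are window
means and γ comes from regressing ln PTT on reference SBP (the exponential
wall law gives ln PTT = const − γP/2, so γ = −2·slope); on simulated data
this recovers the generating γ within 10%. The Chen model is implemented in
its canonical linearized form SBP = SBP₀ − 2/(γ·PTT₀)·(PTT − PTT₀). The
pulse intensity ratio is the per-beat max/min of a positive-baseline PPG
within each R–R interval; beats with non-positive minima or missing pulses
are invalid — a zero-mean band-passed trace cannot carry a meaningful
intensity ratio, which is why the simulator gives the PPG a DC level and the
pipeline computes PIR on the raw channel. MLR variants are ordinary least
squares fitted separately per target, with an explicit rank check that names
collinear columns.

## Evaluation conventions

Sample standard deviations use the n−1 denominator everywhere (error STD,
AAMI, Bland–Altman). BHS thresholds are inclusive (≥ at 60/85/95, 50/75/90,
40/65/85 for grades A/B/C); AAMI passes at |ME| ≤ 5 and STD ≤ 8 mmHg with
the 85-subject population requirement reported as a separate flag.
Hypertension classes are left-closed bins (SBP <120 / [120,130) / [130,140)
/ ≥140; DBP <80 / [80,90) / ≥90 — no prehypertension band for DBP), and the
total accuracy is beat-weighted with per-class accuracies also reported.
Paired protocol comparisons use the two-sided Wilcoxon signed-rank test over
per-subject MAEs by default, with a paired t-test selectable. Bland–Altman
and scatter plots are optional artifacts; all assertions are numeric.

## Known limitations

The simulator's PTT–BP coupling is exact by construction (plus jitter), so
absolute errors here are far smaller than on real recordings and only
relative comparisons between protocols are meaningful. Demographic effects
on BP are linear and modest; real covariate structure is richer. The
multi-day drift model is stationary within a visit. Determinism across
machines holds for fixed BLAS threading; across different BLAS builds,
floating-point sums may differ in the last bits.
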