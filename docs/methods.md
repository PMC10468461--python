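# Methods

This note documents the models, parameters, and design choices behind
`ecgsynth`: a desk-scale factory for privacy-preserving synthetic 12-lead
electrocardiogram (ECG) datasets. The factory has five stages — cohort
simulation (or ingestion), quality filtering, preprocessing, per-lead
generation-model training, and technical validation — each usable on its own
through the library API or the `ecgsynth` CLI.

## The structured ECG simulator

Hospital ECG archives cannot be redistributed, so every stage here is
developed and tested against a controllable simulator rather than clinical
recordings. Each simulated beat is a sum of five Gaussian wavelets (P, Q, R,
S, T), placed on an RR-interval sequence drawn from the configured
heart-rate distribution. The frontal-plane components form a 2-D dipole:
leads I and II are projections of that dipole (lead II at 60°), and the
remaining limb leads are *derived*, not synthesized:

    III = II − I,  aVR = −(I + II)/2,  aVL = I − II/2,  aVF = II − I/2.

These Einthoven/Goldberger identities therefore hold to machine precision on
noiseless output, which gives the combination search and the generator an
exact ground truth. Precordial leads V1–V6 use a fixed per-component weight
progression (net-negative QRS anteriorly, net-positive laterally); they share
the same component time courses, so every lead is a linear combination of at
most five basis signals — a deliberately low-rank world in which linear
derivability is the norm, as it is (approximately) in real ECGs.

Default wavelet geometry: R amplitude 1000 µV on lead II at a 60° axis;
P at `pr_interval` before the R center (σ = 25 ms, 150 µV, fixed 60°
orientation); Q/S flank the R wavelet at ∓40 ms; the T center sits at
`qt_interval` − 120 ms after R with σ = 50 ms. Additive white Gaussian noise
(default SD 8 µV) is applied per lead *after* the limb-lead algebra.

The six diagnosis presets encode textbook class definitions at the signal
level, not any hospital's empirical distribution:

| preset | class-defining parameters |
|---|---|
| normal sinus rhythm | 75 ± 5 bpm, RR CV 0.02, PR 160 ms, QT 400 ms, axis 60° |
| sinus bradycardia | heart rate 45 ± 5 bpm |
| left axis deviation | frontal axis −45° |
| atrial fibrillation | i.i.d. uniform RR with CV 0.2, P amplitude 0, 95 bpm |
| first-degree AV block | PR 280 ms (cohort jitter floored at 210 ms) |
| prolonged QT | QT 520 ms (floored at 490 ms under jitter) |

`simulate_cohort` jitters heart rate (preset SD), PR (±8 ms), QT (±12 ms)
and axis (±8°) per subject from one seeded generator, so cohorts are
reproducible bit-for-bit. Records carry the simulator's wavelet bookkeeping
(R times, P/QRS onsets) in a non-serialized `annotations` field as test
ground truth.

**What the simulator does not emulate:** realistic QRS micro-morphology,
respiration and baseline wander, electrode artifacts beyond white noise,
age/sex effects, or inter-lead noise correlation. Passing tests on simulator
data therefore demonstrate that the pipeline's *mechanics* are correct
(filtering, algebra, training, evaluation protocol), not that generated
morphology is clinically valid.

## Quality filtering

Three screens, mirroring how a hospital archive is distilled before
modelling: (1) exclusion of records whose machine statements match a
low-quality / arm-lead-reversal vocabulary (case-insensitive substring;
`(s)` in a pattern becomes an optional-s wildcard so "Artifact in lead(s)"
matches "Artifact in leads V1, V2"); (2) exclusion of records with an
all-zero lead (electrode not attached; tolerance 0 by default) or fewer
frames than expected (default 5000 = 10 s × 500 Hz); (3) first-visit
deduplication per subject, ties on identical timestamps broken by smallest
record id. Deduplication runs *after* the other screens by default, so a
subject whose first visit was defective still contributes their earliest
clean record; `dedup_first=True` gives the stricter order in which such a
subject is dropped entirely. Every input record receives a machine-readable
decision, so input count = survivors + excluded always holds.

## Preprocessing

Band-pass 0.05–150 Hz (order-4 Butterworth, one second-order-section
cascade) applied forward and backward. Zero-phase filtering squares the
magnitude response and introduces no group delay, preserving ST-segment
morphology; reflect padding of one filter length controls edge transients at
the very low 0.05 Hz corner. The 0.05 Hz corner has a multi-second impulse
response — tests measuring steady-state gain use long signals and central
windows for exactly this reason.

Min–max normalization maps each of the 12 leads independently onto [0, 1].
The per-lead (min, max) pairs are returned as a separate object, serialized
only on explicit request, and never embedded in synthetic output: without
them the µV scale of the source signal cannot be recovered, which is the
privacy mechanism of the whole factory. A `per_record` option normalizes
with one global (min, max) instead; per-lead is the default because it
matches the per-signal privacy argument.

## Lead-combination search

For each target lead, all C(11,3) = 165 triples of the other leads are
scored by one pooled ordinary-least-squares fit with intercept (all frames
of all records stacked); the score is the residual RMSE and the minimum
wins. Scores within 1e-9 of the minimum are treated as exact ties and broken
by enumeration order (canonical-index lexicographic): without this, O(1e-14)
floating-point noise would arbitrarily reorder the many exactly-derivable
limb-lead triples.

A scale subtlety: per-record min–max normalization rescales each record by
its own affine constants, so a *pooled* linear model across normalized
records is no longer exactly linear even where the underlying µV-scale
identity is exact. Exactness oracles (residual < 1e-6 for Einthoven-derivable
targets) therefore run on noiseless µV-scale cohorts; the pipeline still
searches on normalized records, i.e. on the same scale the generation models
consume, where the small pooled-affine mismatch affects all candidates alike.
A published reference table of per-target triples (`reference_table()`) is
shipped for runs without search data.

## The generation model

One model per target lead maps its three input leads (frames × 3, normalized
scale) to the target (frames × 1). Architecture:

* temporal branch — four stacked bidirectional LSTM layers, per-direction
  hidden widths 256/128/64/32 (concatenated bidirectional outputs are twice
  as wide; "width" is read as per-direction, the conventional reading);
* spatial branch — four 1-D convolutions with channels 256/128/64/32,
  kernel 7, stride 1, length-preserving same-padding, ReLU after each
  (length preservation is required for per-frame fusion);
* fusion — per-frame concatenation of the two branch outputs
  (64 + 32 = 96 features), two further bidirectional LSTM layers
  (default widths 32/32), then one per-frame fully connected layer.

Training minimizes MSE (RMSE being the fidelity metric of record; MAE is
available) with Adam at learning rate 1e-4, the forget-gate bias initialized
to 1, and the output bias initialized to 0.5 so an untrained model starts at
the center of the [0, 1] target range rather than being clipped to a
degenerate constant. Epochs and batch size are configuration (defaults 50
and 16) with optional early stopping on a validation split (default fraction
0.2, patience 5). All parameters live in NumPy arrays; initialization and
batch order flow from a single seeded generator, so training histories and
weights are bit-reproducible for a fixed seed on a fixed platform. The
layers and manual backprop live in `ecgsynth.nn` and are verified against
finite-difference gradients in the test suite.

The sequence length is an architecture-independent parameter: full-scale
records use 5000 frames (10 s × 500 Hz); development and validation runs in
this repository use 500-frame records (4 s × 125 Hz) and, where throughput
matters more than capacity, reduced widths (16/16 LSTM, 16/16 CNN, fusion
16, learning rate 1e-3, 6 epochs). Every architecture override is recorded
in the trained model's provenance.

At assembly time the 12 models are applied to each *source* record's real
leads only — generated leads are never fed back as inputs — and outputs are
clipped to [0, 1]. Synthetic records keep the source's diagnosis label and a
provenance pointer (source record id, model input sets) but carry no subject
identity, no acquisition time, and no normalization parameters.

## Validation protocol

Fidelity: per-lead RMSE and cosine similarity between each synthetic record
and its source, aggregated into a lead × diagnosis grid with record-count
weighted means, SDs, and lead-group summaries (standard I–III, extremity
aVR/aVL/aVF, precordial V1–V6). RMSE is reported on the normalized scale
and additionally in µV when the private normalization parameters are
supplied to the report.

Utility: a 1-D CNN binary abnormality classifier (six convolution layers,
kernel 7, max-pool 2 after each, then dense 64 → 1; input frames × 12;
Adam, learning rate 1e-3) is trained once on real and once on synthetic
records. "Fivefold cross-validation combined with a 6:2:2 split" is realized
as five seeded stratified shuffle-splits at 6:2:2 — five folds of a strict
partition cannot simultaneously give 20 % test sets, so the repeated-split
reading honors both stated facts. Per-metric fold vectors (accuracy,
precision, recall, F1; AUC is also computed) are compared with Student's
equal-variance two-sample t-test at α = 0.01 (Welch available by flag);
both-zero-variance cases are flagged and assigned p = 1 when the means agree.
No multiple-testing correction is applied across metrics, and the report
says so. The cross-domain block retrains one classifier on synthetic records
derived from 80 % of the real sources and evaluates it on the held-out 20 %
of real records; a provenance-based guard raises if any test record's
subject (or generation source) appeared in training.

## Numerical and scale choices

* Validation-scale runs use 6 × 50 records of 500 frames (125 Hz × 4 s):
  large enough that bradycardia vs normal is learnable with clear margins
  (3–4 vs 5–6 beats per window) and that fold metrics are stable, small
  enough for interactive iteration.
* The NN core trains in float32; gradient checks run in float64.
* `sosfiltfilt` padlen = 3 × (2 × order + 1) samples of reflect padding.
* Constant leads are rejected before normalization (degenerate-signal
  error) rather than silently producing NaNs.
* Pipeline stage outputs are cached under the work directory keyed by a
  hash of the stage-relevant configuration; re-running with an unchanged
  config loads intermediates instead of recomputing.

## Known limitations

* Simulator realism is deliberately limited (see above); absolute fidelity
  numbers on simulator data do not transfer to hospital data.
* The low-rank lead structure of the simulator makes the 3-lead→1-lead task
  easier than on real ECGs, where derivability across lead systems is only
  approximate; capability tests (overfitting, linear-identity recovery)
  remain informative, absolute RMSE levels do not.
* Training the full 256/128/64/32 architecture on 22,000 × 5000-frame
  records is outside the intended desk scale of this implementation.
* The XML dialect is this package's own; it does not parse vendor ECG XML.
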