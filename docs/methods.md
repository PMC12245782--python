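# Methods

This note documents the modelling and numerical choices behind `ecgwolf`:
what each stage assumes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Signal model and preprocessing

The package operates on a single ECG channel in millivolts. Multi-channel
sources are reduced to one user-selected channel at read time (default
channel 0); every downstream formula is single-signal, so no fusion across
leads is attempted.

* **Normalization** is the literal min-max map to [0, 1]. An optional
  rescale to [−1, 1] is provided for users who prefer a symmetric range;
  the [0, 1] form is the package default because it is the formal
  definition the rest of the pipeline assumes. A constant signal makes the
  denominator zero and is rejected as degenerate rather than imputed.
* **Band-pass** 0.5–40 Hz, 4th-order Butterworth, applied
  forward-backward (`sosfiltfilt`) so the filter is zero-phase and beat
  morphology is not skewed. 0.5 Hz removes baseline wander; 40 Hz removes
  mains and muscle noise while keeping QRS energy. The filter realization
  is a package choice — any zero-phase realization with the same band
  would do.
* **QRS detection** is a reduced Pan–Tompkins chain: median-centering,
  differentiation, squaring, a 150 ms moving average, a fixed threshold at
  0.1 of the maximum of that envelope, and a 0.2 s refractory period. The
  derivative stage is what rejects T waves (high amplitude, low slope);
  the 0.1 threshold was set from the envelope statistics of the synthetic
  beat shapes so that wide (lower-slope) ectopic complexes are still
  caught. This detector is deliberately non-adaptive: it is meant for
  clean, filtered signals and fixture construction, not for clinical-grade
  beat detection.
* **Windowing** is 0-based and half-open. Fixed mode tiles the record
  (`floor((N − W)/S) + 1` windows); R-peak-centered mode places one window
  per detected beat. A window inherits the label of the annotation nearest
  its center among annotations inside it, ties toward the earlier one —
  the source data format does not define window labeling, so this rule is
  ours.
* **Fusion** of equal-length segments is the point-wise arithmetic mean.
  Whether "fusion" of signal pulses means averaging, concatenation, or a
  display overlay is ambiguous in this family of pipelines; the mean is
  implemented because it is the only reading that yields a well-defined
  single signal, and it is exposed as an explicit operation rather than
  buried in the pipeline.

## Features

21 features per window, in a fixed registry order:

| group | features | notes |
|---|---|---|
| energy | `Σ x[n]²` | |
| statistics | mean, variance, median, max, min, RMS | variance is the population form (divisor N) throughout |
| wavelet | energy + variance per band: d1..d4, a4 | db4, 4 levels, periodized |
| texture | contrast, energy, homogeneity, correlation | 1-D co-occurrence |

The wavelet decomposition uses periodization so that, for an orthogonal
mother wavelet and a window length divisible by 2^levels, sub-band energies
sum exactly to the signal energy (checked to 1e-8 in the tests). At 360 Hz
the d3/d4 bands (≈11–45 Hz) carry QRS energy and the a4 band (≲11 Hz)
carries P/T waves and the flutter sawtooth.

The co-occurrence matrix is normally an image-texture tool. Applied to a
1-D signal there is no canonical construction, so the package uses the
minimal faithful one: min-max quantization to 8 levels, co-occurrence of
`(q[t], q[t+lag])` at lag 1, symmetrized, normalized to probabilities. A
constant window puts all mass in one cell; its correlation is undefined
(0/0) and the row is dropped upstream with a logged count rather than
silently filled.

LDA reduction (≤ C−1 = 4 components) is implemented as the generalized
symmetric eigenproblem on between/within scatter with Tikhonov
regularization `ε = 1e-6 × trace(S_w)/d` to stay well posed on small
fixtures. It is off by default: the wrapper selector searches the raw
feature space, because applying a supervised projection before a
supervised wrapper would make the selected "features" uninterpretable and
the ordering of the two reductions is otherwise arbitrary.

Features are z-scored (mean/sd fit on the training split only) before
selection and classification: both KNN distances and gradient training are
scale-sensitive, and the registry mixes units spanning many orders of
magnitude.

## Wrapper feature selection

Binary grey-wolf optimization with the canonical continuous dynamics and a
sigmoid transfer:

* population 30, iterations 100 (defaults); initial masks have exactly
  `min(init_k, d)` bits (default 30, capped at the dimension d);
* exploration parameter `a` decays linearly 2 → 0, reaching 0 exactly on
  the last iteration;
* transfer `S(v) = 1/(1 + e^{−λ(v−0.5)})`, λ = 10. Centering at 0.5 makes
  the transfer consistent with positions initialized at the bit values
  {0, 1}; λ = 10 keeps a ≈0.7% per-bit flip probability at the leader
  position, enough residual exploration to escape ties;
* continuous positions are retained between iterations and binarized only
  for evaluation, keeping the grey-wolf dynamics well defined in the
  binary setting;
* an all-zero mask is repaired to a uniformly random subset of size
  1..init_k (size drawn uniformly), never evaluated empty;
* fitness is pure mean stratified 5-fold CV accuracy of 5-NN on the
  selected columns — no feature-count penalty. Parsimony enters only
  through leader tie-breaking: on exact fitness ties the mask with fewer
  features (then the earlier-evaluated one) leads. Fold assignment is
  fixed per run from the config seed, so fitness is a deterministic
  function of (data, mask, config) and runs are bit-reproducible;
* leaders α/β/δ are the three best-ever *distinct* masks (elitist), so the
  best-so-far convergence curve is nondecreasing by construction, and the
  evaluation budget is exactly `num_wolves × (max_iter + 1)`.

The KNN neighbour count (5) is a package choice exposed in config; the
wrapper-classifier family (KNN) and the 5-fold scheme are fixed by design.
A binary PSO with the same fitness, population, budget and transfer, and a
budget-matched random search, serve as convergence baselines.

## LSTM classifier

Single LSTM layer (50 units, last output), dropout 0.2, dense layer to 5
classes, softmax; categorical cross-entropy (the loss implied by a softmax
classification layer); Adam at learning rate 0.01 with L2 0.001 on weight
matrices (not biases), batch 100, at most 30 epochs; He-normal weights
(the initialization designed for rectifier-family networks, applied here
as configured); forget-gate bias initialized to 1 (standard practice so
early training does not forget); one validation check per epoch with early
stopping after 6 non-improving checks, restoring the best-validation
parameters; gradients clipped at global norm 1.0 as a safeguard against
the unusually high Adam learning rate — with clipping disabled the same
configuration is prone to oscillation.

Selected feature vectors enter as **length-1 sequences**. This mirrors the
construction where per-window feature vectors are handed to a sequence
input layer: the recurrence then degenerates to a single gated cell
application. A raw-window mode (`sequence_mode="raw"`) feeds the samples
themselves as a T-step scalar sequence for users who want true temporal
input. The epoch budget is 30 with early stopping, which naturally yields
shorter runs when validation loss plateaus.

The whole network is NumPy: batched forward pass, exact backpropagation
through time (verified against finite differences to ~1e-10 in
development and against a scalar-loop evaluation of the gate equations in
the tests), and a self-contained Adam. Runs are pure functions of
(data, config, seed).

## Evaluation

Multi-class sensitivity/specificity are one-vs-rest per class,
macro-averaged without weights; per-class values are always reported next
to the macros. A class with no true members is excluded from the macro
mean with a warning. AUC is the trapezoidal integral of the one-vs-rest
ROC over unique score thresholds (equal to the tie-corrected Mann–Whitney
statistic). The error histogram bins `P(true class) − 1` into 20
equal-width bins over the observed range. Paired model comparison is the
exact (binomial) McNemar test on discordant correct/incorrect pairs —
the standard test for two classifiers on one sample set; with no
discordant pairs, p = 1.

## Synthetic data: what it emulates, what it does not

Records are beat trains with log-normal RR intervals and sum-of-Gaussians
beat morphology (P, Q, R, S, T bumps), 360 Hz, Gaussian observation noise
(default sd 0.05 mV), with class signatures: AFib — RR CV 0.25, no P
waves; SVT — RR 0.35 s, CV 0.02; bradycardia — RR 1.333 s; PVC — sinus
base RR 0.80 s with wide-QRS, inverted-T ectopics at rate 0.3/beat;
flutter — RR 0.40 s with a 5 Hz, 0.2 mV sawtooth baseline (≈300/min
atrial rate under 2:1 conduction). These values are standard textbook
physiology for the five rhythms; beat times are recorded as annotations,
giving exact ground truth for detector and segmentation tests.

Dataset windows are 5 s with 2.5 s stride, chosen so that even a
bradycardia window contains ≥ 3 beats and window-level features can see
rhythm statistics, not just morphology. (The generic `segment` operation
defaults to 1 s windows; the 5 s choice is specific to the dataset
builder.) 100 segments per class (500 total, split 350/75/75) is the
desk-scale study condition exercised by the tests and the acceptance
script.

What the generator does **not** emulate: real morphological variability
between patients and electrodes, non-Gaussian noise and artifacts
(electrode motion, muscle noise), rhythm transitions within a record,
P-wave/flutter-wave detail beyond a fixed bump or sawtooth, and any
12-lead structure. Passing tests therefore demonstrate that the pipeline
is implemented correctly and can recover planted, well-separated
structure; they say nothing about clinical-grade accuracy on ambulatory
recordings. The planted feature table (one-hot class means at 6
within-class sd, standard-normal noise columns) plays the same role for
the selector in isolation.

The 70–15–15 split is at the window level, mirroring the sample-level
split of the target setting; with overlapping windows this leaks
correlated samples between splits, which is exactly why the stratified
and record-level split modes exist for users who want a stricter protocol.

## Numerical conventions and degenerate inputs

* WFDB output is format 16 at gain 200 ADC units/mV; round trips are exact
  to one ADC quantum. Labels outside the standard annotation-code table
  are stored as AUX strings so arbitrary text labels round-trip exactly.
* NaN/Inf samples, feature values, and CSV cells are rejected at
  ingestion, never imputed.
* Softmax is computed with max-shift; gate pre-activations are clipped at
  ±60 before the sigmoid (indistinguishable from the exact value in
  float64, immune to overflow warnings).
* Ties: leader selection breaks toward fewer features then earlier
  evaluation; window labeling breaks toward the earlier annotation;
  the median of an even-length window is the mean of the two middle order
  statistics.
* `repair` draws the subset size uniformly, making repaired masks
  unbiased across sizes (χ²-tested).

## Known limitations

* The QRS detector's fixed threshold is tuned to clean filtered signals;
  adaptive thresholding would be needed for noisy ambulatory data.
* Length-1 sequences make the LSTM act as a gated feed-forward layer; the
  temporal machinery only engages in raw-window mode.
* The co-occurrence features discard sign and scale information by
  design (quantization after min-max), so they carry texture, not
  amplitude.
* Training is CPU-only NumPy; it is sized for hundreds-to-thousands of
  windows, not for large-scale training.
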