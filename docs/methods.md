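# Methods

`emophys` implements a multimodal emotion-recognition pipeline that maps
14-channel EEG (128 Hz) and 2-channel ECG (256 Hz) recordings, each rated
1–5 on the Valence/Arousal/Dominance (VAD) scales, to a 3-class label per
dimension. This note documents the models, the numerical choices, and what
the synthetic benchmark does and does not demonstrate.

## Preprocessing

Each recording passes through:

1. **Mains notch** — an IIR notch at 50 Hz with quality factor Q = 30
   (≈1.7 Hz wide). Q is a conventional narrow-notch choice; only the
   centre frequency is fixed by the data's mains environment.
2. **Bandpass** — a 4th-order Butterworth bandpass, 0.5–45 Hz, the
   maximally flat design with |H(Ω)|² = 1/(1 + (Ω/Ω_c)^(2N)). Both filters
   are applied forward–backward (`filtfilt`), i.e. zero phase: waveform
   morphology (and hence R-peak timing) is preserved and the effective
   magnitude response is the square of the single-pass response. The
   half-power (−3 dB) points of the single-pass design sit exactly at the
   cutoffs, which the tests verify against the closed-form magnitude.
   The same band is used for EEG and ECG; the QRS complex has most of its
   energy below 40 Hz, and the R-peak detector refilters internally anyway.
3. **ICA artifact rejection (EEG only)** — FastICA with as many components
   as channels, deterministic under a seed. A component is removed when its
   excess kurtosis exceeds 5.0 (spiky electrode/EMG artifacts) or when more
   than 60 % of its power lies below 3 Hz (ocular/drift components). These
   two criteria are the package's own rejection rule; they capture the
   blink-like and drift artifacts the generator produces while leaving
   band-limited oscillatory activity intact (cleaning an already-clean
   signal changes per-channel RMS by well under 10 %). ECG is not passed
   through ICA: with two near-collinear chest leads there is no artifact
   subspace to separate.
4. **Windowing** — non-overlapping 30 s slices: 3 840 samples per EEG
   window, 7 680 per ECG window. The trailing partial window is dropped;
   every window inherits its trial's VAD scores. Windows are the samples
   the classifier sees.

## EEG features (per channel, per window)

* **Time domain** (7): max, min, mean, variance, peak-to-peak, kurtosis,
  skewness. Kurtosis is *excess* kurtosis (normal → 0); both third and
  fourth moments use the biased (population) normalisation.
* **Band power** (5): Welch PSD (4 s Hann windows, 50 % overlap) integrated
  by the trapezoid rule over Delta 0.5–4, Theta 4–8, Alpha 8–13,
  Beta 13–30, Gamma 30–45 Hz — conventional edges consistent with the
  passband. With band edges on the Welch frequency grid, band power is
  exactly additive over adjacent bands.
* **Sample entropy**: SampEn(m = 2, r = 0.2·SD), Chebyshev metric,
  self-matches excluded, −ln(A/B) over unordered template pairs. For a
  constant signal the value is 0; if no matches exist the conservative
  upper bound −ln(1/(B+1)) is returned. For 30 s windows the series is
  decimated by 4 (anti-aliased, 128 → 32 Hz) before template counting;
  this keeps the O(n²) count tractable at scale while preserving the
  irregularity ordering between signals (noise > sinusoid), which is the
  property downstream stages consume.
* **DFA**: the profile (mean-centred cumulative sum) is split into
  non-overlapping windows per scale, linearly detrended per window; the
  scaling exponent α is the least-squares slope of log F(n) against log n
  over ~12 log-spaced scales from 4 to N/4 samples. Sanity anchors:
  α ≈ 0.5 for white noise, α ≈ 1.5 for Brownian motion, both recovered
  within ±0.1 at n = 4096.

Feature names follow the stable grammar `<channel>.<family>`
(e.g. `AF3.alpha_psd`), channel-major.

## ECG features (per channel, per window)

R-peaks are detected with a Pan–Tompkins-style chain: 5–15 Hz bandpass →
derivative → squaring → 150 ms moving-window integration → peak picking at
25 % of the 98th-percentile integrated amplitude with a 200 ms refractory
period, each detection refined to the local maximum of the QRS-band signal.
The detector is deterministic. RR intervals outside a 300–2000 ms
physiological gate are dropped (logged).

From the RR series (ms):

* **Time domain**: mean RR, heart rate = 60000/meanRR, SDNN, RMSSD, NN50
  (|ΔRR| > 50 ms), pNN50.
* **Poincaré**: SD1 = √(Var(ΔRR)/2), SD2 = √(2·SDNN² − SD1²), using
  population variances so SD1² + SD2² = 2·SDNN² holds exactly (SD2² is
  clamped at 0 with a warning if numerically negative).
* **Frequency domain**: the tachogram is cubic-interpolated onto a 4 Hz
  grid, mean-removed, and a Hann periodogram is integrated over the
  Task-Force bands VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz, plus
  LF/HF. On a 30 s window the VLF band has essentially no spectral
  support; VLF is still computed (it is part of the published feature set)
  but should be treated as unreliable at this window length. HRV is
  computed per 30 s window rather than per trial so that EEG and ECG
  features share one sample grid.

## Feature fusion and selection

EEG and ECG vectors of aligned windows are concatenated EEG-first
(full set: 14×14 = 196 EEG + 2×12 = 24 ECG columns). Failed windows
(e.g. no detectable beats) contribute NaNs that are median-imputed with a
logged count. A random forest with **80 trees** ranks features by
normalized mean-impurity-decrease importance (permutation importance is
available behind a flag); `tree_count_study` reports ranking stability
(mean Spearman correlation across seed pairs) and timing for tree counts
{50, 80, 100}.

Two retention modes exist because a 9-row importance ranking and a
56 + 10 retained-feature set are both meaningful summaries of the same
selection: plain `top_k` (default k = 9) keeps the nine highest-ranked
columns; `top_families` expands the top-ranked (modality, family) pairs
across all channels, which with 4 EEG families and 5 ECG families yields
4×14 = 56 EEG plus 5×2 = 10 ECG features. The reference EEG family set is
{alpha_psd, gamma_psd, beta_psd, dfa}; the ECG set is
{mean_rr, heart_rate, vlf, sd2, sdnn}.

## Classifier

The Att-1DCNN-GRU treats the selected feature vector as a length-F,
one-channel sequence:

    Conv1D(256, k=3, ReLU) → Conv1D(256, k=3, ReLU) → MaxPool1D(2)
    → GRU(256, full sequence) → additive attention → Dense(128, ReLU)
    → Dense(3) → softmax

Attention scores each GRU timestep with e_t = vᵀ tanh(W h_t + b)
(attention dim 64), softmax-normalises them (weights are nonnegative and
sum to 1) and returns the weighted sum; if every timestep output is the
same vector the attention output is that vector. Training minimises
categorical cross-entropy −(1/m)ΣΣ y log ŷ (predictions clipped at 1e-7
before the log) with Adam (lr = 0.001, β₁ = 0.9, β₂ = 0.999), batch size
256, 50 epochs, no early stopping by default (available behind a flag);
the weights from the epoch with the lowest validation loss are retained.
Per-epoch train metrics are running minibatch averages; validation metrics
are full-set. Features are z-scored with training-split statistics. The
whole network — forward pass, full BPTT through the GRU, Adam — is
implemented explicitly in NumPy, which keeps runs bit-reproducible for a
fixed seed on a fixed BLAS configuration and makes every gradient
checkable against finite differences (the tests do this).

Pool size 2, attention dim 64 and dense width 128 are the package's
defaults where the architecture description leaves the value open. One
independent model is trained per VAD dimension; scores collapse to classes
as {1,2}→0, {3}→1, {4,5}→2. Splitting is stratified: 20 % test, then 10 %
of the remaining training rows as validation (n = 1000 → 720/80/200).

## Evaluation

Accuracy, precision, recall and F1 follow the binary-count definitions,
reduced one-vs-rest with macro averaging for the 3-class task; undefined
ratios are reported as 0 and flagged. Confusion matrices are reported as
counts and row-normalized probabilities. Accuracy equals the trace ratio
of the count matrix, and micro-averaged recall equals accuracy (tested).

## Synthetic benchmark

The generator emulates the DREAMER geometry. EEG is a sum of band-limited
Gaussian noise with per-class RMS amplitudes plus broadband noise
(SD 4 µV-equivalent), optionally contaminated by 50 Hz mains (2 µV), slow
sinusoidal drift (10 µV at 0.15 Hz) and blink-like frontal Gaussian bumps
(80 µV, 0.3 events/s, 150 ms width, frontally weighted topography). ECG is
a Gaussian-bump PQRST template (R ≈ 1 mV) at beat times whose RR intervals
carry 20 ms Gaussian jitter and sinusoidal modulation at 0.1 Hz and
0.3 Hz. Randomness flows from one seed through a substream per
subject × trial.

The **separable** preset separates classes in exactly the features the
pipeline extracts — alpha/beta/gamma balance (18/4/2 vs 10/8/4 vs 5/14/7),
mean heart rate (60/70/80 bpm) and LF/HF modulation depth — so a correct
implementation should classify held-out windows nearly perfectly, and a
broken stage (filtering, detection, feature math, selection, training)
shows up as lost accuracy. The **null** preset gives all classes one
generating distribution, so accuracy should stay in the 3-class chance
band. The study scale is 5 subjects × 12 trials × 300 s = 600 windows.

What passing does **not** show: the generator has no head-model mixing, no
1/f background, no inter-subject variability, no genuine emotion—signal
relationship; windows from one trial land in both train and test, as they
do under segment-level splitting. Results on synthetic data therefore
validate the machinery, not any claim about real emotional states, and
accuracies here are not comparable to published accuracies on real
datasets.

## Degenerate inputs and numerical conventions

Rank-deficient EEG (collinear channels) is rejected before ICA with the
offending pair named. Recordings shorter than one window yield an empty
segment list with a warning. Fewer than 3 detected beats raises
"insufficient beats"; such windows become NaN features and are imputed.
LF/HF is NaN when HF is 0. SDNN and Poincaré use population (ddof = 0)
variances. All floating point is float64.

## Known limitations

* VLF power on 30 s windows is reported but physically unreliable.
* The RF importance ranking is not bitwise invariant to column permutation
  (tree tie-breaking depends on column order); the planted-signal ranking
  is permutation-stable and tested.
* ICA rejection thresholds are tuned to the generator's artifact classes;
  real EOG/EMG may need different settings.
* A DEAP-format loader is out of scope; the DREAMER-style MAT reader and
  the delimited-text reader are the two ingestion paths.
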