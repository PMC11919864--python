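# emophys

Multimodal emotion recognition from physiological electrical signals:
a tested Python implementation of the full EEG + ECG pipeline —
preprocessing, feature extraction, random-forest feature selection, and an
attention 1D-CNN-GRU classifier — for 3-class recognition of the
Valence/Arousal/Dominance (VAD) emotion dimensions.

It is written for researchers who want an end-to-end, reproducible
reference pipeline they can run on DREAMER-style recordings (14-channel
EEG at 128 Hz, 2-channel ECG at 256 Hz, self-report scores 1–5) or on the
built-in synthetic benchmark, and inspect or replace any stage.

## What it computes

1. **Preprocessing** — 50 Hz notch, 0.5–45 Hz 4th-order Butterworth
   bandpass (|H(Ω)|² = 1/(1 + (Ω/Ω_c)^{2N})), zero-phase application, ICA
   artifact rejection for EEG, and slicing into 30 s windows (3 840 EEG /
   7 680 ECG samples).
2. **Features** — per EEG channel: 7 time-domain statistics, Welch band
   power in Delta/Theta/Alpha/Beta/Gamma, sample entropy
   SampEn(m, r) = −ln(A/B), and the DFA scaling exponent α. Per ECG
   channel: Pan–Tompkins-style R-peak detection, then the HRV panel —
   mean RR, heart rate, SDNN, RMSSD, NN50, pNN50, Poincaré SD1/SD2, and
   VLF/LF/HF power with LF/HF.
3. **Selection** — fused feature table ranked by random-forest importance
   (80 trees); keep the top-k features (default 9) or expand the
   top-ranked families to all channels (4×14 = 56 EEG + 5×2 = 10 ECG).
4. **Classification** — per VAD dimension, scores map {1,2}→0, {3}→1,
   {4,5}→2 and an Att-1DCNN-GRU
   (Conv256·k3 → Conv256·k3 → MaxPool → GRU256 → additive attention →
   Dense → softmax) is trained with Adam (lr 0.001) under categorical
   cross-entropy, batch 256, 50 epochs, on a stratified 80/20 split with
   10 % of the training rows held out for validation. The network,
   including backpropagation through the GRU and the Adam update, is
   implemented explicitly in NumPy and is bit-reproducible under a seed.
5. **Evaluation** — accuracy, one-vs-rest precision/recall/F1 with macro
   averaging, and confusion matrices (counts and probabilities).

A synthetic generator produces labeled EEG+ECG trials with controllable
per-band power, heart rate, LF/HF modulation, mains/drift/blink artifacts
and full ground truth, so the pipeline is testable without any dataset
download. See `docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
from emophys.pipeline import PipelineConfig, run_pipeline
from emophys.synth import SynthSpec
from emophys.model import ModelConfig

config = PipelineConfig(
    synth=SynthSpec.separable(n_subjects=2, n_trials=9, duration=120.0),
    model=ModelConfig(epochs=10),
    seed=1,
)
result = run_pipeline(config)
print(result.results.summary())
print(result.report)
```

prints (abridged):

```
          Att-1DCNN-GRU Results
==============================================
Dimension:        valence
N train samples:  51
N features:       9
N parameters:     641667
Conv filters:     256, 256 (kernel 3)
GRU units:        256  Attention dim: 64
Optimizer:        Adam (lr=0.001)
Epochs run:       10 (batch 256)
Final train loss: 0.1269  acc: 1.0000
Final val loss:   0.1424  acc: 1.0000
==============================================
Evaluation report (valence), n=15
  accuracy:        1.0000
  macro F1:        1.0000
  confusion (rows = true, cols = predicted):
    [5, 0, 0]
    [0, 5, 0]
    [0, 0, 5]
```

Here 18 synthetic trials of 120 s yield 72 windows of 30 s; the random
forest ranks the 220 fused features and keeps the 9 most discriminative
(gamma/beta band powers and HRV spectral features on this preset); the
classifier then separates the three planted classes perfectly on the 15
held-out windows. On the `null` preset, where all classes share one
generating distribution, accuracy stays at 3-class chance.

The same flow is available from the shell:

```bash
emophys synth --preset separable --subjects 2 --trials 9 --duration 120 --seed 1 --out data/
emophys run --seed 1 --out results/run1/
```

Stage-wise subcommands (`preprocess`, `features`, `select`, `train`,
`evaluate`) operate on intermediate files; see `emophys --help`.

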