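"""Labeled synthetic EEG+ECG generation with controllable class structure.

Every pipeline stage is testable without any download: trials mimic the
DREAMER geometry (14-channel EEG at 128 Hz, 2-channel ECG at 256 Hz, one
1-5 score per VAD dimension) and carry full ground truth (artifact-free
EEG, true beat times, true band amplitudes).

EEG is a sum of band-limited Gaussian noise components with per-class RMS
amplitudes plus broadband noise, optionally contaminated by 50 Hz mains,
slow drift and blink-like frontal bumps. ECG is a Gaussian-bump PQRST
template laid down at beat times whose RR intervals carry Gaussian jitter
and sinusoidal modulation at 0.1 Hz (LF) and 0.3 Hz (HF) with per-class
depths.

The ``separable`` preset separates the three classes in the alpha/beta/gamma
balance, mean heart rate and LF/HF modulation depth — exactly the features
the pipeline extracts; the ``null`` preset gives every class identical
generating parameters, so any classifier should sit at 3-class chance.

All randomness flows from one seed through a named substream per
subject x trial, so regenerating a single trial is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal as sps

from .io import (
    DREAMER_ECG_NAMES,
    DREAMER_EEG_NAMES,
    DreamerTrial,
    Recording,
    TrialScores,
    save_dreamer_container,
)

__all__ = ["ClassProfile", "SynthSpec", "GroundTruth", "SynthDataset",
           "generate_recording", "generate_dataset"]

_BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Frontal weighting of the blink-like artifact across the 14 electrodes.
_BLINK_TOPOGRAPHY = np.array(
    [1.0, 0.7, 0.6, 0.3, 0.1, 0.05, 0.02, 0.02, 0.05, 0.1, 0.3, 0.6, 0.7, 1.0]
)


@dataclass
class ClassProfile:
    """Generating parameters of one emotion class."""

    band_amplitudes: dict[str, float]  # RMS amplitude per EEG band (uV-like)
    heart_rate_bpm: float
    rr_jitter_ms: float = 20.0
    lf_depth: float = 0.05  # fractional RR modulation at 0.1 Hz
    hf_depth: float = 0.05  # fractional RR modulation at 0.3 Hz


def _separable_profiles() -> list[ClassProfile]:
    base = {"delta": 12.0, "theta": 8.0}
    return [
        ClassProfile({**base, "alpha": 18.0, "beta": 4.0, "gamma": 2.0},
                     heart_rate_bpm=60.0, lf_depth=0.08, hf_depth=0.02),
        ClassProfile({**base, "alpha": 10.0, "beta": 8.0, "gamma": 4.0},
                     heart_rate_bpm=70.0, lf_depth=0.05, hf_depth=0.05),
        ClassProfile({**base, "alpha": 5.0, "beta": 14.0, "gamma": 7.0},
                     heart_rate_bpm=80.0, lf_depth=0.02, hf_depth=0.08),
    ]


def _null_profiles() -> list[ClassProfile]:
    mid = _separable_profiles()[1]
    return [replace(mid, band_amplitudes=dict(mid.band_amplitudes)) for _ in range(3)]


@dataclass
class SynthSpec:
    """Study-scale generation parameters.

    Defaults give 5 subjects x 12 trials x 300 s = 600 segments of 30 s,
    class-balanced across the 3 classes.
    """

    n_subjects: int = 5
    n_trials: int = 12
    duration: float = 300.0
    eeg_rate: float = 128.0
    ecg_rate: float = 256.0
    profiles: list[ClassProfile] = field(default_factory=_separable_profiles)
    mains_amplitude: float = 2.0
    drift_amplitude: float = 10.0
    drift_freq: float = 0.15
    blink_rate: float = 0.3  # events per second
    blink_amplitude: float = 80.0
    eeg_noise_sd: float = 4.0
    ecg_noise_sd: float = 10.0
    seed: int = 0
    preset: str = "separable"

    def validate(self) -> None:
        if self.duration <= 0 or self.eeg_rate <= 0 or self.ecg_rate <= 0:
            raise ValueError("durations and rates must be positive")
        if len(self.profiles) != 3:
            raise ValueError("exactly 3 class profiles required")

    @classmethod
    def separable(cls, **kw) -> "SynthSpec":
        return cls(profiles=_separable_profiles(), preset="separable", **kw)

    @classmethod
    def null(cls, **kw) -> "SynthSpec":
        return cls(profiles=_null_profiles(), preset="null", **kw)


@dataclass
class GroundTruth:
    """What the generator knows: the quantities each stage should recover."""

    class_label: int
    clean_eeg: np.ndarray  # channels x samples, before artifacts
    band_amplitudes: dict[str, float]
    beat_times: np.ndarray  # s
    rr_ms: np.ndarray
    heart_rate_bpm: float
    lf_depth: float
    hf_depth: float


def _trial_rng(spec: SynthSpec, subject: int, trial: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), int(subject), int(trial)])


def _band_noise(rng, n, rate, lo, hi, rms):
    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, min(hi, rate / 2 * 0.99)], btype="bandpass",
                     fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def _blink_source(rng, n, rate, events_per_s, amplitude):
    t = np.arange(n) / rate
    src = np.zeros(n)
    n_events = rng.poisson(events_per_s * n / rate)
    centers = np.sort(rng.uniform(0, n / rate, size=n_events))
    for c in centers:
        src += amplitude * np.exp(-0.5 * ((t - c) / 0.15) ** 2)
    return src


def synth_ecg_waveform(beat_times: np.ndarray, n: int, rate: float) -> np.ndarray:
    """PQRST Gaussian-bump template summed at each beat time (uV-like)."""
    waves = [  # (offset s, amplitude, width s)
        (-0.20, 120.0, 0.060),   # P
        (-0.04, -150.0, 0.020),  # Q
        (0.00, 1000.0, 0.022),   # R
        (0.04, -250.0, 0.020),   # S
        (0.30, 300.0, 0.090),    # T
    ]
    t = np.arange(n) / rate
    x = np.zeros(n)
    for tb in beat_times:
        lo = max(0, int((tb - 0.6) * rate))
        hi = min(n, int((tb + 0.8) * rate))
        w = t[lo:hi]
        for off, amp, width in waves:
            x[lo:hi] += amp * np.exp(-0.5 * ((w - tb - off) / width) ** 2)
    return x


def _beat_times(rng, profile: ClassProfile, duration: float) -> np.ndarray:
    rr_mean = 60.0 / profile.heart_rate_bpm
    times = [0.4]
    while times[-1] < duration - 0.5:
        t = times[-1]
        mod = (1.0
               + profile.lf_depth * np.sin(2 * np.pi * 0.1 * t)
               + profile.hf_depth * np.sin(2 * np.pi * 0.3 * t))
        rr = rr_mean * mod + rng.normal(0.0, profile.rr_jitter_ms / 1000.0)
        rr = max(rr, 0.3)
        times.append(t + rr)
    return np.asarray(times[:-1]) if times[-1] >= duration else np.asarray(times)


def generate_recording(
    spec: SynthSpec, class_label: int, subject_id: int = 0, trial_id: int = 0
) -> tuple[Recording, Recording, TrialScores, GroundTruth]:
    """One synthetic trial: EEG + ECG recordings, scores and ground truth."""
    spec.validate()
    if not 0 <= class_label < len(spec.profiles):
        raise ValueError(f"class_label must be in 0..{len(spec.profiles) - 1}")
    profile = spec.profiles[class_label]
    rng = _trial_rng(spec, subject_id, trial_id)

    n_eeg = int(round(spec.duration * spec.eeg_rate))
    n_ecg = int(round(spec.duration * spec.ecg_rate))
    t_eeg = np.arange(n_eeg) / spec.eeg_rate
    t_ecg = np.arange(n_ecg) / spec.ecg_rate

    clean = np.zeros((len(DREAMER_EEG_NAMES), n_eeg))
    for ch in range(clean.shape[0]):
        for band, (lo, hi) in _BAND_EDGES.items():
            amp = profile.band_amplitudes.get(band, 0.0)
            if amp > 0:
                clean[ch] += _band_noise(rng, n_eeg, spec.eeg_rate, lo, hi, amp)
        clean[ch] += spec.eeg_noise_sd * rng.standard_normal(n_eeg)

    eeg = clean.copy()
    if spec.mains_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        eeg += spec.mains_amplitude * np.sin(2 * np.pi * 50.0 * t_eeg + phase)
    if spec.drift_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=eeg.shape[0])
        eeg += spec.drift_amplitude * np.sin(
            2 * np.pi * spec.drift_freq * t_eeg[None, :] + phases[:, None]
        )
    if spec.blink_rate > 0 and spec.blink_amplitude > 0:
        blink = _blink_source(rng, n_eeg, spec.eeg_rate, spec.blink_rate,
                              spec.blink_amplitude)
        eeg += _BLINK_TOPOGRAPHY[:, None] * blink[None, :]

    beats = _beat_times(rng, profile, spec.duration)
    ecg_wave = synth_ecg_waveform(beats, n_ecg, spec.ecg_rate)
    ecg = np.vstack([
        ecg_wave + spec.ecg_noise_sd * rng.standard_normal(n_ecg),
        0.7 * ecg_wave + spec.ecg_noise_sd * rng.standard_normal(n_ecg),
    ])
    if spec.mains_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        ecg += 0.5 * spec.mains_amplitude * np.sin(2 * np.pi * 50.0 * t_ecg + phase)

    score_pool = {0: (1, 2), 1: (3,), 2: (4, 5)}[class_label]
    scores = TrialScores(*(int(rng.choice(score_pool)) for _ in range(3)))

    rec_eeg = Recording(eeg, spec.eeg_rate, DREAMER_EEG_NAMES, "EEG", subject_id, trial_id)
    rec_ecg = Recording(ecg, spec.ecg_rate, DREAMER_ECG_NAMES, "ECG", subject_id, trial_id)
    truth = GroundTruth(
        class_label=class_label,
        clean_eeg=clean,
        band_amplitudes={b: profile.band_amplitudes.get(b, 0.0) for b in _BAND_EDGES},
        beat_times=beats,
        rr_ms=np.diff(beats) * 1000.0,
        heart_rate_bpm=profile.heart_rate_bpm,
        lf_depth=profile.lf_depth,
        hf_depth=profile.hf_depth,
    )
    return rec_eeg, rec_ecg, scores, truth


@dataclass
class SynthDataset:
    spec: SynthSpec
    trials: list[DreamerTrial]
    truths: list[GroundTruth]

    @property
    def class_labels(self) -> list[int]:
        return [t.class_label for t in self.truths]

    def save(self, out_dir) -> None:
        """Write the MAT container, a labels CSV and a ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_dreamer_container(self.trials, out / "dataset.mat")
        rows = [
            {
                "subject": tr.eeg.subject_id,
                "trial": tr.eeg.trial_id,
                "class": gt.class_label,
                **tr.scores.as_dict(),
            }
            for tr, gt in zip(self.trials, self.truths)
        ]
        pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
        gt_json = [
            {
                "subject": int(tr.eeg.subject_id),
                "trial": int(tr.eeg.trial_id),
                "class": gt.class_label,
                "heart_rate_bpm": gt.heart_rate_bpm,
                "band_amplitudes": gt.band_amplitudes,
                "n_beats": int(len(gt.beat_times)),
                "beat_times": [round(float(b), 6) for b in gt.beat_times],
            }
            for tr, gt in zip(self.trials, self.truths)
        ]
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(gt_json, fh)


def generate_dataset(spec: SynthSpec) -> SynthDataset:
    """n_subjects x n_trials trials, classes cycled for balance."""
    spec.validate()
    trials: list[DreamerTrial] = []
    truths: list[GroundTruth] = []
    for s in range(spec.n_subjects):
        for t in range(spec.n_trials):
            cls = t % 3
            eeg, ecg, scores, truth = generate_recording(spec, cls, s, t)
            trials.append(DreamerTrial(eeg=eeg, ecg=ecg, scores=scores))
            truths.append(truth)
    return SynthDataset(spec=spec, trials=trials, truths=truths)
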