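"""Signal containers and I/O.

Defines the canonical in-memory :class:`Recording` (channels x samples) and
:class:`TrialScores` types, a reader/writer pair for the DREAMER-style MATLAB
container (nested struct ``DREAMER.Data{subject}.EEG.stimuli{trial}`` etc.),
a generic delimited-text signal loader, and lossless persistence of feature
tables (CSV canonical, MAT offered for interoperability).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io as sio

__all__ = [
    "Recording",
    "TrialScores",
    "ContainerLayoutError",
    "DreamerTrial",
    "load_dreamer_container",
    "save_dreamer_container",
    "load_delimited",
    "save_feature_table_csv",
    "load_feature_table_csv",
    "save_feature_table_mat",
    "load_feature_table_mat",
]

#: Expected DREAMER geometry, used only for validation warnings.
DREAMER_EEG_RATE = 128.0
DREAMER_ECG_RATE = 256.0
DREAMER_EEG_CHANNELS = 14
DREAMER_ECG_CHANNELS = 2

#: Emotiv EPOC electrode order used by DREAMER.
DREAMER_EEG_NAMES = [
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
]
DREAMER_ECG_NAMES = ["ECG1", "ECG2"]


class ContainerLayoutError(ValueError):
    """Raised when a MAT container lacks the expected field hierarchy."""


@dataclass
class TrialScores:
    """Self-reported 1-5 ratings for the three VAD emotion dimensions."""

    valence: int
    arousal: int
    dominance: int

    def __post_init__(self) -> None:
        for name in ("valence", "arousal", "dominance"):
            v = getattr(self, name)
            if int(v) != v or not 1 <= int(v) <= 5:
                raise ValueError(f"{name} score must be an integer in 1..5, got {v!r}")
            setattr(self, name, int(v))

    def as_dict(self) -> dict[str, int]:
        return {"valence": self.valence, "arousal": self.arousal, "dominance": self.dominance}


@dataclass
class Recording:
    """A multichannel uniformly sampled signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values (arbitrary units, microvolt-like for EEG).
    rate : float
        Sampling frequency in Hz.
    channel_names : sequence of str
        One label per channel, in on-disk order (never reordered).
    modality : {"EEG", "ECG"}
    subject_id, trial_id : str or int, optional
    """

    data: np.ndarray
    rate: float
    channel_names: Sequence[str]
    modality: str
    subject_id: object = None
    trial_id: object = None
    nonstandard_layout: bool = field(default=False)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.modality not in ("EEG", "ECG"):
            raise ValueError(f"modality must be 'EEG' or 'ECG', got {self.modality!r}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        self.channel_names = list(self.channel_names)
        expected = (
            (DREAMER_EEG_RATE, DREAMER_EEG_CHANNELS)
            if self.modality == "EEG"
            else (DREAMER_ECG_RATE, DREAMER_ECG_CHANNELS)
        )
        if (self.rate, self.n_channels) != expected:
            self.nonstandard_layout = True

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def copy_with(self, data: np.ndarray) -> "Recording":
        """Return a copy of this recording carrying new sample values."""
        return Recording(
            data=np.asarray(data, dtype=float),
            rate=self.rate,
            channel_names=list(self.channel_names),
            modality=self.modality,
            subject_id=self.subject_id,
            trial_id=self.trial_id,
        )

    def require_finite(self) -> None:
        bad = ~np.isfinite(self.data)
        if bad.any():
            chans = [self.channel_names[i] for i in np.unique(np.where(bad)[0])]
            raise ValueError(
                f"non-finite samples in {self.modality} recording "
                f"(subject={self.subject_id}, trial={self.trial_id}) channels {chans}"
            )


@dataclass
class DreamerTrial:
    """One subject x trial entry of a DREAMER-style container."""

    eeg: Recording
    ecg: Recording
    scores: TrialScores
    eeg_baseline: Recording | None = None
    ecg_baseline: Recording | None = None


# ---------------------------------------------------------------------------
# DREAMER-style MAT container
# ---------------------------------------------------------------------------

def _get(obj, name: str, path: str):
    try:
        return getattr(obj, name)
    except AttributeError:
        raise ContainerLayoutError(f"container is missing field '{path}'") from None


def _trial_matrix(cell, idx: int):
    """Extract trial ``idx`` from a MAT cell array as samples x channels."""
    arr = np.asarray(cell)
    if arr.ndim == 0:
        return np.atleast_2d(np.asarray(arr.item(), dtype=float))
    if arr.dtype != object:
        # squeeze_me collapsed a single-trial cell to the matrix itself
        if idx != 0:
            raise ContainerLayoutError(f"trial index {idx} out of range for single-trial cell")
        return np.atleast_2d(np.asarray(arr, dtype=float))
    return np.atleast_2d(np.asarray(arr.ravel()[idx], dtype=float))


def load_dreamer_container(path) -> list[DreamerTrial]:
    """Load a DREAMER-layout MAT file into (EEG, ECG, scores) triples.

    Returns one :class:`DreamerTrial` per subject x trial, in container
    order. Raises :class:`ContainerLayoutError` when the expected field
    hierarchy is absent and ``ValueError`` when samples are non-finite.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mat = sio.loadmat(str(path), squeeze_me=True, struct_as_record=False)
    if "DREAMER" not in mat:
        raise ContainerLayoutError("container is missing field 'DREAMER'")
    root = mat["DREAMER"]
    data = _get(root, "Data", "DREAMER.Data")
    subjects = np.atleast_1d(np.asarray(data, dtype=object).ravel())
    out: list[DreamerTrial] = []
    for s_idx, subj in enumerate(subjects):
        if subj is None or (isinstance(subj, np.ndarray) and subj.size == 0):
            continue
        eeg = _get(subj, "EEG", f"DREAMER.Data[{s_idx}].EEG")
        ecg = _get(subj, "ECG", f"DREAMER.Data[{s_idx}].ECG")
        eeg_stim = _get(eeg, "stimuli", f"DREAMER.Data[{s_idx}].EEG.stimuli")
        ecg_stim = _get(ecg, "stimuli", f"DREAMER.Data[{s_idx}].ECG.stimuli")
        eeg_base = getattr(eeg, "baseline", None)
        ecg_base = getattr(ecg, "baseline", None)
        val = np.atleast_1d(_get(subj, "ScoreValence", f"DREAMER.Data[{s_idx}].ScoreValence"))
        aro = np.atleast_1d(_get(subj, "ScoreArousal", f"DREAMER.Data[{s_idx}].ScoreArousal"))
        dom = np.atleast_1d(_get(subj, "ScoreDominance", f"DREAMER.Data[{s_idx}].ScoreDominance"))
        n_trials = len(np.asarray(val).ravel())
        for t_idx in range(n_trials):
            eeg_mat = _trial_matrix(eeg_stim, t_idx).T  # -> channels x samples
            ecg_mat = _trial_matrix(ecg_stim, t_idx).T
            eeg_names = (
                DREAMER_EEG_NAMES if eeg_mat.shape[0] == DREAMER_EEG_CHANNELS
                else [f"EEG{i+1}" for i in range(eeg_mat.shape[0])]
            )
            ecg_names = (
                DREAMER_ECG_NAMES if ecg_mat.shape[0] == DREAMER_ECG_CHANNELS
                else [f"ECG{i+1}" for i in range(ecg_mat.shape[0])]
            )
            rec_eeg = Recording(eeg_mat, DREAMER_EEG_RATE, eeg_names, "EEG", s_idx, t_idx)
            rec_ecg = Recording(ecg_mat, DREAMER_ECG_RATE, ecg_names, "ECG", s_idx, t_idx)
            rec_eeg.require_finite()
            rec_ecg.require_finite()
            trial = DreamerTrial(
                eeg=rec_eeg,
                ecg=rec_ecg,
                scores=TrialScores(
                    int(np.asarray(val).ravel()[t_idx]),
                    int(np.asarray(aro).ravel()[t_idx]),
                    int(np.asarray(dom).ravel()[t_idx]),
                ),
            )
            for attr, base, rate, names in (
                ("eeg_baseline", eeg_base, DREAMER_EEG_RATE, eeg_names),
                ("ecg_baseline", ecg_base, DREAMER_ECG_RATE, ecg_names),
            ):
                if base is None or not np.asarray(base).size:
                    continue
                mat_b = _trial_matrix(base, t_idx).T
                if mat_b.size:
                    setattr(trial, attr, Recording(
                        mat_b, rate, names, trial.eeg.modality if "eeg" in attr else "ECG",
                        s_idx, t_idx,
                    ))
            out.append(trial)
    return out


def save_dreamer_container(trials: Iterable[DreamerTrial], path) -> None:
    """Write (EEG, ECG, scores) triples as a DREAMER-layout MAT file.

    Trials are grouped by ``subject_id`` (container order preserved); the
    result round-trips through :func:`load_dreamer_container`.
    """
    trials = list(trials)
    by_subject: dict[object, list[DreamerTrial]] = {}
    for t in trials:
        by_subject.setdefault(t.eeg.subject_id, []).append(t)

    def cell(mats: list[np.ndarray]) -> np.ndarray:
        c = np.empty((len(mats), 1), dtype=object)
        for i, m in enumerate(mats):
            c[i, 0] = np.asarray(m)
        return c

    subj_structs = np.empty((len(by_subject), 1), dtype=object)
    for i, (_, ts) in enumerate(by_subject.items()):
        eeg = {
            "stimuli": cell([t.eeg.data.T for t in ts]),
            "baseline": cell([
                (t.eeg_baseline.data.T if t.eeg_baseline is not None else np.zeros((0, 0)))
                for t in ts
            ]),
        }
        ecg = {
            "stimuli": cell([t.ecg.data.T for t in ts]),
            "baseline": cell([
                (t.ecg_baseline.data.T if t.ecg_baseline is not None else np.zeros((0, 0)))
                for t in ts
            ]),
        }
        subj_structs[i, 0] = {
            "EEG": eeg,
            "ECG": ecg,
            "EEG_SamplingRate": DREAMER_EEG_RATE,
            "ECG_SamplingRate": DREAMER_ECG_RATE,
            "ScoreValence": np.array([[t.scores.valence] for t in ts], dtype=float),
            "ScoreArousal": np.array([[t.scores.arousal] for t in ts], dtype=float),
            "ScoreDominance": np.array([[t.scores.dominance] for t in ts], dtype=float),
        }
    root = {
        "Data": subj_structs,
        "noOfSubjects": float(len(by_subject)),
        "noOfVideoSequences": float(len(trials) // max(len(by_subject), 1)),
    }
    sio.savemat(str(path), {"DREAMER": root}, do_compression=False)


# ---------------------------------------------------------------------------
# Delimited text signals
# ---------------------------------------------------------------------------

def load_delimited(path, rate: float, modality: str, delimiter: str | None = None) -> Recording:
    """Read a rectangular delimited numeric table as a Recording.

    One column per channel. A first row of non-numeric labels is taken as the
    header; otherwise channel names are auto-generated. Ragged rows and
    non-numeric cells raise ``ValueError`` citing the offending location.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if delimiter is None:
            try:
                delimiter = csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
            except csv.Error:
                delimiter = ","
        rows = [r for r in csv.reader(fh, delimiter=delimiter) if r]
    if not rows:
        raise ValueError(f"{path}: empty file")

    def parse_row(row, row_idx):
        vals = []
        for col_idx, cell in enumerate(row):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {row_idx}, column {col_idx}"
                ) from None
        return vals

    header: list[str] | None = None
    try:
        first = parse_row(rows[0], 0)
    except ValueError:
        header = [c.strip() for c in rows[0]]
        first = None
    data_rows = rows if first is not None else rows[1:]
    start = 0 if first is not None else 1
    n_cols = len(data_rows[0]) if data_rows else len(header or [])
    parsed = []
    for i, row in enumerate(data_rows):
        if len(row) != n_cols:
            raise ValueError(
                f"{path}: ragged row {start + i}: expected {n_cols} columns, got {len(row)}"
            )
        parsed.append(parse_row(row, start + i))
    arr = np.asarray(parsed, dtype=float).T  # columns -> channels
    names = header if header is not None else [f"ch{i+1}" for i in range(arr.shape[0])]
    return Recording(arr, rate=rate, channel_names=names, modality=modality)


# ---------------------------------------------------------------------------
# Feature tables (CSV canonical; MAT for interoperability)
# ---------------------------------------------------------------------------

def save_feature_table_csv(df: pd.DataFrame, path) -> None:
    """Persist a samples x features table with its header, losslessly."""
    df.to_csv(path, index=True, float_format="%.17g")


def load_feature_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, float_precision="round_trip")


def save_feature_table_mat(df: pd.DataFrame, path) -> None:
    sio.savemat(
        str(path),
        {
            "values": df.to_numpy(dtype=float),
            "feature_names": np.array(list(df.columns), dtype=object),
            "row_ids": np.array([str(i) for i in df.index], dtype=object),
        },
    )


def load_feature_table_mat(path) -> pd.DataFrame:
    mat = sio.loadmat(str(path), squeeze_me=True)
    for key in ("values", "feature_names"):
        if key not in mat:
            raise ContainerLayoutError(f"feature-table MAT is missing field '{key}'")
    values = np.atleast_2d(np.asarray(mat["values"], dtype=float))
    names = [str(n) for n in np.atleast_1d(mat["feature_names"])]
    if values.size == 0:
        values = values.reshape(0, len(names))
    idx = [str(i) for i in np.atleast_1d(mat.get("row_ids", np.arange(values.shape[0])))]
    return pd.DataFrame(values, columns=names, index=idx)
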