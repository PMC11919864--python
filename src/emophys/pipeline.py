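"""End-to-end orchestration: data -> preprocess -> features -> select ->
train -> evaluate.

The stages mirror the processing flow: (1) assemble trials (synthetic or
from a MAT container), (2) denoise and slice into 30 s segments, (3) extract
EEG and ECG features and fuse them, (4) random-forest feature selection,
(5) stratified 80/20 split with 10%-of-train validation and Att-1DCNN-GRU
training, (6) evaluation on the held-out test set. Every artifact is
written with a provenance header (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (
    ECGFeatureSpec,
    EEGFeatureSpec,
    ecg_feature_vector,
    eeg_feature_vector,
)
from .io import DreamerTrial, load_dreamer_container
from .model import (
    AttCnnGru,
    AttCnnGruResults,
    ModelConfig,
    map_score_to_class,
    split_dataset,
)
from .preprocess import FilterSpec, ICARejectionSpec, preprocess_recording
from .selection import (
    FeatureTable,
    fuse,
    rank_features,
    select_top_families,
    select_top_k,
)
from .synth import SynthSpec, generate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "extract_features", "preprocess_trials"]

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """One document controlling every stage (YAML/JSON loadable)."""

    dimension: str = "valence"
    dataset_path: str | None = None  # MAT container; None -> synthesize
    synth: SynthSpec = field(default_factory=SynthSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    ica: ICARejectionSpec = field(default_factory=ICARejectionSpec)
    use_ica: bool = True
    window_s: float = 30.0
    eeg_features: EEGFeatureSpec = field(default_factory=EEGFeatureSpec)
    ecg_features: ECGFeatureSpec = field(default_factory=ECGFeatureSpec)
    n_trees: int = 80
    selection_mode: str = "top_k"  # or "top_families"
    top_k: int = 9
    top_families: int = 9
    model: ModelConfig = field(default_factory=ModelConfig)
    test_fraction: float = 0.2
    val_fraction: float = 0.1
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.dimension not in ("valence", "arousal", "dominance"):
            raise PipelineConfigError(f"unknown dimension {self.dimension!r}")
        if self.selection_mode not in ("top_k", "top_families"):
            raise PipelineConfigError(f"unknown selection_mode {self.selection_mode!r}")
        if self.dataset_path is not None and not Path(self.dataset_path).exists():
            raise PipelineConfigError(f"dataset path does not exist: {self.dataset_path}")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("synth", SynthSpec), ("filter", FilterSpec), ("ica", ICARejectionSpec),
            ("eeg_features", EEGFeatureSpec), ("ecg_features", ECGFeatureSpec),
            ("model", ModelConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub = {k: v for k, v in d[key].items()
                       if k in {f.name for f in dataclasses.fields(typ)}}
                d[key] = typ(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise PipelineConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    report: "object"
    results: AttCnnGruResults
    feature_table: FeatureTable
    selected_table: FeatureTable
    ranking: "object"
    artifacts: dict[str, str] = field(default_factory=dict)


def preprocess_trials(trials: list[DreamerTrial], config: PipelineConfig):
    """Stage 2: denoise and window all trials; returns (eeg_segs, ecg_segs)."""
    eeg_segments, ecg_segments = [], []
    for trial in trials:
        eeg_segments.extend(
            preprocess_recording(
                trial.eeg, config.filter, labels=trial.scores,
                window_s=config.window_s, use_ica=config.use_ica,
                ica_rejection=config.ica, seed=config.seed,
            )
        )
        ecg_segments.extend(
            preprocess_recording(
                trial.ecg, config.filter, labels=trial.scores,
                window_s=config.window_s, use_ica=False,
            )
        )
    return eeg_segments, ecg_segments


def extract_features(eeg_segments, ecg_segments, config: PipelineConfig) -> FeatureTable:
    """Stage 3: per-segment EEG + ECG feature vectors, fused EEG-first."""
    eeg_vectors = [eeg_feature_vector(s, config.eeg_features) for s in eeg_segments]
    ecg_vectors = [ecg_feature_vector(s, config.ecg_features) for s in ecg_segments]
    labels = pd.Series(
        [map_score_to_class(getattr(s.label, config.dimension)) for s in eeg_segments],
        index=[s.segment_id for s in eeg_segments],
        name=config.dimension,
    )
    eeg_table = FeatureTable.from_vectors(eeg_vectors, "EEG", labels)
    ecg_table = FeatureTable.from_vectors(ecg_vectors, "ECG")
    return fuse(eeg_table, ecg_table).impute_median()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all six stages and (optionally) write artifacts to disk."""
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s start", name)
        timings[name] = time.perf_counter()

    def done(name, shape):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.1fs: %s", name, timings[name], shape)

    stage("load")
    if config.dataset_path is not None:
        trials = load_dreamer_container(config.dataset_path)
    else:
        synth = dataclasses.replace(config.synth, seed=config.seed)
        trials = generate_dataset(synth).trials
    done("load", f"{len(trials)} trials")

    stage("preprocess")
    eeg_segments, ecg_segments = preprocess_trials(trials, config)
    done("preprocess", f"{len(eeg_segments)} EEG / {len(ecg_segments)} ECG segments")
    if not eeg_segments:
        raise PipelineConfigError("no segments produced; recordings shorter than one window?")

    stage("features")
    table = extract_features(eeg_segments, ecg_segments, config)
    done("features", f"{table.n_samples} x {len(table.feature_names)}")

    stage("select")
    ranking = rank_features(table, n_trees=config.n_trees, seed=config.seed)
    if config.selection_mode == "top_k":
        selected = select_top_k(table, ranking, config.top_k)
    else:
        selected = select_top_families(table, ranking, config.top_families)
    done("select", f"{len(selected.feature_names)} features retained")

    stage("train")
    train, val, test = split_dataset(
        selected, config.test_fraction, config.val_fraction, seed=config.seed
    )
    cfg = dataclasses.replace(config.model, seed=config.seed)
    model = AttCnnGru.from_feature_table(train, config=cfg, dimension=config.dimension)
    results = model.fit(validation=val)
    done("train", f"{len(results.history)} epochs")

    stage("evaluate")
    report = results.evaluate(test)
    done("evaluate", f"accuracy {report.accuracy:.3f}")

    artifacts: dict[str, str] = {}
    if out_dir:
        def _write(name, fn):
            path = out_dir / name
            fn(path)
            artifacts[name] = str(path)

        header = json.dumps(provenance)
        _write("features.csv", table.save_csv)
        _write("selected_features.csv", selected.save_csv)
        _write("ranking.csv", ranking.save_csv)
        _write("history.csv", lambda p: results.history.to_csv(p, index=False))
        _write("model.npz", results.save)
        _write("report.json", report.to_json)
        _write("report.txt", lambda p: Path(p).write_text(str(report) + "\n"))
        _write(
            "manifest.json",
            lambda p: Path(p).write_text(json.dumps(
                {**provenance, "timings_s": {k: round(v, 3) for k, v in timings.items()},
                 "config": config.to_dict(), "artifacts": sorted(artifacts)},
                indent=2, default=str,
            )),
        )
        logger.info("artifacts written to %s (provenance %s)", out_dir, header)
    return PipelineResult(
        report=report, results=results, feature_table=table,
        selected_table=selected, ranking=ranking, artifacts=artifacts,
    )
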