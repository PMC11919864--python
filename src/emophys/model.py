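"""The Att-1DCNN-GRU emotion classifier, as Model/Results objects.

:class:`AttCnnGru` is built from a training design matrix and 3-class labels
(one model per emotion dimension — valence, arousal or dominance); its
:meth:`~AttCnnGru.fit` trains with Adam under categorical cross-entropy and
returns an :class:`AttCnnGruResults` carrying the fitted weights, per-epoch
history, the feature-name contract and evaluation helpers.

Self-report scores (1-5) collapse to three classes: {1,2} -> 0 (low),
{3} -> 1 (neutral), {4,5} -> 2 (high).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import nn
from .evaluation import EvaluationReport, multiclass_report
from .io import TrialScores
from .selection import FeatureTable

__all__ = [
    "ModelConfig",
    "TrainingDivergedError",
    "map_score_to_class",
    "map_scores_to_classes",
    "split_dataset",
    "AttCnnGru",
    "AttCnnGruResults",
    "grid_search",
]

logger = logging.getLogger(__name__)

DIMENSIONS = ("valence", "arousal", "dominance")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    Defaults are the selected grid point: 256 kernels in both convolutional
    layers, kernel size 3, 256 GRU units, 50 epochs, batch size 256,
    Adam at learning rate 0.001.
    """

    conv1_filters: int = 256
    conv2_filters: int = 256
    kernel_size: int = 3
    pool_size: int = 2
    gru_units: int = 256
    attention_dim: int = 64
    dense_units: int = 128
    n_classes: int = 3
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 256
    seed: int = 0
    early_stopping: bool = False
    early_stopping_patience: int = 10

    def validate(self) -> None:
        for name in ("conv1_filters", "conv2_filters", "kernel_size", "pool_size",
                     "gru_units", "attention_dim", "dense_units", "n_classes",
                     "epochs", "batch_size"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not 0 < self.learning_rate < 1:
            raise ValueError("learning_rate must be in (0, 1)")


def map_score_to_class(score: int) -> int:
    """Collapse a 1-5 self-report score to a 3-way class index."""
    if score in (1, 2):
        return 0
    if score == 3:
        return 1
    if score in (4, 5):
        return 2
    raise ValueError(f"score must be in 1..5, got {score!r}")


def map_scores_to_classes(scores: TrialScores) -> dict[str, int]:
    """Per-dimension class indices for one trial's VAD ratings."""
    return {dim: map_score_to_class(getattr(scores, dim)) for dim in DIMENSIONS}


def split_dataset(
    table: FeatureTable,
    test_fraction: float = 0.2,
    val_fraction: float = 0.1,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Stratified train/validation/test split.

    First ``test_fraction`` is held out, then ``val_fraction`` of the
    remaining training rows becomes the validation set (so the default
    80/20 with 10%-of-train validation gives 72/8/20 overall).
    """
    if table.labels is None:
        raise ValueError("feature table carries no labels")
    y = table.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if stratify and counts.min() < 10:
        raise ValueError(
            f"class {classes[counts.argmin()]} has only {counts.min()} samples; "
            "need >= 10 per class to stratify"
        )
    idx = np.arange(len(y))
    strat = y if stratify else None
    idx_train, idx_test = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=strat
    )
    strat2 = y[idx_train] if stratify else None
    idx_fit, idx_val = train_test_split(
        idx_train, test_size=val_fraction, random_state=seed, stratify=strat2
    )

    def subset(ix):
        return FeatureTable(table.df.iloc[ix], table.labels.iloc[ix], table.provenance)

    return subset(np.sort(idx_fit)), subset(np.sort(idx_val)), subset(np.sort(idx_test))


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


class AttCnnGru:
    """Attention 1D-CNN-GRU model bound to training data.

    Parameters
    ----------
    endog : array-like of int, shape (n,)
        Class labels in ``0..n_classes-1``.
    exog : ndarray or DataFrame, shape (n, n_features)
        Feature matrix; column names become the feature contract.
    config : ModelConfig, optional
    feature_names : sequence of str, optional
        Required when ``exog`` has no column names.
    """

    def __init__(self, endog, exog, config: ModelConfig | None = None,
                 feature_names=None, dimension: str | None = None) -> None:
        self.config = config or ModelConfig()
        self.config.validate()
        if isinstance(exog, pd.DataFrame):
            self.feature_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            self.feature_names = (
                list(feature_names) if feature_names is not None
                else [f"x{i}" for i in range(X.shape[1])]
            )
        y = np.asarray(endog, dtype=int)
        if len(y) != len(X):
            raise ValueError("endog and exog lengths differ")
        if y.min() < 0 or y.max() >= self.config.n_classes:
            raise ValueError(f"labels must lie in 0..{self.config.n_classes - 1}")
        if X.shape[1] < self.config.kernel_size:
            raise ValueError("fewer features than the convolution kernel size")
        self.endog = y
        self.exog = X
        self.dimension = dimension

    @classmethod
    def from_feature_table(
        cls, table: FeatureTable, config: ModelConfig | None = None,
        dimension: str | None = None,
    ) -> "AttCnnGru":
        if table.labels is None:
            raise ValueError("feature table carries no labels")
        return cls(table.labels.to_numpy(), table.df, config=config, dimension=dimension)

    # -- training ----------------------------------------------------------

    def fit(self, validation: tuple | FeatureTable | None = None,
            verbose: bool = False) -> "AttCnnGruResults":
        """Train with Adam + categorical cross-entropy.

        ``validation`` is either a ``(X_val, y_val)`` pair or a labelled
        :class:`FeatureTable`; the epoch with the lowest validation loss
        supplies the retained weights (training loss if no validation set).
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        mu = self.exog.mean(axis=0)
        sd = self.exog.std(axis=0)
        sd[sd == 0] = 1.0
        X = (self.exog - mu) / sd
        Y = _one_hot(self.endog, cfg.n_classes)

        if isinstance(validation, FeatureTable):
            Xv_raw = validation.df[self.feature_names].to_numpy(dtype=float)
            yv = validation.labels.to_numpy()
        elif validation is not None:
            Xv_raw = np.asarray(validation[0], dtype=float)
            yv = np.asarray(validation[1], dtype=int)
        else:
            Xv_raw = yv = None

        params = nn.init_params(cfg, X.shape[1], rng)
        opt = nn.AdamState(params, lr=cfg.learning_rate)
        history = []
        best = {"loss": np.inf, "params": None, "epoch": -1}
        n = len(X)
        last_finite = -1
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            # epoch metrics are running minibatch averages (Keras-style)
            loss_sum = 0.0
            correct = 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                probs, cache = nn.forward(params, X[sel], cfg)
                loss_sum += nn.categorical_cross_entropy(Y[sel], probs) * len(sel)
                correct += int(np.sum(probs.argmax(axis=1) == self.endog[sel]))
                grads = nn.backward(params, cache, Y[sel], cfg)
                nn.adam_step(params, grads, opt)
            train_loss = loss_sum / n
            train_acc = correct / n
            row = {"epoch": epoch, "loss": train_loss, "accuracy": train_acc}
            monitor = train_loss
            if Xv_raw is not None:
                val_probs, _ = nn.forward(params, (Xv_raw - mu) / sd, cfg)
                Yv = _one_hot(yv, cfg.n_classes)
                row["val_loss"] = nn.categorical_cross_entropy(Yv, val_probs)
                row["val_accuracy"] = float(np.mean(val_probs.argmax(axis=1) == yv))
                monitor = row["val_loss"]
            history.append(row)
            if not np.isfinite(train_loss):
                raise TrainingDivergedError(
                    f"loss became non-finite at epoch {epoch}; "
                    f"last finite epoch: {last_finite}"
                )
            last_finite = epoch
            if monitor < best["loss"]:
                best = {"loss": monitor, "params": copy.deepcopy(params), "epoch": epoch}
            if verbose:
                logger.info("epoch %d: %s", epoch, row)
            if (cfg.early_stopping and Xv_raw is not None
                    and epoch - best["epoch"] >= cfg.early_stopping_patience):
                break
        final_params = best["params"] if best["params"] is not None else params
        return AttCnnGruResults(
            model=self,
            params=final_params,
            history=pd.DataFrame(history),
            standardizer=(mu, sd),
            best_epoch=best["epoch"],
        )


class AttCnnGruResults:
    """Fitted Att-1DCNN-GRU: weights, history, prediction and evaluation."""

    def __init__(self, model: AttCnnGru, params: dict, history: pd.DataFrame,
                 standardizer: tuple[np.ndarray, np.ndarray], best_epoch: int) -> None:
        self.model = model
        self.config = model.config
        self.params = params
        self.history = history
        self.standardizer = standardizer
        self.best_epoch = best_epoch
        self.feature_names = model.feature_names

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _check_features(self, X) -> np.ndarray:
        if isinstance(X, FeatureTable):
            X = X.df
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names:
                raise ValueError(
                    "feature names do not match the training contract: "
                    f"expected {self.feature_names}, got {list(X.columns)}"
                )
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability rows (each sums to 1)."""
        X = self._check_features(X)
        mu, sd = self.standardizer
        probs, _ = nn.forward(self.params, (X - mu) / sd, self.config)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def evaluate(self, X, y=None, dimension: str | None = None) -> EvaluationReport:
        """Accuracy/precision/recall/F1 + confusion matrix on held-out data."""
        if isinstance(X, FeatureTable):
            y = X.labels.to_numpy()
        if y is None:
            raise ValueError("labels required for evaluation")
        pred = self.predict(X)
        return multiclass_report(
            np.asarray(y, dtype=int), pred, n_classes=self.config.n_classes,
            dimension=dimension or self.model.dimension,
        )

    def save(self, path) -> None:
        """Persist weights + config + feature contract as a single archive."""
        meta = {
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "best_epoch": self.best_epoch,
            "dimension": self.model.dimension,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            __mu__=self.standardizer[0],
            __sd__=self.standardizer[1],
            **self.params,
        )

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavoured)."""
        cfg = self.config
        h = self.history
        lines = [
            "          Att-1DCNN-GRU Results",
            "=" * 46,
            f"Dimension:        {self.model.dimension or '-'}",
            f"N train samples:  {len(self.model.endog)}",
            f"N features:       {len(self.feature_names)}",
            f"N parameters:     {self.n_parameters}",
            f"Conv filters:     {cfg.conv1_filters}, {cfg.conv2_filters} (kernel {cfg.kernel_size})",
            f"GRU units:        {cfg.gru_units}  Attention dim: {cfg.attention_dim}",
            f"Optimizer:        Adam (lr={cfg.learning_rate})",
            f"Epochs run:       {len(h)} (batch {cfg.batch_size})",
            f"Best epoch:       {self.best_epoch}",
            f"Final train loss: {h['loss'].iloc[-1]:.4f}  acc: {h['accuracy'].iloc[-1]:.4f}",
        ]
        if "val_loss" in h:
            lines.append(
                f"Final val loss:   {h['val_loss'].iloc[-1]:.4f}  "
                f"acc: {h['val_accuracy'].iloc[-1]:.4f}"
            )
        lines.append("=" * 46)
        return "\n".join(lines)


def load_results(path) -> AttCnnGruResults:
    """Inverse of :meth:`AttCnnGruResults.save` (model bound to empty data)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = {k: z[k] for k in z.files if not k.startswith("__")}
        mu, sd = z["__mu__"], z["__sd__"]
    cfg = ModelConfig(**meta["config"])
    n_feat = len(meta["feature_names"])
    stub = AttCnnGru(
        np.zeros(1, dtype=int), np.zeros((1, n_feat)), config=cfg,
        feature_names=meta["feature_names"], dimension=meta["dimension"],
    )
    return AttCnnGruResults(stub, params, pd.DataFrame(), (mu, sd), meta["best_epoch"])


def grid_search(
    configs: list[ModelConfig],
    train: FeatureTable,
    val: FeatureTable,
    dimension: str | None = None,
) -> pd.DataFrame:
    """Fit every config on ``train`` and rank by validation accuracy."""
    if not configs:
        raise ValueError("need at least one config")
    rows = []
    for i, cfg in enumerate(configs):
        model = AttCnnGru.from_feature_table(train, config=cfg, dimension=dimension)
        res = model.fit(validation=val)
        probs = res.predict_proba(val.df)
        acc = float(np.mean(probs.argmax(axis=1) == val.labels.to_numpy()))
        rows.append(
            {
                "config_index": i,
                "conv1_filters": cfg.conv1_filters,
                "conv2_filters": cfg.conv2_filters,
                "kernel_size": cfg.kernel_size,
                "gru_units": cfg.gru_units,
                "epochs": cfg.epochs,
                "batch_size": cfg.batch_size,
                "val_accuracy": acc,
            }
        )
    out = pd.DataFrame(rows).sort_values("val_accuracy", ascending=False)
    return out.reset_index(drop=True)
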