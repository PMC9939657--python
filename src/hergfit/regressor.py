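"""Spectrogram -> normalized-parameter regressor.

Maps a current spectrogram to the nine normalized channel parameters,
trained with mean squared error.  Training follows a two-stage resolution
schedule: a first stage on lower-resolution spectrograms over a subset of
the data, then a transfer stage at full resolution over the full set,
reusing the weights.

The default backbone is deliberately small — a resolution-agnostic
front-end (bilinear pooling of the input grid to a fixed feature grid)
feeding a multilayer perceptron — sized for CPU training on a few thousand
examples.  Because the front-end pools any resolution to the same feature
grid, weights transfer across the stage schedule's resolutions.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.neural_network import MLPRegressor

from .dataset import Dataset
from .errors import ModelFormatError, TrainingError
from .features import (DEFAULT_STFT, DEFAULT_TRACE_SCALE, Spectrogram,
                       StftParams, _resize, stft_spectrogram, trace_to_input)
from .priors import DEFAULT_NORMALIZATION, NormalizationSpec

_MAGIC = "hergfit-regressor"
_VERSION = 1


@dataclass(frozen=True)
class StageSpec:
    """One step of the resolution schedule."""

    resolution: tuple[int, int]
    n_examples: int | None   # None = full training set
    epochs: int


@dataclass(frozen=True)
class RegressorConfig:
    backbone: str = "small_mlp"
    input_resolution: tuple[int, int] = (129, 129)
    pool_grid: tuple[int, int] = (24, 24)
    hidden_layers: tuple[int, ...] = (256, 128)
    batch_size: int = 64
    learning_rate: float = 1e-3
    alpha: float = 1e-5          # L2 penalty
    standardize_features: bool = False  # z-score features on stage-0 stats
    seed: int = 0
    stage_schedule: tuple[StageSpec, ...] = (
        StageSpec(resolution=(97, 97), n_examples=None, epochs=60),
        StageSpec(resolution=(129, 129), n_examples=None, epochs=40),
    )
    stft: StftParams = DEFAULT_STFT
    trace_scale: float = DEFAULT_TRACE_SCALE

    def __post_init__(self):
        if not self.stage_schedule:
            raise ValueError("stage schedule must be non-empty")
        for st in self.stage_schedule:
            if min(st.resolution) < 2 or st.epochs < 1:
                raise ValueError(f"bad stage {st}")


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over the batch of the squared Euclidean error ||f(x) - y||^2."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    pred = np.atleast_2d(pred)
    target = np.atleast_2d(target)
    return float(np.mean(np.sum((pred - target) ** 2, axis=1)))


@dataclass
class TrainedRegressor:
    mlp: MLPRegressor
    config: RegressorConfig
    norm: NormalizationSpec
    training_log: list = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def _features(self, spec: Spectrogram) -> np.ndarray:
        x = _resize(spec.grid, *self.config.pool_grid).ravel()
        if self.feature_mean is not None:
            x = (x - self.feature_mean) / self.feature_std
        return x

    def predict(self, spec: Spectrogram) -> np.ndarray:
        """Normalized 9-vector, clipped to [0,1]."""
        if spec.resolution != tuple(self.config.input_resolution):
            raise ValueError(
                f"spectrogram resolution {spec.resolution} != model input "
                f"{tuple(self.config.input_resolution)}; resize first"
            )
        x = self._features(spec)[None, :]
        return np.clip(self.mlp.predict(x)[0], 0.0, 1.0)

    def predict_trace(self, trace) -> np.ndarray:
        """Convenience: trace -> spectrogram at model resolution -> predict."""
        spec = trace_to_input(trace, tuple(self.config.input_resolution),
                              params=self.config.stft,
                              trace_scale=self.config.trace_scale)
        return self.predict(spec)

    def predict_batch(self, specs: list[Spectrogram]) -> np.ndarray:
        X = np.stack([self._features(s) for s in specs])
        return np.clip(self.mlp.predict(X), 0.0, 1.0)


def _dataset_features(ds: Dataset, resolution, config: RegressorConfig) -> np.ndarray:
    """Spectrogram features (pooled, flattened) for every trace in a dataset."""
    feats = np.empty((len(ds), config.pool_grid[0] * config.pool_grid[1]))
    for i in range(len(ds)):
        spec = stft_spectrogram(ds.traces[i], params=config.stft,
                                trace_scale=config.trace_scale)
        grid = _resize(spec.grid, *resolution)          # stage resolution
        feats[i] = _resize(grid, *config.pool_grid).ravel()
    return feats


def train(
    config: RegressorConfig,
    train_data: Dataset,
    val_data: Dataset | None = None,
    norm: NormalizationSpec = DEFAULT_NORMALIZATION,
    verbose: bool = False,
) -> TrainedRegressor:
    """Run the stage schedule; returns the trained regressor with its log.

    Each stage prepares spectrograms at its resolution (first ``n_examples``
    of the training set, or all) and continues optimizing the same weights
    (adam, fixed learning rate).  Raises :class:`TrainingError` if the loss
    becomes non-finite.
    """
    if len(train_data) == 0:
        raise ValueError("empty training set")
    if config.backbone != "small_mlp":
        raise ValueError(f"unknown backbone {config.backbone!r}")

    mlp = MLPRegressor(
        hidden_layer_sizes=tuple(config.hidden_layers),
        solver="adam",
        alpha=config.alpha,
        batch_size=min(config.batch_size, len(train_data)),
        learning_rate_init=config.learning_rate,
        random_state=config.seed,
        warm_start=True,
        max_iter=1,
        tol=0.0,
        n_iter_no_change=10**9,  # run every scheduled epoch
    )
    log: list[dict] = []
    feat_mean = feat_std = None
    for si, stage in enumerate(config.stage_schedule):
        n = len(train_data) if stage.n_examples is None else min(stage.n_examples, len(train_data))
        X = _dataset_features(_subset(train_data, n), stage.resolution, config)
        if config.standardize_features:
            if feat_mean is None:
                # frozen at stage 0 so later stages and inference share one
                # transform; off by default — the raw low-frequency bins carry
                # the amplitude cue for g_Kr and z-scoring washes it out
                feat_mean = X.mean(axis=0)
                feat_std = X.std(axis=0) + 1e-8
            X = (X - feat_mean) / feat_std
        y = train_data.targets[:n]
        mlp.set_params(max_iter=stage.epochs)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ConvergenceWarning: epochs are the budget
            mlp.fit(X, y)
        losses = [float(v) for v in mlp.loss_curve_]
        if not np.all(np.isfinite(losses)):
            raise TrainingError(f"training loss diverged in stage {si}")
        entry = {"stage": si, "resolution": list(stage.resolution), "n_examples": n,
                 "epochs": stage.epochs, "loss_curve": losses,
                 "final_train_mse": mse_loss(mlp.predict(X), y)}
        if val_data is not None and len(val_data) > 0:
            Xv = _dataset_features(val_data, stage.resolution, config)
            if feat_mean is not None:
                Xv = (Xv - feat_mean) / feat_std
            entry["val_mse"] = mse_loss(mlp.predict(Xv), val_data.targets)
        log.append(entry)
        if verbose:
            print(f"stage {si}: res={stage.resolution} n={n} "
                  f"train_mse={entry['final_train_mse']:.5f} "
                  f"val_mse={entry.get('val_mse', float('nan')):.5f}")
    return TrainedRegressor(mlp=mlp, config=config, norm=norm, training_log=log,
                            feature_mean=feat_mean, feature_std=feat_std)


def _subset(ds: Dataset, n: int) -> Dataset:
    if n >= len(ds):
        return ds
    return Dataset(traces=ds.traces[:n], targets=ds.targets[:n],
                   theta=ds.theta[:n], manifest=dict(ds.manifest, n=n))


def save(model: TrainedRegressor, path) -> None:
    """Serialize model + embedded config to a single file."""
    payload = {
        "magic": _MAGIC,
        "version": _VERSION,
        "config": asdict(model.config),
        "norm": asdict(model.norm),
        "training_log": model.training_log,
        "mlp": model.mlp,
        "feature_mean": model.feature_mean,
        "feature_std": model.feature_std,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load(path) -> TrainedRegressor:
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _MAGIC:
        raise ModelFormatError(f"{path} is not a saved regressor")
    if payload.get("version") != _VERSION:
        raise ModelFormatError(
            f"model version {payload.get('version')} != supported {_VERSION}"
        )
    cfg = payload["config"]
    cfg["stage_schedule"] = tuple(
        StageSpec(resolution=tuple(s["resolution"]), n_examples=s["n_examples"],
                  epochs=s["epochs"]) for s in cfg["stage_schedule"]
    )
    cfg["stft"] = StftParams(**cfg["stft"])
    for key in ("input_resolution", "pool_grid", "hidden_layers"):
        cfg[key] = tuple(cfg[key])
    norm = payload["norm"]
    return TrainedRegressor(
        mlp=payload["mlp"],
        config=RegressorConfig(**cfg),
        norm=NormalizationSpec(log_flags=tuple(norm["log_flags"]),
                               lo=tuple(norm["lo"]), hi=tuple(norm["hi"])),
        training_log=payload["training_log"],
        feature_mean=payload.get("feature_mean"),
        feature_std=payload.get("feature_std"),
    )
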