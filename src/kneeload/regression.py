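"""Surrogate regressors mapping kinematic (and optionally GRF) samples to
the five knee-contact-force targets.

Two families are provided, mirroring common practice in biomechanical
surrogate modelling:

* a multi-output feed-forward neural network (two ReLU hidden layers of 400
  units, Adam, mean-squared-error loss) with early stopping on a held-out
  validation split, and
* a bank of five independent single-output epsilon-insensitive support
  vector regressions with a Gaussian kernel of fixed scale (SVR has no
  native multi-output mode).

Inputs are standardized inside the surrogate (a fixed kernel scale is
meaningless on mixed degree/body-weight units); targets are left in
body-weight units so reported errors are physical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .errors import ConfigurationError, ContractError, TrainingError
from .preprocess import SampleSet


@dataclass(frozen=True)
class ANNConfig:
    """Feed-forward network hyperparameters.

    Defaults: two hidden layers of 400 rectifier units, Adam with
    lr=1e-3 and betas (0.9, 0.999), minibatches of 256, 10% validation
    split, and early stopping after 10 epochs without validation
    improvement.
    """

    hidden_layers: tuple = (400, 400)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    early_stop_patience: int = 10
    max_epochs: int = 500
    batch_size: int = 256
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience < 1:
            raise ConfigurationError("early_stop_patience must be >= 1")
        if any(w <= 0 for w in self.hidden_layers):
            raise ConfigurationError("hidden layer widths must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ConfigurationError("validation_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SVRConfig:
    """Gaussian-kernel SVR hyperparameters, fixed rather than tuned.

    ``kernel_scale`` s enters the kernel as K(u, v) =
    exp(-||u - v||^2 / (2 s^2)) on standardized inputs by default;
    the alternate convention exp(-||u - v||^2 / s^2) is selectable.
    ``max_train_rows`` caps the kernel problem size by stratified-by-trial
    thinning (kernel methods scale quadratically in rows).
    """

    kernel_scale: float = 0.6
    epsilon: float = 0.01  # BW, half-width of the insensitive tube
    box_constraint: float = 1.0
    standardize_inputs: bool = True
    scale_convention: str = "half"  # "half": 2 s^2 denominator; "plain": s^2
    max_train_rows: int = 20000
    tol: float = 1e-3  # dual solver stopping tolerance
    polynomial_degree: int = 1  # retained for the polynomial form; unused with rbf

    def __post_init__(self):
        if self.kernel_scale <= 0:
            raise ConfigurationError("kernel_scale must be > 0")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be >= 0")
        if self.box_constraint <= 0:
            raise ConfigurationError("box_constraint must be > 0")
        if self.scale_convention not in ("half", "plain"):
            raise ConfigurationError("scale_convention must be 'half' or 'plain'")

    @property
    def gamma(self) -> float:
        denom = 2.0 if self.scale_convention == "half" else 1.0
        return 1.0 / (denom * self.kernel_scale**2)


class EarlyStopping:
    """Stop when the monitored loss has not improved for ``patience`` epochs.

    ``update`` returns True exactly ``patience`` epochs after the last
    improvement (strict improvement by more than ``min_delta``).
    """

    def __init__(self, patience: int, min_delta: float = 0.0):
        if patience < 1:
            raise ConfigurationError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.epochs_since_best = 0

    def update(self, loss: float) -> bool:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


@dataclass
class TrainedSurrogate:
    """A fitted regressor plus its input standardization and feature list."""

    kind: str  # "ann" | "svr_bank" | "custom"
    model: object  # MLPRegressor, list[SVR], or a callable for "custom"
    feature_names: list
    target_names: list
    input_mean: np.ndarray
    input_sd: np.ndarray
    training_log: list = field(default_factory=list)


def _standardization(x: np.ndarray):
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def train_ann(train: SampleSet, cfg: ANNConfig | None = None) -> TrainedSurrogate:
    """Fit the multi-output network with explicit epoch-wise early stopping.

    A ``validation_fraction`` share of the training rows is held out (never
    touching any test data); after each epoch the validation MSE is logged
    and training stops once it has failed to improve for
    ``early_stop_patience`` consecutive epochs, or at ``max_epochs``.
    """
    if cfg is None:
        cfg = ANNConfig()
    if train.n_samples == 0:
        raise TrainingError("training set is empty")
    if not np.all(np.isfinite(train.Y)):
        raise TrainingError("targets must be finite")

    mean, sd = _standardization(train.X)
    x = (train.X - mean) / sd
    y = train.Y

    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    if n_val >= n:
        raise TrainingError("not enough rows for a validation split")
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    x_fit, y_fit = x[fit_idx], y[fit_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    net = MLPRegressor(
        hidden_layer_sizes=tuple(cfg.hidden_layers),
        activation="relu",
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        beta_1=cfg.beta1,
        beta_2=cfg.beta2,
        batch_size=min(cfg.batch_size, x_fit.shape[0]),
        shuffle=True,
        random_state=cfg.seed,
        max_iter=1,  # epochs are driven manually through partial_fit
    )
    stopper = EarlyStopping(cfg.early_stop_patience)
    log = []
    best_loss = np.inf
    best_params = None
    for epoch in range(cfg.max_epochs):
        net.partial_fit(x_fit, y_fit)
        residual = net.predict(x_val) - y_val
        val_loss = float(np.mean(residual**2))
        log.append({"epoch": epoch, "val_mse": val_loss})
        if not np.isfinite(val_loss):
            raise TrainingError("validation loss diverged (NaN/inf)", log=log)
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = (
                [w.copy() for w in net.coefs_],
                [b.copy() for b in net.intercepts_],
            )
        if stopper.update(val_loss):
            break
    if best_params is not None:  # restore the best validation snapshot
        net.coefs_, net.intercepts_ = best_params

    return TrainedSurrogate(
        kind="ann",
        model=net,
        feature_names=list(train.feature_names),
        target_names=list(train.target_names),
        input_mean=mean,
        input_sd=sd,
        training_log=log,
    )


def _thin_rows(train: SampleSet, max_rows: int) -> np.ndarray:
    """Indices of at most ``max_rows`` rows, thinned evenly within each trial."""
    n = train.n_samples
    if n <= max_rows:
        return np.arange(n)
    stride = n / max_rows
    if "trial" in train.provenance.columns:
        keep = []
        for _, group in train.provenance.groupby("trial", sort=True):
            rows = group.index.to_numpy()
            n_keep = max(1, int(round(len(rows) / stride)))
            keep.append(rows[np.linspace(0, len(rows) - 1, n_keep).astype(int)])
        idx = np.unique(np.concatenate(keep))
    else:
        idx = np.linspace(0, n - 1, max_rows).astype(int)
    return idx


def train_svr(
    train: SampleSet,
    cfg: SVRConfig | None = None,
    targets: list | None = None,
) -> TrainedSurrogate:
    """Fit one epsilon-insensitive Gaussian-kernel SVR per target.

    ``targets`` restricts the bank to a subset of target names; the members
    are independent single-output models, so a subset bank is identical to
    the corresponding members of the full bank.
    """
    if cfg is None:
        cfg = SVRConfig()
    if train.n_samples == 0:
        raise TrainingError("training set is empty")
    if not np.all(np.isfinite(train.Y)):
        raise TrainingError("targets must be finite")
    target_names = list(train.target_names) if targets is None else list(targets)
    cols = [train.target_names.index(t) for t in target_names]

    if cfg.standardize_inputs:
        mean, sd = _standardization(train.X)
    else:
        mean = np.zeros(train.X.shape[1])
        sd = np.ones(train.X.shape[1])

    idx = _thin_rows(train, cfg.max_train_rows)
    x = (train.X[idx] - mean) / sd
    models = []
    for col in cols:
        svr = SVR(kernel="rbf", gamma=cfg.gamma, epsilon=cfg.epsilon,
                  C=cfg.box_constraint, tol=cfg.tol)
        svr.fit(x, train.Y[idx, col])
        models.append(svr)

    return TrainedSurrogate(
        kind="svr_bank",
        model=models,
        feature_names=list(train.feature_names),
        target_names=target_names,
        input_mean=mean,
        input_sd=sd,
        training_log=[{"rows_used": int(len(idx))}],
    )


def predict(surrogate: TrainedSurrogate, samples: SampleSet) -> np.ndarray:
    """Row-aligned predictions (BW units) for a sample set.

    Feature names must match the training feature list exactly; rows are
    independent, so permuting input rows permutes predictions identically.
    """
    if list(samples.feature_names) != list(surrogate.feature_names):
        raise ContractError(
            "feature names do not match the surrogate's training features"
        )
    n_targets = len(surrogate.target_names)
    if samples.n_samples == 0:
        return np.empty((0, n_targets))
    x = (samples.X - surrogate.input_mean) / surrogate.input_sd
    if surrogate.kind == "ann":
        out = surrogate.model.predict(x)
        return out.reshape(len(x), n_targets)
    if surrogate.kind == "svr_bank":
        return np.column_stack([m.predict(x) for m in surrogate.model])
    if surrogate.kind == "custom":
        return np.asarray(surrogate.model(samples))
    raise ConfigurationError(f"unknown surrogate kind {surrogate.kind!r}")
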