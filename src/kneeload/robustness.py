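"""Outlier-contamination study: how prediction quality degrades when a
growing share of training samples is replaced by heavy-tailed outliers.

Replacement values are drawn from a Student-t distribution (2 degrees of
freedom by default, so heavy-tailed with infinite variance) scaled per
variable by the standard deviation of the original, uncontaminated training
data.  Only training folds are ever touched; held-out assessment data stay
pristine at every contamination level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .evaluation import make_folds, pearson_r
from .preprocess import FeatureTensor, SampleSet, unfold
from .regression import predict
from .evaluation import _train  # shared trainer dispatch

DEFAULT_PROPORTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass(frozen=True)
class ContaminationSpec:
    """What to corrupt, how much, and with which heavy-tailed law."""

    proportions: tuple = DEFAULT_PROPORTIONS
    df: float = 2.0  # Student-t degrees of freedom
    targets_of_corruption: str = "both"  # "inputs" | "outputs" | "both"
    seed: int = 0

    def __post_init__(self):
        if not all(0 < p < 1 for p in self.proportions):
            raise ConfigurationError("proportions must lie in (0, 1)")
        if self.df <= 0:
            raise ConfigurationError("df must be > 0")
        if self.targets_of_corruption not in ("inputs", "outputs", "both"):
            raise ConfigurationError(
                "targets_of_corruption must be inputs, outputs or both"
            )


def contaminate(
    train: SampleSet, spec: ContaminationSpec, proportion: float
) -> SampleSet:
    """Replace floor(proportion * N) rows with Student-t outliers.

    Each selected row's designated values (inputs, outputs or both) are
    replaced by t(df) draws scaled by the per-variable standard deviation
    of the original training data; unselected rows are bit-identical.
    A zero proportion returns the input unchanged.
    """
    if train.n_samples == 0:
        raise DataError("cannot contaminate an empty training set")
    if proportion == 0:
        return train
    if not 0 < proportion < 1:
        raise ConfigurationError("proportion must lie in [0, 1)")
    rng = np.random.default_rng([spec.seed, int(round(proportion * 1000))])
    n_replace = int(np.floor(proportion * train.n_samples))
    idx = rng.choice(train.n_samples, size=n_replace, replace=False)

    x = train.X.copy()
    y = train.Y.copy()
    if spec.targets_of_corruption in ("inputs", "both"):
        sd = train.X.std(axis=0)
        x[idx] = rng.standard_t(spec.df, size=(n_replace, x.shape[1])) * sd
    if spec.targets_of_corruption in ("outputs", "both"):
        sd = train.Y.std(axis=0)
        y[idx] = rng.standard_t(spec.df, size=(n_replace, y.shape[1])) * sd
    return SampleSet(
        X=x, Y=y,
        feature_names=list(train.feature_names),
        target_names=list(train.target_names),
        provenance=train.provenance.copy(),
    )


def robustness_curve(
    tensor: FeatureTensor,
    model_kind: str,
    scheme: str,
    spec: ContaminationSpec | None = None,
    ann_cfg=None,
    svr_cfg=None,
    k: int = 3,
    seed: int = 0,
    targets: list | None = None,
    include_control: bool = True,
    surrogate_factory=None,
) -> pd.DataFrame:
    """Fold-averaged Pearson R per target at each contamination level.

    For every proportion the training folds are contaminated (per-variable
    scale recomputed from that fold's own uncontaminated data), the model is
    retrained and the pristine held-out fold is scored.  The returned frame
    has one row per level and one column per target; the control row at
    level 0.0 is the uncontaminated experiment.
    """
    if spec is None:
        spec = ContaminationSpec()
    plan = make_folds(tensor, scheme, k=k, seed=seed)
    levels = ((0.0,) if include_control else ()) + tuple(spec.proportions)

    eval_targets = targets or list(tensor.target_names)
    records = {}
    for level in levels:
        r_values = {t: [] for t in eval_targets}
        for fold in range(k):
            train_set = unfold(tensor, plan.train_trials(fold))
            test_set = unfold(tensor, plan.test_trials(fold))
            contaminated = contaminate(train_set, spec, level)
            surrogate = _train(
                model_kind, contaminated, ann_cfg, svr_cfg,
                None if seed is None else seed + fold, surrogate_factory,
                targets,
            )
            yhat = predict(surrogate, test_set)
            for j, target in enumerate(surrogate.target_names):
                if target not in r_values:
                    continue  # multi-output models predict more than we track
                col = test_set.target_names.index(target)
                r_values[target].append(pearson_r(test_set.Y[:, col], yhat[:, j]))
        records[level] = {t: float(np.mean(v)) for t, v in r_values.items() if v}
    frame = pd.DataFrame(records).T
    frame.index.name = "proportion"
    return frame


def fit_trend_slope(curve: pd.DataFrame, target: str) -> float:
    """Least-squares slope of fold-averaged R versus contamination level."""
    levels = curve.index.to_numpy(dtype=float)
    values = curve[target].to_numpy(dtype=float)
    return float(np.polyfit(levels, values, 1)[0])


def plot_robustness(curve: pd.DataFrame, ax=None):
    """Line chart of R against contamination proportion, one line per target."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for target in curve.columns:
        ax.plot(curve.index * 100, curve[target], marker="o", label=target)
    ax.set_xlabel("contaminated training samples (%)")
    ax.set_ylabel("Pearson R (fold average)")
    ax.legend(fontsize=8)
    return ax
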