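"""Cross-validated assessment of the surrogates.

Two three-fold schemes: ``LeaveTrialsOut`` partitions stance slices at
random (a subject's stances can appear on both sides of the split) and
``LeaveSubjectsOut`` partitions subjects, keeping every subject's stances in
a single fold.  Metrics are RMSE in body-weight units, NRMSE as a percent of
each target's range, and Pearson's R; they are pooled over all held-out time
points of a fold, then averaged across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, DataError, DomainError
from .preprocess import FeatureTensor, SampleSet, unfold
from .regression import ANNConfig, SVRConfig, TrainedSurrogate, predict, train_ann, train_svr

SCHEMES = ("LeaveTrialsOut", "LeaveSubjectsOut")

#: Target ranges (BW) printed for the original cohort: med_x, med_y, med_z,
#: lat_y, lat_z.  Usable as a fixed Delta-y preset for NRMSE.
REFERENCE_DELTA_Y = {
    "med_x": 8.069,
    "med_y": 12.164,
    "med_z": 1.389,
    "lat_y": 9.657,
    "lat_z": 0.007,
}


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every tensor trial to one of k folds."""

    scheme: str
    k: int
    assignments: np.ndarray  # (M,) fold index per trial
    seed: int

    def test_trials(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_trials(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(
    tensor: FeatureTensor, scheme: str, k: int = 3, seed: int = 0
) -> FoldPlan:
    """Seeded balanced partition honoring the scheme constraint.

    Fold sizes differ by at most one unit (stances for LeaveTrialsOut,
    subjects for LeaveSubjectsOut); under LeaveSubjectsOut all of a
    subject's stances share one fold.
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    m = tensor.n_trials
    assignments = np.empty(m, dtype=int)
    if scheme == "LeaveTrialsOut":
        if m < k:
            raise DataError(f"need >= {k} trials for {k}-fold LeaveTrialsOut")
        order = rng.permutation(m)
        for fold, chunk in enumerate(np.array_split(order, k)):
            assignments[chunk] = fold
    else:
        subjects = tensor.meta["subject_id"].to_numpy()
        unique = np.unique(subjects)
        if len(unique) < k:
            raise DataError(f"need >= {k} subjects for {k}-fold LeaveSubjectsOut")
        order = rng.permutation(len(unique))
        subject_fold = {}
        for fold, chunk in enumerate(np.array_split(unique[order], k)):
            for sid in chunk:
                subject_fold[sid] = fold
        assignments = np.array([subject_fold[s] for s in subjects])
    return FoldPlan(scheme=scheme, k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root of the mean squared residual."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ContractError("y and yhat must be equal-length and non-empty")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def nrmse(y: np.ndarray, yhat: np.ndarray, delta_y: float) -> float:
    """RMSE as a percentage of the target's range ``delta_y``."""
    if delta_y <= 0:
        raise DomainError("delta_y must be > 0")
    return rmse(y, yhat) / delta_y * 100.0


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Product-moment correlation between target and prediction."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ContractError("y and yhat must be equal-length with >= 2 points")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise DomainError("Pearson R undefined for a zero-variance series")
    return float(np.corrcoef(y, yhat)[0, 1])


# ---------------------------------------------------------------------------
# experiments


@dataclass
class EvalReport:
    """Per-fold and fold-averaged metrics for one model x scheme x input-set
    experiment."""

    model_kind: str
    scheme: str
    use_grf: bool
    delta_y: dict  # target -> range used for NRMSE
    table: pd.DataFrame  # columns: fold, target, rmse, nrmse, r

    def fold_mean(self) -> pd.DataFrame:
        """Metrics averaged over folds, one row per target."""
        return self.table.groupby("target", sort=False)[
            ["rmse", "nrmse", "r"]
        ].mean()

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "scheme": self.scheme,
            "use_grf": self.use_grf,
            "delta_y": self.delta_y,
            "per_fold": self.table.to_dict(orient="records"),
            "fold_mean": self.fold_mean().reset_index().to_dict(orient="records"),
        }


def dataset_ranges(tensor: FeatureTensor) -> dict:
    """Per-target max-min range over the whole dataset (BW)."""
    pooled = np.concatenate(tensor.Y, axis=1)
    return {
        name: float(pooled[i].max() - pooled[i].min())
        for i, name in enumerate(tensor.target_names)
    }


def _resolve_delta_y(tensor: FeatureTensor, delta_y) -> dict:
    if delta_y == "dataset" or delta_y is None:
        return dataset_ranges(tensor)
    if delta_y == "reference":
        return {t: REFERENCE_DELTA_Y[t] for t in tensor.target_names}
    return dict(delta_y)


def _train(kind, samples, ann_cfg, svr_cfg, seed, surrogate_factory, targets=None):
    if surrogate_factory is not None:
        return surrogate_factory(samples)
    if kind == "ann":
        cfg = ann_cfg or ANNConfig()
        if seed is not None:
            from dataclasses import replace

            cfg = replace(cfg, seed=seed)
        return train_ann(samples, cfg)
    if kind == "svr":
        return train_svr(samples, svr_cfg or SVRConfig(), targets=targets)
    raise ConfigurationError(f"unknown model kind {kind!r}")


def run_experiment(
    tensor: FeatureTensor,
    model_kind: str,
    scheme: str,
    use_grf: bool = True,
    ann_cfg: ANNConfig | None = None,
    svr_cfg: SVRConfig | None = None,
    k: int = 3,
    seed: int = 0,
    delta_y="dataset",
    surrogate_factory=None,
    targets: list | None = None,
) -> EvalReport:
    """Train on k-1 folds, assess on the held-out fold, for every fold.

    Metrics are pooled over all held-out time points of a fold.  Under
    LeaveSubjectsOut the train/test subject disjointness is asserted at run
    time.  ``surrogate_factory`` (SampleSet -> TrainedSurrogate) replaces
    the built-in trainers, e.g. to inject an oracle in tests.
    """
    plan = make_folds(tensor, scheme, k=k, seed=seed)
    ranges = _resolve_delta_y(tensor, delta_y)
    rows = []
    for fold in range(k):
        train_set = unfold(tensor, plan.train_trials(fold))
        test_set = unfold(tensor, plan.test_trials(fold))
        if scheme == "LeaveSubjectsOut":
            overlap = set(train_set.provenance["subject_id"]) & set(
                test_set.provenance["subject_id"]
            )
            if overlap:
                raise ContractError(
                    f"subject leakage across the fold boundary: {sorted(overlap)}"
                )
        surrogate = _train(
            model_kind, train_set, ann_cfg, svr_cfg,
            None if seed is None else seed + fold, surrogate_factory, targets,
        )
        yhat = predict(surrogate, test_set)
        eval_targets = surrogate.target_names
        for j, target in enumerate(eval_targets):
            col = test_set.target_names.index(target)
            y = test_set.Y[:, col]
            rows.append(
                {
                    "fold": fold,
                    "target": target,
                    "rmse": rmse(y, yhat[:, j]),
                    "nrmse": nrmse(y, yhat[:, j], ranges[target]),
                    "r": pearson_r(y, yhat[:, j]),
                }
            )
    return EvalReport(
        model_kind=model_kind,
        scheme=scheme,
        use_grf=use_grf,
        delta_y={t: ranges[t] for t in (targets or tensor.target_names)},
        table=pd.DataFrame(rows),
    )


def render_results_table(reports: list[EvalReport], metric: str = "nrmse") -> pd.DataFrame:
    """Pivot fold-averaged metrics into a scheme-blocked model x target table."""
    frames = []
    for report in reports:
        mean = report.fold_mean()[metric]
        frames.append(
            pd.DataFrame(
                {
                    "scheme": report.scheme,
                    "model": report.model_kind,
                    "inputs": "GRF" if report.use_grf else "noGRF",
                    **{t: [mean[t]] for t in mean.index},
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
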