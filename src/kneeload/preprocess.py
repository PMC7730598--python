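"""Data conditioning: filtering, stance segmentation, body-weight
normalization, left-leg mirroring, variance filtering and tensor assembly.

The chain turns raw per-leg recordings plus their ground-truth contact
forces into ragged 3-D tensors (variables x trials x time) where a "trial"
is one stance phase, and finally into flat per-time-point sample matrices
for regression.  Gait cycles are deliberately not aligned in time: every
time sample is an independent regression observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, ContractError, DataError, DomainError
from .msk import KCFSeries, PlanarLimbModel, compute_kcf, default_model
from .synthetic import ANGLE_CHANNELS, G, GRF_CHANNELS, GaitTrial

#: z-channels negated when mirroring a left-side trial.
_GRF_Z_ROW = GRF_CHANNELS.index("grf_z")
_KCF_Z_ROWS = (KCFSeries.CHANNELS.index("med_z"), KCFSeries.CHANNELS.index("lat_z"))


def lowpass(series: np.ndarray, cutoff_hz: float, rate: float,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis.

    Raises ``ConfigurationError`` if the cutoff reaches the Nyquist rate.
    """
    if cutoff_hz >= rate / 2:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({rate / 2} Hz)"
        )
    if cutoff_hz <= 0:
        raise ConfigurationError("cutoff must be positive")
    b, a = butter(order, cutoff_hz, fs=rate)
    return filtfilt(b, a, np.asarray(series, dtype=float), axis=-1)


def downsample_grf(trial: GaitTrial, cutoff_hz: float = 6.0) -> np.ndarray:
    """Low-pass the GRFs and keep every k-th sample on the angle grid."""
    ratio = trial.grf_rate / trial.angle_rate
    k = round(ratio)
    if abs(ratio - k) > 1e-9:
        raise ContractError("grf_rate must be an integer multiple of angle_rate")
    filtered = lowpass(trial.grf, cutoff_hz, trial.grf_rate) if cutoff_hz else trial.grf
    out = filtered[:, ::k]
    return out[:, : trial.angles.shape[1]]


def normalize_bw(forces_n: np.ndarray, mass_kg: float) -> np.ndarray:
    """Convert Newtons to body-weight units (divide by mass * g)."""
    if mass_kg <= 0:
        raise DomainError("mass must be strictly positive")
    return np.asarray(forces_n, dtype=float) / (mass_kg * G)


@dataclass
class ProcessedTrial:
    """One conditioned recording: filtered angles plus BW-normalized forces
    on the common angle-rate grid.  ``mirrored`` tracks whether the left-leg
    z negation has been applied, preventing double processing."""

    subject_id: str
    side: str
    speed: float
    mass: float
    rate: float
    angles: np.ndarray  # (13, T) degrees, filtered
    grf: np.ndarray  # (3, T) BW
    kcf: np.ndarray  # (6, T) BW
    mirrored: bool = False


def mirror_left(trial: ProcessedTrial) -> ProcessedTrial:
    """Negate the mediolateral (z) force channels of a left-side trial.

    Angles and the x/y force channels are untouched.  Applying it to a
    right-side or already-mirrored trial violates the contract.
    """
    if trial.side != "left":
        raise ContractError("mirror_left applies to left-side trials only")
    if trial.mirrored:
        raise ContractError("trial is already mirrored")
    grf = trial.grf.copy()
    grf[_GRF_Z_ROW] *= -1.0
    kcf = trial.kcf.copy()
    for row in _KCF_Z_ROWS:
        kcf[row] *= -1.0
    # lat_x is identically zero, negation is a no-op there by construction
    return replace(trial, grf=grf, kcf=kcf, mirrored=True)


def preprocess_trial(
    trial: GaitTrial,
    kcf: KCFSeries,
    cutoff_hz: float = 6.0,
    mirror: bool = True,
) -> ProcessedTrial:
    """Condition one raw trial: filter, downsample, BW-normalize, mirror."""
    if isinstance(trial, ProcessedTrial):
        raise ContractError("trial is already preprocessed")
    if kcf.subject_id != trial.subject.subject_id or kcf.side != trial.side:
        raise ContractError("KCF series does not belong to this trial")
    angles = lowpass(trial.angles, cutoff_hz, trial.angle_rate)
    grf = normalize_bw(downsample_grf(trial, cutoff_hz), trial.subject.mass)
    out = ProcessedTrial(
        subject_id=trial.subject.subject_id,
        side=trial.side,
        speed=trial.speed,
        mass=trial.subject.mass,
        rate=trial.angle_rate,
        angles=angles,
        grf=grf,
        kcf=kcf.data.copy(),
    )
    if mirror and trial.side == "left":
        out = mirror_left(out)
    return out


@dataclass(frozen=True)
class StanceInterval:
    """Half-open [start, end) index range of one stance phase on the
    angle-rate grid."""

    trial: ProcessedTrial
    start_index: int
    end_index: int
    side: str

    def __post_init__(self):
        if self.end_index <= self.start_index:
            raise ConfigurationError("end_index must exceed start_index")

    @property
    def length(self) -> int:
        return self.end_index - self.start_index


def detect_stance(
    trial: ProcessedTrial,
    threshold_bw: float = 0.05,
    min_duration_s: float = 0.02,
) -> list[StanceInterval]:
    """Threshold the vertical GRF to find complete stance phases.

    Heel-strike is the upward crossing of ``threshold_bw`` body weights,
    toe-off the downward crossing.  Above- and below-threshold runs shorter
    than ``min_duration_s`` are treated as chatter (hysteresis); intervals
    clipped by the record edges are discarded so every returned interval is
    a complete stance.
    """
    vertical = trial.grf[1]
    above = vertical > threshold_bw
    min_len = max(1, int(round(min_duration_s * trial.rate)))

    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]

    # hysteresis: close short gaps between consecutive stance runs
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_len:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    intervals = []
    for s, e in merged:
        if e - s < min_len:
            continue
        if s == 0 or e == len(vertical):
            continue  # incomplete stance at a record boundary
        intervals.append(
            StanceInterval(trial=trial, start_index=int(s), end_index=int(e),
                           side=trial.side)
        )
    return intervals


# ---------------------------------------------------------------------------
# tensors and sample sets


@dataclass
class FeatureTensor:
    """Ragged (variables x trials x time) container for inputs and targets.

    ``X[m]`` is (Nx, T_m) and ``Y[m]`` is (Ny, T_m) for stance m; lengths
    differ across stances and no temporal alignment is performed.  ``meta``
    carries one row of provenance per stance.
    """

    X: list  # of (Nx, T_m) arrays
    Y: list  # of (Ny, T_m) arrays
    feature_names: list
    target_names: list
    meta: pd.DataFrame  # columns: subject_id, side, speed

    @property
    def n_trials(self) -> int:
        return len(self.X)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([x.shape[1] for x in self.X])

    def subset(self, trial_indices) -> "FeatureTensor":
        idx = list(trial_indices)
        return FeatureTensor(
            X=[self.X[i] for i in idx],
            Y=[self.Y[i] for i in idx],
            feature_names=list(self.feature_names),
            target_names=list(self.target_names),
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )


def assemble(
    trials: list[ProcessedTrial],
    stance_lists: list,
    use_grf: bool = True,
) -> FeatureTensor:
    """Build the ragged tensors, one slice per stance interval.

    Inputs are the 13 angle channels, plus the 3 GRF channels when
    ``use_grf``; targets are all 6 contact-force channels (the variance
    filter decides afterwards which survive).
    """
    if len(trials) != len(stance_lists):
        raise ContractError("one stance list per trial is required")
    feature_names = list(ANGLE_CHANNELS) + (list(GRF_CHANNELS) if use_grf else [])
    target_names = list(KCFSeries.CHANNELS)
    xs, ys, meta_rows = [], [], []
    for trial, intervals in zip(trials, stance_lists):
        for interval in intervals:
            sl = slice(interval.start_index, interval.end_index)
            block = trial.angles[:, sl]
            if use_grf:
                block = np.vstack([block, trial.grf[:, sl]])
            xs.append(block)
            ys.append(trial.kcf[:, sl])
            meta_rows.append(
                {"subject_id": trial.subject_id, "side": trial.side,
                 "speed": trial.speed}
            )
    if not xs:
        raise DataError("no stance intervals: cannot assemble tensors")
    return FeatureTensor(
        X=xs, Y=ys, feature_names=feature_names, target_names=target_names,
        meta=pd.DataFrame(meta_rows),
    )


def drop_low_variance(tensor: FeatureTensor, threshold: float = 1e-6):
    """Remove features whose pooled standard deviation falls below threshold.

    The standard deviation is computed per feature over all trials and time
    points (a dataset-level decision); dropped names are reported.  With a
    zero threshold nothing is dropped.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")

    def keep_mask(blocks, names):
        pooled = np.concatenate(blocks, axis=1)
        sd = pooled.std(axis=1)
        keep = sd >= threshold if threshold > 0 else np.ones(len(names), bool)
        return keep, [n for n, k in zip(names, keep) if not k]

    keep_x, dropped_x = keep_mask(tensor.X, tensor.feature_names)
    keep_y, dropped_y = keep_mask(tensor.Y, tensor.target_names)
    if not keep_x.any() or not keep_y.any():
        raise DataError("variance filter removed every feature")
    filtered = FeatureTensor(
        X=[x[keep_x] for x in tensor.X],
        Y=[y[keep_y] for y in tensor.Y],
        feature_names=[n for n, k in zip(tensor.feature_names, keep_x) if k],
        target_names=[n for n, k in zip(tensor.target_names, keep_y) if k],
        meta=tensor.meta.copy(),
    )
    report = {"inputs_dropped": dropped_x, "outputs_dropped": dropped_y}
    return filtered, report


@dataclass
class SampleSet:
    """Flat per-time-point samples with provenance.

    Rows are ordered trial-major, time-minor; ``provenance`` has columns
    trial, subject_id, side, speed, time_index so downstream folds can
    verify subject disjointness.
    """

    X: np.ndarray  # (N, Nx)
    Y: np.ndarray  # (N, Ny)
    feature_names: list
    target_names: list
    provenance: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def unfold(tensor: FeatureTensor, trial_subset=None) -> SampleSet:
    """Linearize tensor slices into an independent-sample matrix."""
    if trial_subset is None:
        trial_subset = range(tensor.n_trials)
    trial_subset = list(trial_subset)
    if not trial_subset:
        raise DataError("trial_subset must be non-empty")
    xs, ys, rows = [], [], []
    for m in trial_subset:
        xs.append(tensor.X[m].T)
        ys.append(tensor.Y[m].T)
        meta = tensor.meta.iloc[m]
        t_m = tensor.X[m].shape[1]
        rows.append(
            pd.DataFrame(
                {
                    "trial": m,
                    "subject_id": meta["subject_id"],
                    "side": meta["side"],
                    "speed": meta["speed"],
                    "time_index": np.arange(t_m),
                }
            )
        )
    return SampleSet(
        X=np.concatenate(xs, axis=0),
        Y=np.concatenate(ys, axis=0),
        feature_names=list(tensor.feature_names),
        target_names=list(tensor.target_names),
        provenance=pd.concat(rows, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# end-to-end helper


def build_tensor(
    trials: list[GaitTrial],
    model: PlanarLimbModel | None = None,
    use_grf: bool = True,
    variance_threshold: float = 1e-6,
    stance_threshold_bw: float = 0.05,
    quasi_static: bool = False,
):
    """Raw trials -> ground truth -> conditioning -> filtered tensors.

    Returns ``(tensor, report)`` where the report lists dropped features.
    """
    if model is None:
        model = default_model()
    processed, stances = [], []
    for trial in trials:
        kcf = compute_kcf(trial, model, quasi_static=quasi_static)
        pt = preprocess_trial(trial, kcf)
        processed.append(pt)
        stances.append(detect_stance(pt, threshold_bw=stance_threshold_bw))
    tensor = assemble(processed, stances, use_grf=use_grf)
    return drop_low_variance(tensor, variance_threshold)
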