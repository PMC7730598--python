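"""Stance-cycle summaries: time-normalized ensemble curves with percentile
bands, and first/second peak tables of the vertical contact-force
components by walking speed.

Each stance is resampled to 100 phase points by quadratic interpolation;
averaging is two-stage (within subject first, then across subjects) and the
5-95% band is taken across all contributing cycles.  Peaks are searched in
the early-stance half ([0%, 50%) of stance) and late-stance half
([50%, 100%]) separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from .errors import DataError


def time_normalize(cycle_series: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Resample a stance-phase series onto a uniform 100-point phase grid.

    Quadratic (second-order) interpolation; reproduces polynomials of degree
    <= 2 exactly and returns the input unchanged when it is already a
    uniform ``n_points`` grid.
    """
    y = np.asarray(cycle_series, dtype=float)
    if y.shape[-1] < 3:
        raise DataError("a cycle needs at least 3 samples to resample")
    phase = np.linspace(0.0, 1.0, y.shape[-1])
    grid = np.linspace(0.0, 1.0, n_points)
    return interp1d(phase, y, kind="quadratic", axis=-1)(grid)


@dataclass
class Cycle:
    """One time-normalized stance of one target variable."""

    subject_id: str
    speed: float
    target: str
    curve: np.ndarray  # (n_points,)


@dataclass
class EnsembleCurve:
    """Mean and 5-95% percentile band over time-normalized cycles."""

    target: str
    speed: float
    mean: np.ndarray  # (n_points,)
    p05: np.ndarray
    p95: np.ndarray
    n_cycles: int


def ensemble(cycles: list, speed: float, target: str) -> EnsembleCurve:
    """Average cycles within each subject first, then across subjects.

    Percentile bands are computed across all individual cycles (the spread
    of trials, not of subject means).
    """
    selected = [c for c in cycles if c.speed == speed and c.target == target]
    if not selected:
        raise DataError(f"no cycles for target {target!r} at {speed} km/h")
    stack = np.vstack([c.curve for c in selected])
    by_subject = {}
    for c in selected:
        by_subject.setdefault(c.subject_id, []).append(c.curve)
    subject_means = np.vstack([np.mean(v, axis=0) for v in by_subject.values()])
    return EnsembleCurve(
        target=target,
        speed=speed,
        mean=subject_means.mean(axis=0),
        p05=np.percentile(stack, 5, axis=0),
        p95=np.percentile(stack, 95, axis=0),
        n_cycles=len(selected),
    )


def find_peaks(curve: np.ndarray) -> tuple[float, float]:
    """(first, second) peak of a 100-point stance curve.

    First peak is the maximum over early stance ([0%, 50%) of the phase
    grid), second over late stance ([50%, 100%]).
    """
    curve = np.asarray(curve, dtype=float)
    half = curve.shape[0] // 2
    return float(curve[:half].max()), float(curve[half:].max())


def peak_table(cycles: list, targets=("med_y", "lat_y")) -> pd.DataFrame:
    """Mean (sd) of first/second peaks per speed and target.

    Cell means are two-stage (mean peak within subject, then across
    subjects); the standard deviation is taken across all individual cycle
    peaks.  Speeds without cycles are omitted with a warning.
    """
    speeds = sorted({c.speed for c in cycles})
    rows = []
    for speed in speeds:
        row = {"speed": speed}
        for target in targets:
            selected = [c for c in cycles if c.speed == speed and c.target == target]
            if not selected:
                warnings.warn(f"no {target} cycles at {speed} km/h; row omitted")
                continue
            peaks = np.array([find_peaks(c.curve) for c in selected])  # (n, 2)
            by_subject = {}
            for c, pk in zip(selected, peaks):
                by_subject.setdefault(c.subject_id, []).append(pk)
            subj_means = np.vstack([np.mean(v, axis=0) for v in by_subject.values()])
            for i, which in enumerate(("peak1", "peak2")):
                row[f"{target}_{which}_mean"] = float(subj_means[:, i].mean())
                row[f"{target}_{which}_sd"] = float(peaks[:, i].std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("speed")


def collect_cycles(
    processed_trials: list,
    stance_lists: list,
    targets=("med_x", "med_y", "med_z", "lat_y", "lat_z"),
    n_points: int = 100,
) -> list:
    """Time-normalized stance cycles of the contact-force channels."""
    from .msk import KCFSeries

    cycles = []
    for trial, intervals in zip(processed_trials, stance_lists):
        for interval in intervals:
            sl = slice(interval.start_index, interval.end_index)
            for target in targets:
                row = KCFSeries.CHANNELS.index(target)
                series = trial.kcf[row, sl]
                if series.shape[0] < 3:
                    continue
                cycles.append(
                    Cycle(
                        subject_id=trial.subject_id,
                        speed=trial.speed,
                        target=target,
                        curve=time_normalize(series, n_points),
                    )
                )
    return cycles
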