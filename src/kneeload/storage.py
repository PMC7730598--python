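"""Tab-delimited motion-storage I/O and cohort on-disk layout.

The dialect is the plain-text time-series format common in the mocap
ecosystem: a short header (``name`` line, ``nRows=``, ``nColumns=``,
``inDegrees=``, terminated by ``endheader``), then a tab-separated column
header starting with ``time``, then fixed-precision numeric rows.  Files
written here round-trip bit-exactly through the reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .msk import KCFSeries
from .synthetic import ANGLE_CHANNELS, GRF_CHANNELS, GaitTrial, SubjectProfile

_FLOAT_FMT = "%.8f"


def write_motion(
    path, name: str, time: np.ndarray, columns: dict, in_degrees: bool
) -> Path:
    """Write labelled series as motion-storage text; first column is time."""
    path = Path(path)
    names = list(columns)
    data = np.column_stack([np.asarray(time, float)] + [np.asarray(columns[n], float) for n in names])
    lines = [
        name,
        f"nRows={data.shape[0]}",
        f"nColumns={data.shape[1]}",
        f"inDegrees={'yes' if in_degrees else 'no'}",
        "endheader",
        "\t".join(["time"] + names),
    ]
    for row in data:
        lines.append("\t".join(_FLOAT_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_motion(path):
    """Parse a motion-storage file.

    Returns ``(name, frame, in_degrees)`` where ``frame`` is a DataFrame
    whose first column is ``time``.  Malformed headers, row-count or
    column-count mismatches, ragged rows, non-monotone time and empty data
    sections raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header = {}
    name = None
    body_start = None
    for i, line in enumerate(lines):
        if i == 0:
            name = line.strip()
            continue
        if line.strip() == "endheader":
            body_start = i + 1
            break
        if "=" not in line:
            raise FormatError(f"{path.name}:{i + 1}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        header[key.strip()] = value.strip()
    if body_start is None:
        raise FormatError(f"{path.name}: missing endheader")
    for key in ("nRows", "nColumns"):
        if key not in header:
            raise FormatError(f"{path.name}: header lacks {key}")
    n_rows, n_cols = int(header["nRows"]), int(header["nColumns"])
    in_degrees = header.get("inDegrees", "no") == "yes"

    if body_start >= len(lines):
        raise FormatError(f"{path.name}: empty data section")
    col_names = lines[body_start].split("\t")
    if col_names[0] != "time":
        raise FormatError(
            f"{path.name}:{body_start + 1}: first column must be 'time'"
        )
    if len(col_names) != n_cols:
        raise FormatError(
            f"{path.name}:{body_start + 1}: {len(col_names)} columns, "
            f"header declares {n_cols}"
        )
    data_lines = [l for l in lines[body_start + 1:] if l.strip()]
    if not data_lines:
        raise FormatError(f"{path.name}: empty data section")
    if len(data_lines) != n_rows:
        raise FormatError(
            f"{path.name}: {len(data_lines)} data rows, header declares {n_rows}"
        )
    rows = []
    for j, line in enumerate(data_lines):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise FormatError(
                f"{path.name}:{body_start + 2 + j}: ragged row "
                f"({len(parts)} values, expected {n_cols})"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path.name}:{body_start + 2 + j}: {exc}") from None
    frame = pd.DataFrame(rows, columns=col_names)
    t = frame["time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path.name}: time column is not strictly increasing")
    return name, frame, in_degrees


# ---------------------------------------------------------------------------
# trial and cohort layout


def _trial_stem(trial: GaitTrial) -> str:
    return f"{trial.subject.subject_id}_{trial.side}_{trial.speed:g}kmh"


def write_trial(trial: GaitTrial, directory) -> dict:
    """One angles file and one GRF file per trial; returns their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = _trial_stem(trial)
    angle_path = write_motion(
        directory / f"{stem}_angles.mot",
        f"{stem} joint angles",
        trial.angle_time,
        {name: trial.angles[i] for i, name in enumerate(ANGLE_CHANNELS)},
        in_degrees=True,
    )
    grf_path = write_motion(
        directory / f"{stem}_grf.mot",
        f"{stem} ground reaction forces",
        trial.grf_time,
        {name: trial.grf[i] for i, name in enumerate(GRF_CHANNELS)},
        in_degrees=False,
    )
    return {"angles": angle_path, "grf": grf_path}


def write_kcf(series: KCFSeries, path) -> Path:
    """Contact-force series as motion-storage text (BW units)."""
    return write_motion(
        path,
        f"{series.subject_id} {series.side} {series.speed:g}kmh knee contact forces (BW)",
        series.time,
        {name: series.data[i] for i, name in enumerate(KCFSeries.CHANNELS)},
        in_degrees=False,
    )


def write_cohort(trials: list, directory) -> Path:
    """Write all trial files plus a manifest CSV describing the cohort."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        paths = write_trial(trial, directory)
        p = trial.subject
        rows.append(
            {
                "subject_id": p.subject_id,
                "side": trial.side,
                "speed": trial.speed,
                "mass": p.mass,
                "height": p.height,
                "age_group": p.age_group,
                "max_speed": p.max_speed,
                "shod": p.shod,
                "subject_seed": p.seed,
                "angle_rate": trial.angle_rate,
                "grf_rate": trial.grf_rate,
                "angles_file": paths["angles"].name,
                "grf_file": paths["grf"].name,
            }
        )
    manifest = directory / "cohort_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(directory) -> list:
    """Rebuild GaitTrial objects from a cohort directory written above."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "cohort_manifest.csv")
    profiles = {}
    trials = []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        if sid not in profiles:
            profiles[sid] = SubjectProfile(
                subject_id=sid,
                age_group=row["age_group"],
                mass=float(row["mass"]),
                height=float(row["height"]),
                max_speed=int(row["max_speed"]),
                shod=row["shod"],
                seed=int(row["subject_seed"]),
            )
        _, angle_frame, _ = read_motion(directory / row["angles_file"])
        _, grf_frame, _ = read_motion(directory / row["grf_file"])
        trials.append(
            GaitTrial(
                subject=profiles[sid],
                side=row["side"],
                speed=float(row["speed"]),
                angle_rate=float(row["angle_rate"]),
                angles=angle_frame[list(ANGLE_CHANNELS)].to_numpy().T,
                grf_rate=float(row["grf_rate"]),
                grf=grf_frame[list(GRF_CHANNELS)].to_numpy().T,
            )
        )
    return trials
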