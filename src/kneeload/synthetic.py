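"""Synthetic treadmill-walking cohort generator.

Emulates the statistical structure of a multi-speed treadmill gait protocol:
each subject walks at 3-7 km/h in 1 km/h increments up to a subject-specific
maximum speed, with ~10 s of continuous recording per speed.  Joint angles
(13 channels, degrees, 100 Hz) are band-limited Fourier series in gait-cycle
phase with subject-specific coefficient perturbations; ground reaction forces
(3 channels, Newtons, 1000 Hz) have the classic double-hump vertical stance
profile whose peaks grow with speed, a braking/propulsion anteroposterior
wave and a small mediolateral component.  Left legs are generated in a
left-handed mediolateral sign convention, so downstream mirroring of the
z-channels is genuinely required.

Everything is deterministic given the configured seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError

G = 9.81  # m/s^2, used for body-weight conversion throughout the package

#: Fixed order of the 13 angle channels (degrees).
ANGLE_CHANNELS = (
    "lumbar_extension",
    "lumbar_bending",
    "lumbar_rotation",
    "pelvis_tilt",
    "pelvis_list",
    "pelvis_rotation",
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "patella_flexion",
    "ankle_flexion",
    "subtalar_eversion",
)

#: Fixed order of the 3 ground-reaction-force channels (Newtons).
GRF_CHANNELS = ("grf_x", "grf_y", "grf_z")

_MAX_SPEED_VALUES = (4, 5, 6, 7)
#: Empirical proportions of subjects stopping at 4, 5, 6 and 7 km/h
#: (counts 4, 13, 31, 5; normalized to sum to one).
MAX_SPEED_PROPORTIONS = tuple(c / 53 for c in (4, 13, 31, 5))

_SHOD_VALUES = ("barefoot", "both", "shod")
# reported counts 20 / 11 / 25, normalized to sum to one
_SHOD_PROPORTIONS = (20 / 56, 11 / 56, 25 / 56)

_YOUNG_FRACTION = 40 / 54


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and protocol metadata for one synthetic subject."""

    subject_id: str
    age_group: str  # "young" | "elderly"
    mass: float  # kg
    height: float  # m
    max_speed: int  # km/h, highest speed the subject completed
    shod: str  # "barefoot" | "shod" | "both"
    seed: int

    def __post_init__(self):
        if self.mass <= 0 or self.height <= 0:
            raise ConfigurationError("mass and height must be strictly positive")
        if not 4 <= self.max_speed <= 7:
            raise ConfigurationError("max_speed must lie in {4,5,6,7} km/h")
        if self.age_group not in ("young", "elderly"):
            raise ConfigurationError(f"unknown age_group {self.age_group!r}")
        if self.shod not in _SHOD_VALUES:
            raise ConfigurationError(f"unknown shod condition {self.shod!r}")

    @property
    def body_weight(self) -> float:
        """Body weight in Newtons."""
        return self.mass * G


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the emulated protocol: the full 3-7 km/h speed grid,
    10 s of recording per speed, 100 Hz angles and 1000 Hz forces, and
    small additive measurement noise (0.5 deg on angles, 5 N on forces).
    """

    n_subjects: int = 20
    speed_grid: tuple = (3, 4, 5, 6, 7)
    seconds_per_speed: float = 10.0
    noise_sd_angles: float = 0.5  # degrees
    noise_sd_grf: float = 5.0  # Newtons
    master_seed: int = 0
    angle_rate: float = 100.0  # Hz
    grf_rate: float = 1000.0  # Hz
    sides: tuple = ("right", "left")

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not set(self.speed_grid) <= {3, 4, 5, 6, 7}:
            raise ConfigurationError("speed_grid must be a subset of {3,...,7} km/h")
        if self.seconds_per_speed <= 0:
            raise ConfigurationError("seconds_per_speed must be positive")
        if self.noise_sd_angles < 0 or self.noise_sd_grf < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        ratio = self.grf_rate / self.angle_rate
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ConfigurationError("angle_rate must divide grf_rate exactly")
        if any(s not in ("left", "right") for s in self.sides):
            raise ConfigurationError("sides must be drawn from {'left','right'}")


@dataclass
class GaitTrial:
    """One leg x speed x subject continuous recording."""

    subject: SubjectProfile
    side: str
    speed: float  # km/h
    angle_rate: float  # Hz
    angles: np.ndarray  # (13, T) degrees
    grf_rate: float  # Hz
    grf: np.ndarray  # (3, k*T) Newtons

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"unknown side {self.side!r}")
        if self.angles.shape[0] != len(ANGLE_CHANNELS):
            raise ConfigurationError("angles must have 13 channels")
        if self.grf.shape[0] != len(GRF_CHANNELS):
            raise ConfigurationError("grf must have 3 channels")
        ratio = self.grf_rate / self.angle_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError("angle_rate must divide grf_rate exactly")

    @property
    def angle_time(self) -> np.ndarray:
        return np.arange(self.angles.shape[1]) / self.angle_rate

    @property
    def grf_time(self) -> np.ndarray:
        return np.arange(self.grf.shape[1]) / self.grf_rate

    def angle(self, name: str) -> np.ndarray:
        return self.angles[ANGLE_CHANNELS.index(name)]


def make_cohort(cfg: CohortConfig) -> list[SubjectProfile]:
    """Draw ``cfg.n_subjects`` subject profiles.

    Maximum walking speed is sampled from the empirical stopping proportions
    (4, 13, 31, 5)/54 at 4-7 km/h; age group, shod condition and
    anthropometrics follow the emulated cohort's composition.
    """
    rng = np.random.default_rng(cfg.master_seed)
    profiles = []
    for i in range(cfg.n_subjects):
        age_group = "young" if rng.random() < _YOUNG_FRACTION else "elderly"
        mass = float(np.clip(rng.normal(72.0 if age_group == "young" else 70.0, 9.0), 48, 105))
        height = float(np.clip(rng.normal(1.72, 0.07), 1.50, 1.95))
        max_speed = int(rng.choice(_MAX_SPEED_VALUES, p=MAX_SPEED_PROPORTIONS))
        shod = str(rng.choice(_SHOD_VALUES, p=_SHOD_PROPORTIONS))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:03d}",
                age_group=age_group,
                mass=mass,
                height=height,
                max_speed=max_speed,
                shod=shod,
                seed=int(rng.integers(2**31)),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# waveform machinery

# Base Fourier templates per angle channel: (offset deg, [(harmonic, amp deg,
# phase rad), ...]).  Magnitudes are plausible sagittal-gait values; channels
# that drive the planar ground-truth model (pelvis tilt, hip/knee/ankle
# flexion) carry the realistic shapes, the remaining channels are small
# periodic signals that merely provide variance.
_ANGLE_TEMPLATES = {
    "lumbar_extension": (-8.0, [(1, 1.5, 0.3), (2, 1.0, 1.1)]),
    "lumbar_bending": (0.0, [(1, 2.5, 2.0), (2, 0.8, 0.4)]),
    "lumbar_rotation": (0.0, [(1, 3.0, -1.2), (2, 1.0, 0.9)]),
    "pelvis_tilt": (8.0, [(2, 1.8, 0.6), (1, 1.0, -0.5)]),
    "pelvis_list": (0.0, [(1, 3.5, 1.4), (2, 1.2, -0.8)]),
    "pelvis_rotation": (0.0, [(1, 5.0, -0.3), (3, 0.8, 0.2)]),
    "hip_flexion": (8.0, [(1, 20.0, 0.0), (2, 3.5, 1.8), (3, 1.2, -0.6)]),
    "hip_adduction": (1.0, [(1, 4.5, 2.6), (2, 2.0, 0.8)]),
    "hip_rotation": (-2.0, [(1, 4.0, -2.0), (2, 1.5, 1.3)]),
    "knee_flexion": (25.0, [(1, 22.0, -4.52), (2, 10.0, -1.9), (3, 4.0, 0.5)]),
    "patella_flexion": (20.0, [(1, 17.0, -4.52), (2, 8.0, -1.9), (3, 3.0, 0.5)]),
    "ankle_flexion": (0.0, [(1, 8.0, -2.5), (2, 5.0, 0.9), (3, 2.0, -0.2)]),
    "subtalar_eversion": (-1.0, [(1, 3.0, 1.0), (2, 1.5, -1.4)]),
}

# Channels whose amplitudes scale with walking speed.
_SPEED_SCALED = {
    "hip_flexion",
    "knee_flexion",
    "patella_flexion",
    "ankle_flexion",
    "pelvis_rotation",
    "pelvis_list",
    "hip_adduction",
}


@dataclass(frozen=True)
class _SubjectStyle:
    """Subject-level waveform coefficients, constant across speeds and sides."""

    cadence_factor: float
    stance_offset: float
    grf_peak_offset: float
    grf_shape_q: float
    grf_asym: float
    grf_ml_factor: float
    amp_factors: np.ndarray  # (13,)
    offset_shifts: np.ndarray  # (13,) degrees
    phase_shifts: np.ndarray  # (13,) radians


def _subject_style(profile: SubjectProfile) -> _SubjectStyle:
    rng = np.random.default_rng([profile.seed, 11])
    n = len(ANGLE_CHANNELS)
    return _SubjectStyle(
        cadence_factor=float(np.clip(1.0 + 0.04 * rng.standard_normal(), 0.88, 1.12)),
        stance_offset=float(np.clip(0.01 * rng.standard_normal(), -0.025, 0.025)),
        grf_peak_offset=float(np.clip(0.02 * rng.standard_normal(), -0.05, 0.05)),
        grf_shape_q=float(np.clip(0.25 + 0.03 * rng.standard_normal(), 0.15, 0.35)),
        grf_asym=float(np.clip(0.05 + 0.02 * rng.standard_normal(), 0.0, 0.12)),
        grf_ml_factor=float(np.clip(1.0 + 0.12 * rng.standard_normal(), 0.7, 1.3)),
        amp_factors=np.clip(1.0 + 0.10 * rng.standard_normal(n), 0.75, 1.25),
        offset_shifts=2.0 * rng.standard_normal(n),
        phase_shifts=0.08 * rng.standard_normal(n),
    )


def cadence_spm(profile: SubjectProfile, speed: float) -> float:
    """Cadence in steps/min: 70 + 10*speed, scaled by a subject factor."""
    return (70.0 + 10.0 * speed) * _subject_style(profile).cadence_factor


def stance_fraction(profile: SubjectProfile, speed: float) -> float:
    """Stance fraction of the gait cycle, clipped to [0.55, 0.70]."""
    frac = 0.68 - 0.02 * (speed - 3.0) + _subject_style(profile).stance_offset
    return float(np.clip(frac, 0.55, 0.70))


def _shod_condition(profile: SubjectProfile, speed: float) -> str:
    if profile.shod == "both":
        # alternate footwear between consecutive speeds
        return "shod" if int(round(speed)) % 2 == 0 else "barefoot"
    return profile.shod


def _stance_phase(t: np.ndarray, cycle_hz: float, phase0: float, frac: float):
    """Return (in_stance bool array, u in [0,1) progression within stance)."""
    phase = (cycle_hz * t + phase0) % 1.0
    in_stance = phase < frac
    u = np.where(in_stance, phase / frac, 0.0)
    return in_stance, u


def _vertical_profile(u: np.ndarray, q: float, asym: float) -> np.ndarray:
    """Unit-normalized double-hump stance shape on u in [0,1]."""
    shape = np.sin(np.pi * u) + q * np.sin(3 * np.pi * u) + asym * np.sin(2 * np.pi * u)
    u_dense = np.linspace(0, 1, 2001)
    peak = np.max(
        np.sin(np.pi * u_dense) + q * np.sin(3 * np.pi * u_dense) + asym * np.sin(2 * np.pi * u_dense)
    )
    return shape / peak


def synthesize_trial(
    profile: SubjectProfile, side: str, speed: float, cfg: CohortConfig
) -> GaitTrial:
    """Generate one continuous multi-cycle recording for a leg at one speed.

    Raises
    ------
    DomainError
        If ``speed`` exceeds the subject's maximum walking speed.
    """
    if speed > profile.max_speed:
        raise DomainError(
            f"{profile.subject_id} stopped at {profile.max_speed} km/h; "
            f"cannot synthesize {speed} km/h"
        )
    if side not in ("left", "right"):
        raise ConfigurationError(f"unknown side {side!r}")

    style = _subject_style(profile)
    cyc_hz = cadence_spm(profile, speed) / 120.0  # one gait cycle = two steps
    frac = stance_fraction(profile, speed)
    phase0 = 0.65 if side == "right" else 0.15
    bw = profile.body_weight
    shod_factor = 0.97 if _shod_condition(profile, speed) == "shod" else 1.0
    z_sign = 1.0 if side == "right" else -1.0  # left leg in left-handed z convention

    side_code = 0 if side == "right" else 1
    noise_rng = np.random.default_rng([profile.seed, side_code, int(round(speed * 10)), 7])

    # ---- angles at angle_rate -------------------------------------------
    n_ang = int(round(cfg.seconds_per_speed * cfg.angle_rate))
    t_ang = np.arange(n_ang) / cfg.angle_rate
    phi = cyc_hz * t_ang + phase0
    angles = np.empty((len(ANGLE_CHANNELS), n_ang))
    for c, name in enumerate(ANGLE_CHANNELS):
        offset, harmonics = _ANGLE_TEMPLATES[name]
        speed_factor = 1.0 + (0.06 * (speed - 5.0) if name in _SPEED_SCALED else 0.0)
        wave = np.full(n_ang, offset + style.offset_shifts[c] * 0.3)
        for k, amp, ph in harmonics:
            wave += (
                amp
                * style.amp_factors[c]
                * speed_factor
                * shod_factor
                * np.cos(2 * np.pi * k * phi + ph + style.phase_shifts[c])
            )
        angles[c] = wave
    if cfg.noise_sd_angles > 0:
        angles += noise_rng.normal(0.0, cfg.noise_sd_angles, angles.shape)

    # ---- ground reaction forces at grf_rate ------------------------------
    n_grf = int(round(cfg.seconds_per_speed * cfg.grf_rate))
    t_grf = np.arange(n_grf) / cfg.grf_rate
    in_stance, u = _stance_phase(t_grf, cyc_hz, phase0, frac)

    peak_bw = float(np.clip(1.02 + 0.09 * (speed - 3.0) + style.grf_peak_offset, 1.01, 1.45))
    shape_v = _vertical_profile(u, style.grf_shape_q, style.grf_asym)
    fy = bw * peak_bw * shape_v
    fx = -0.18 * bw * (1.0 + 0.03 * (speed - 5.0)) * np.sin(2 * np.pi * u) * np.sin(np.pi * u)
    # mediolateral load tracks the vertical double hump (medially directed for
    # the right leg), so the adduction moment peaks with the compressive load
    fz = z_sign * 0.08 * bw * peak_bw * style.grf_ml_factor * (
        0.75 * shape_v + 0.25 * np.sin(np.pi * u)
    )
    grf = np.vstack([fx, fy, fz])
    grf[:, ~in_stance] = 0.0
    if cfg.noise_sd_grf > 0:
        # measurement noise applies while the foot loads the plate; the
        # unloaded plate is exactly zero so swing stays force-free
        noise = noise_rng.normal(0.0, cfg.noise_sd_grf, grf.shape)
        grf[:, in_stance] += noise[:, in_stance]
    grf[1] = np.maximum(grf[1], 0.0)  # a force plate cannot pull down

    return GaitTrial(
        subject=profile,
        side=side,
        speed=float(speed),
        angle_rate=cfg.angle_rate,
        angles=angles,
        grf_rate=cfg.grf_rate,
        grf=grf,
    )


def synthesize_cohort_trials(
    profiles: list[SubjectProfile], cfg: CohortConfig
) -> list[GaitTrial]:
    """All trials of a cohort: every subject x side x attainable speed."""
    trials = []
    for profile in profiles:
        for speed in cfg.speed_grid:
            if speed > profile.max_speed:
                continue
            for side in cfg.sides:
                trials.append(synthesize_trial(profile, side, speed, cfg))
    return trials


def attach_ground_truth(trial: GaitTrial, model=None):
    """Compute the trial's knee-contact-force ground truth.

    Delegates to :func:`kneeload.msk.compute_kcf`; by construction of the
    planar contact split the lateral anteroposterior channel is constant,
    so the downstream variance filter removes it.
    """
    from .msk import compute_kcf, default_model

    if model is None:
        model = default_model()
    return compute_kcf(trial, model)
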