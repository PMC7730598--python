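"""Planar musculoskeletal ground truth: knee net moments -> static
optimization of muscle activations -> joint reaction -> medial/lateral split.

The model is a documented planar (sagittal) reduction of a full lower-limb
musculoskeletal analysis.  Foot and shank are rigid segments with
Dempster-style anthropometric fractions; three lumped knee-spanning muscle
groups (quadriceps, hamstrings, gastrocnemius) with constant sagittal moment
arms resolve the net knee moment through a convex static-optimization
program; the total articular load is then shared between two frontal-plane
contact points that balance the knee adduction moment.

Conventions
-----------
Sagittal working frame: x forward, y up.  Local tibia frame of the reported
contact forces: x anteroposterior (positive backwards), y distal-proximal
(positive downwards, i.e. compression positive), z mediolateral (positive
inwards).  The net sagittal knee moment ``tau`` is extension-positive; the
frontal moment ``m_frontal`` is adduction-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .errors import ConfigurationError, ContractError, NumericalError
from .synthetic import G, GaitTrial


@dataclass(frozen=True)
class Muscle:
    """One lumped musculotendon actuator spanning the knee.

    ``sagittal_moment_arm`` is signed (extensors positive, metres);
    ``compressive_fraction`` is the cosine of the line-of-action angle to the
    tibial long axis, i.e. the fraction of muscle force that compresses the
    joint.
    """

    name: str
    f_max: float  # N
    sagittal_moment_arm: float  # m, extensors positive
    compressive_fraction: float  # in (0, 1]

    def __post_init__(self):
        if self.f_max <= 0:
            raise ConfigurationError(f"{self.name}: f_max must be > 0")
        if self.sagittal_moment_arm == 0:
            raise ConfigurationError(f"{self.name}: moment arm must be nonzero")
        if not 0 < self.compressive_fraction <= 1:
            raise ConfigurationError(
                f"{self.name}: compressive_fraction must be in (0, 1]"
            )


@dataclass(frozen=True)
class PlanarLimbModel:
    """Segment anthropometry, muscle set and contact geometry.

    Length/mass/centre-of-mass/gyration values are fractions of body height,
    body mass and segment length respectively (Dempster-style tables).
    ``contact_spacing`` is the full mediolateral distance between the medial
    and lateral tibiofemoral contact points; ``frontal_alignment`` is a
    varus/valgus bias of the load line in degrees (varus positive).
    """

    shank_length_frac: float = 0.246
    foot_length_frac: float = 0.152
    shank_mass_frac: float = 0.0465
    foot_mass_frac: float = 0.0145
    shank_com_frac: float = 0.433  # from the knee, along the shank
    foot_com_frac: float = 0.5  # from the ankle, along the foot
    shank_gyration_frac: float = 0.302
    foot_gyration_frac: float = 0.475
    cop_frac: float = 0.25  # centre of pressure, from the ankle along the foot
    muscles: tuple = ()
    contact_spacing: float = 0.045  # m, full medial-lateral contact distance
    frontal_alignment: float = 0.0  # degrees, varus positive
    reserve_weight: float = 1000.0  # dimensionless penalty on reserve torque
    reserve_torque_scale: float = 1.0  # N*m, normalization of the reserve term

    def __post_init__(self):
        if self.contact_spacing <= 0:
            raise ConfigurationError("contact_spacing must be > 0")
        for name in (
            "shank_length_frac",
            "foot_length_frac",
            "shank_mass_frac",
            "foot_mass_frac",
            "shank_com_frac",
            "foot_com_frac",
            "shank_gyration_frac",
            "foot_gyration_frac",
        ):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if self.reserve_weight < 1:
            raise ConfigurationError("reserve_weight must be >= 1")


def default_model() -> PlanarLimbModel:
    """Three lumped muscle groups with textbook moment arms and strengths."""
    return PlanarLimbModel(
        muscles=(
            Muscle("quadriceps", f_max=6000.0, sagittal_moment_arm=0.045,
                   compressive_fraction=0.94),
            Muscle("hamstrings", f_max=3500.0, sagittal_moment_arm=-0.035,
                   compressive_fraction=0.92),
            Muscle("gastrocnemius", f_max=2500.0, sagittal_moment_arm=-0.022,
                   compressive_fraction=0.97),
        )
    )


@dataclass
class JointLoadState:
    """Net knee load at one time point, before muscle-force resolution."""

    time: float  # s
    tau: float  # N*m, net sagittal knee moment, extension positive
    m_frontal: float  # N*m, frontal-plane moment, adduction positive
    intersegmental_force: np.ndarray  # (3,) N, local tibia frame

    def __post_init__(self):
        values = np.concatenate(
            [[self.time, self.tau, self.m_frontal], self.intersegmental_force]
        )
        if not np.all(np.isfinite(values)):
            raise ContractError("JointLoadState requires finite values")


@dataclass
class ActivationSolution:
    """Result of the static-optimization program at one time point."""

    activations: np.ndarray  # (n_muscles,) in [0, 1]
    reserve_torque: float  # N*m
    objective: float  # dimensionless


@dataclass
class KCFSeries:
    """Medial/lateral knee contact forces in body-weight units.

    Channels: med_x, med_y, med_z, lat_x, lat_y, lat_z in the local knee
    frame (x anteroposterior positive backwards, y distal-proximal positive
    downwards, z mediolateral positive inwards).  Left-side series keep the
    generator's left-handed z convention until mirrored in preprocessing.
    """

    CHANNELS = ("med_x", "med_y", "med_z", "lat_x", "lat_y", "lat_z")

    rate: float  # Hz
    data: np.ndarray  # (6, T), BW
    subject_id: str
    side: str
    speed: float
    mirrored: bool = False

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.CHANNELS.index(name)]


# ---------------------------------------------------------------------------
# inverse dynamics


def _segment_geometry(model: PlanarLimbModel, subject_mass: float,
                      subject_height: float) -> dict:
    ls = model.shank_length_frac * subject_height
    lf = model.foot_length_frac * subject_height
    ms = model.shank_mass_frac * subject_mass
    mf = model.foot_mass_frac * subject_mass
    return {
        "L_s": ls, "L_f": lf, "m_s": ms, "m_f": mf,
        "I_s": ms * (model.shank_gyration_frac * ls) ** 2,
        "I_f": mf * (model.foot_gyration_frac * lf) ** 2,
    }


def _inverse_dynamics_arrays(
    angles_deg: np.ndarray,
    grf: np.ndarray,
    rate: float,
    side: str,
    mass: float,
    height: float,
    model: PlanarLimbModel,
    quasi_static: bool = False,
) -> dict:
    """Vectorized planar Newton-Euler over foot+shank about the knee.

    ``angles_deg`` is the (13, T) filtered angle block, ``grf`` the (3, T)
    force block already aligned to the angle grid (Newtons).  Returns arrays
    ``tau`` (extension-positive sagittal knee moment), ``m_frontal``
    (adduction-positive) and ``interseg`` ((3, T), local tibia frame, N).

    The knee centre is treated as an inertially fixed point (steady treadmill
    progression); segment accelerations are taken from the knee-relative
    kinematics, or dropped entirely in quasi-static mode.
    """
    from .synthetic import ANGLE_CHANNELS

    geo = _segment_geometry(model, mass, height)
    idx = {name: ANGLE_CHANNELS.index(name) for name in
           ("pelvis_tilt", "hip_flexion", "knee_flexion", "ankle_flexion")}
    rad = np.radians

    theta_thigh = rad(angles_deg[idx["pelvis_tilt"]] + angles_deg[idx["hip_flexion"]])
    theta_shank = theta_thigh - rad(angles_deg[idx["knee_flexion"]])
    alpha_foot = theta_shank + rad(angles_deg[idx["ankle_flexion"]])

    sin_s, cos_s = np.sin(theta_shank), np.cos(theta_shank)
    foot_dir = np.stack([np.cos(alpha_foot), np.sin(alpha_foot)])  # (2, T)
    ankle = np.stack([geo["L_s"] * sin_s, -geo["L_s"] * cos_s])  # rel. knee
    r_shank_com = model.shank_com_frac * ankle
    r_foot_com = ankle + model.foot_com_frac * geo["L_f"] * foot_dir
    r_cop = ankle + model.cop_frac * geo["L_f"] * foot_dir

    dt = 1.0 / rate
    if quasi_static:
        a_shank = np.zeros_like(r_shank_com)
        a_foot = np.zeros_like(r_foot_com)
        omdot_s = np.zeros_like(theta_shank)
        omdot_f = np.zeros_like(alpha_foot)
    else:
        a_shank = np.gradient(np.gradient(r_shank_com, dt, axis=1), dt, axis=1)
        a_foot = np.gradient(np.gradient(r_foot_com, dt, axis=1), dt, axis=1)
        omdot_s = np.gradient(np.gradient(theta_shank, dt), dt)
        omdot_f = np.gradient(np.gradient(alpha_foot, dt), dt)

    fx, fy, fz = grf
    cross = lambda r, f: r[0] * f[1] - r[1] * f[0]  # z of planar r x F

    grav = np.array([0.0, -G])
    m_ext = (
        cross(r_cop, np.stack([fx, fy]))
        + cross(r_shank_com, geo["m_s"] * grav[:, None] * np.ones_like(r_shank_com))
        + cross(r_foot_com, geo["m_f"] * grav[:, None] * np.ones_like(r_foot_com))
    )
    dh_dt = (
        geo["I_s"] * omdot_s + geo["I_f"] * omdot_f
        + geo["m_s"] * cross(r_shank_com, a_shank)
        + geo["m_f"] * cross(r_foot_com, a_foot)
    )
    # positive external z-moment extends the knee; the internal (muscle)
    # moment must supply the remainder, reported extension-positive
    tau = dh_dt - m_ext

    # frontal plane: mediolateral GRF lever about the knee centre, plus an
    # optional varus/valgus bias of the vertical load line
    z_sign = 1.0 if side == "right" else -1.0
    h_knee = -r_cop[1]  # vertical drop from knee to centre of pressure
    m_frontal = z_sign * fz * h_knee + np.tan(
        np.radians(model.frontal_alignment)
    ) * fy * h_knee

    # intersegmental force (femur on tibia) in the global frame
    m_tot = geo["m_s"] + geo["m_f"]
    f_global = (
        geo["m_s"] * a_shank + geo["m_f"] * a_foot
        - np.stack([fx, fy])
        - m_tot * grav[:, None]
    )
    # resolve in the local tibia frame (x backwards, y distally down)
    local_x = -cos_s * f_global[0] - sin_s * f_global[1]
    local_y = sin_s * f_global[0] - cos_s * f_global[1]
    local_z = -fz  # mediolateral transfer, in the trial's own handedness

    return {
        "tau": tau,
        "m_frontal": m_frontal,
        "interseg": np.stack([local_x, local_y, local_z]),
    }


def inverse_dynamics_knee(
    trial: GaitTrial,
    model: PlanarLimbModel | None = None,
    quasi_static: bool = False,
) -> list[JointLoadState]:
    """Per-time-point net knee loads for a trial.

    The trial's angles are low-pass filtered at 6 Hz and its GRFs filtered
    and downsampled onto the angle grid before the Newton-Euler pass.
    """
    from .preprocess import downsample_grf, lowpass

    if model is None:
        model = default_model()
    angles = lowpass(trial.angles, 6.0, trial.angle_rate)
    grf = downsample_grf(trial)
    arrays = _inverse_dynamics_arrays(
        angles, grf, trial.angle_rate, trial.side,
        trial.subject.mass, trial.subject.height, model, quasi_static,
    )
    times = np.arange(angles.shape[1]) / trial.angle_rate
    return [
        JointLoadState(
            time=float(t),
            tau=float(arrays["tau"][i]),
            m_frontal=float(arrays["m_frontal"][i]),
            intersegmental_force=arrays["interseg"][:, i].copy(),
        )
        for i, t in enumerate(times)
    ]


# ---------------------------------------------------------------------------
# static optimization


def _muscle_gains(model: PlanarLimbModel) -> np.ndarray:
    """Moment produced per unit activation for each muscle (N*m)."""
    if not model.muscles:
        raise ConfigurationError("model must include at least one knee muscle")
    return np.array([m.sagittal_moment_arm * m.f_max for m in model.muscles])


def static_optimization(
    state: JointLoadState, model: PlanarLimbModel
) -> ActivationSolution:
    """Resolve muscle redundancy at one time point.

    Solves the convex program

        min  sum(a_i^2) + w * (tau_res / tau_0)^2
        s.t. sum(r_i * f_max_i * a_i) + tau_res = tau,  0 <= a_i <= 1

    which, after eliminating the reserve torque, is a bounded linear least
    squares problem with a unique minimizer.  The reserve actuator absorbs
    whatever moment the muscles cannot (or should not, at quadratic cost)
    produce, so the program is feasible for any ``tau``.
    """
    q = _muscle_gains(model)
    w = model.reserve_weight
    tau0 = model.reserve_torque_scale
    sw = np.sqrt(w) / tau0
    n = len(q)
    a_mat = np.vstack([np.eye(n), sw * q])
    b_vec = np.concatenate([np.zeros(n), [sw * state.tau]])
    result = lsq_linear(a_mat, b_vec, bounds=(0.0, 1.0), tol=1e-14)
    if not result.success:
        raise NumericalError(f"static optimization failed: {result.message}")
    a = np.clip(result.x, 0.0, 1.0)
    tau_res = state.tau - float(q @ a)
    objective = float(a @ a + w * (tau_res / tau0) ** 2)
    return ActivationSolution(activations=a, reserve_torque=tau_res,
                              objective=objective)


def solve_activations_batch(
    tau: np.ndarray, model: PlanarLimbModel, iterations: int = 120
) -> np.ndarray:
    """Vectorized static optimization across time points.

    Exploits the KKT structure of the program in :func:`static_optimization`:
    at the optimum a_i = clip(q_i * lam, 0, 1) where lam = W * tau_res and
    W = w / tau_0^2, and lam solves the scalar monotone equation
    lam / W + sum(q_i * clip(q_i * lam, 0, 1)) = tau.  Solved by bisection
    simultaneously for all frames; agrees with the per-point solver to
    numerical precision (property-tested).
    """
    q = _muscle_gains(model)
    w_eff = model.reserve_weight / model.reserve_torque_scale**2
    tau = np.asarray(tau, dtype=float)

    lam_max = w_eff * (np.max(np.abs(tau), initial=0.0) + np.sum(np.abs(q))) + 1.0
    lo = np.full(tau.shape, -lam_max)
    hi = np.full(tau.shape, lam_max)

    def residual(lam):
        a = np.clip(np.multiply.outer(lam, q), 0.0, 1.0)
        return lam / w_eff + a @ q - tau

    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        high = residual(mid) > 0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    lam = 0.5 * (lo + hi)
    return np.clip(np.multiply.outer(lam, q), 0.0, 1.0)


# ---------------------------------------------------------------------------
# joint reaction and contact split


def joint_reaction(
    state: JointLoadState, sol: ActivationSolution, model: PlanarLimbModel
) -> np.ndarray:
    """Total knee force (3 components, N, local tibia frame).

    Muscle forces add their compressive component along the tibial axis
    (positive downwards) and their residual shear along the anteroposterior
    axis, signed so extensor pull is anterior; the intersegmental force
    carries the external and inertial contribution.
    """
    fx, fy, fz = state.intersegmental_force
    for muscle, a in zip(model.muscles, sol.activations):
        force = a * muscle.f_max
        cf = muscle.compressive_fraction
        fy += force * cf
        fx += -np.sign(muscle.sagittal_moment_arm) * force * np.sqrt(1.0 - cf**2)
    return np.array([fx, fy, fz])


def split_contact(
    total_force: np.ndarray, m_frontal: float, model: PlanarLimbModel
) -> tuple[np.ndarray, np.ndarray]:
    """Share the total knee load between medial and lateral contact points.

    The compressive components solve F_med + F_lat = F_y and
    (d/2)(F_med - F_lat) = M_f; a negative solution is clamped to zero with
    the full load on the other compartment (unilateral contact).  Contact
    transmits compression only, so a net distractive (negative) total load
    leaves both compartments unloaded.  Shear goes to the medial compartment
    (lateral x identically 0); the mediolateral component is distributed in
    proportion to the compressive shares.
    """
    d = model.contact_spacing
    if d <= 0:
        raise ConfigurationError("contact_spacing must be > 0")
    total_x, total_y, total_z = total_force
    f_y = max(total_y, 0.0)
    f_med = 0.5 * f_y + m_frontal / d
    f_lat = f_y - f_med
    if f_med < 0.0:
        f_med, f_lat = 0.0, f_y
    elif f_lat < 0.0:
        f_med, f_lat = f_y, 0.0
    share_med = f_med / f_y if f_y > 0 else 0.5
    med = np.array([total_x, f_med, total_z * share_med])
    lat = np.array([0.0, f_lat, total_z * (1.0 - share_med)])
    return med, lat


def _split_contact_batch(total: np.ndarray, m_frontal: np.ndarray,
                         model: PlanarLimbModel) -> np.ndarray:
    """Vectorized :func:`split_contact`; ``total`` is (3, T).  Returns (6, T)."""
    d = model.contact_spacing
    f_y = np.maximum(total[1], 0.0)
    f_med = np.clip(0.5 * f_y + m_frontal / d, 0.0, f_y)
    f_lat = f_y - f_med
    share = np.divide(f_med, f_y, out=np.full_like(f_y, 0.5), where=f_y > 0)
    zeros = np.zeros_like(f_y)
    return np.stack([
        total[0], f_med, total[2] * share,
        zeros, f_lat, total[2] * (1.0 - share),
    ])


def compute_kcf(
    trial: GaitTrial,
    model: PlanarLimbModel | None = None,
    quasi_static: bool = False,
) -> KCFSeries:
    """Full ground-truth chain for one trial, in body-weight units.

    Composes filtering/downsampling, planar inverse dynamics, static
    optimization (vectorized across frames), joint reaction and the
    medial/lateral split, then normalizes Newtons by mass * g.
    """
    from .preprocess import downsample_grf, lowpass

    if model is None:
        model = default_model()
    angles = lowpass(trial.angles, 6.0, trial.angle_rate)
    grf = downsample_grf(trial)
    arrays = _inverse_dynamics_arrays(
        angles, grf, trial.angle_rate, trial.side,
        trial.subject.mass, trial.subject.height, model, quasi_static,
    )

    activations = solve_activations_batch(arrays["tau"], model)  # (T, n)
    total = arrays["interseg"].copy()  # (3, T)
    for j, muscle in enumerate(model.muscles):
        force = activations[:, j] * muscle.f_max
        cf = muscle.compressive_fraction
        total[1] += force * cf
        total[0] += -np.sign(muscle.sagittal_moment_arm) * force * np.sqrt(1 - cf**2)

    data = _split_contact_batch(total, arrays["m_frontal"], model)
    data /= trial.subject.body_weight
    return KCFSeries(
        rate=trial.angle_rate,
        data=data,
        subject_id=trial.subject.subject_id,
        side=trial.side,
        speed=trial.speed,
    )
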