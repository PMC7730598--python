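"""Planar ground-truth chain: inverse dynamics, static optimization,
joint reaction and the medial/lateral contact split."""

from dataclasses import replace

import numpy as np
import pytest

import kneeload as kl
from kneeload.errors import ConfigurationError
from kneeload.msk import (
    G,
    JointLoadState,
    Muscle,
    PlanarLimbModel,
    _inverse_dynamics_arrays,
    _split_contact_batch,
    default_model,
    solve_activations_batch,
)
from _oracles import grid_search_activation_objective


def _state(tau=0.0, m_frontal=0.0, interseg=(0.0, 0.0, 0.0)):
    return JointLoadState(
        time=0.0, tau=tau, m_frontal=m_frontal,
        intersegmental_force=np.array(interseg, dtype=float),
    )


def _single_muscle_model(r=0.04, f_max=3000.0, cf=1.0, w=1e6):
    return PlanarLimbModel(
        muscles=(Muscle("ext", f_max=f_max, sagittal_moment_arm=r,
                        compressive_fraction=cf),),
        reserve_weight=w,
    )


class TestInverseDynamics:
    @staticmethod
    def _still_arrays(model, mass, height, knee_flex_deg, T=50):
        """Stationary posture: hanging shank/foot at a fixed knee angle."""
        angles = np.zeros((13, T))
        from kneeload.synthetic import ANGLE_CHANNELS

        angles[ANGLE_CHANNELS.index("knee_flexion")] = knee_flex_deg
        grf = np.zeros((3, T))
        return _inverse_dynamics_arrays(
            angles, grf, 100.0, "right", mass, height, model
        )

    def test_zero_grf_stationary_matches_pendulum_moment(self):
        """With no external load the knee moment is the gravitational moment
        of the hanging foot+shank, computable in closed form."""
        model = replace(default_model(), cop_frac=0.25)
        mass, height, knee = 70.0, 1.75, 30.0
        arrays = self._still_arrays(model, mass, height, knee)
        theta_s = -np.radians(knee)  # thigh vertical, shank swung back
        ls = model.shank_length_frac * height
        lf = model.foot_length_frac * height
        ms, mf = model.shank_mass_frac * mass, model.foot_mass_frac * mass
        # moments of gravity about the knee; foot is horizontal at alpha=theta_s
        x_s = model.shank_com_frac * ls * np.sin(theta_s)
        x_f = ls * np.sin(theta_s) + model.foot_com_frac * lf * np.cos(theta_s)
        expected_tau = G * (ms * x_s + mf * x_f)  # = -(r x mg)_z
        np.testing.assert_allclose(arrays["tau"], expected_tau, atol=1e-9)
        np.testing.assert_allclose(arrays["m_frontal"], 0.0, atol=1e-12)
        # femur carries the hanging segments: pure upward (distractive) force
        np.testing.assert_allclose(
            arrays["interseg"][1], -(ms + mf) * G * np.cos(theta_s), atol=1e-9
        )

    def test_upright_stance_with_grf_through_knee_is_moment_free(self):
        """Vertical GRF through the knee centre: the only remaining knee
        moment is the foot's own small gravitational moment."""
        model = replace(default_model(), cop_frac=0.0)  # COP at the ankle
        mass, height = 70.0, 1.75
        angles = np.zeros((13, 40))
        grf = np.zeros((3, 40))
        grf[1] = mass * G
        arrays = _inverse_dynamics_arrays(angles, grf, 100.0, "right",
                                          mass, height, model)
        x_foot_com = model.foot_com_frac * model.foot_length_frac * height
        foot_gravity_tau = model.foot_mass_frac * mass * G * x_foot_com
        np.testing.assert_allclose(arrays["tau"], foot_gravity_tau, atol=1e-9)
        np.testing.assert_allclose(arrays["m_frontal"], 0.0, atol=1e-12)

    def test_external_moment_is_linear_in_grf(self):
        model = default_model()
        mass, height = 70.0, 1.75
        angles = np.zeros((13, 30))
        angles[6] = 20.0  # hip flexion tips the shank forward
        grf1 = np.zeros((3, 30))
        grf1[1] = 400.0
        grf2 = 2.0 * grf1
        base = self._still_arrays(model, mass, height, 0.0, T=30)["tau"]
        tau1 = _inverse_dynamics_arrays(angles * 0, grf1, 100.0, "right",
                                        mass, height, model)["tau"]
        tau2 = _inverse_dynamics_arrays(angles * 0, grf2, 100.0, "right",
                                        mass, height, model)["tau"]
        np.testing.assert_allclose(tau2 - base, 2 * (tau1 - base), atol=1e-9)

    def test_nonuniform_time_grid_rejected(self, one_trial):
        bad = replace(one_trial) if False else one_trial
        states = kl.inverse_dynamics_knee(one_trial)
        assert len(states) == one_trial.angles.shape[1]
        assert all(np.isfinite(s.tau) for s in states)


class TestStaticOptimization:
    def test_single_extensor_analytic(self):
        model = _single_muscle_model(r=0.04, f_max=3000.0)
        sol = kl.static_optimization(_state(tau=60.0), model)
        assert sol.activations[0] == pytest.approx(0.5, abs=1e-6)
        assert sol.reserve_torque == pytest.approx(0.0, abs=1e-3)

    def test_two_identical_extensors_share_equally(self):
        m = Muscle("e", f_max=3000.0, sagittal_moment_arm=0.04,
                   compressive_fraction=0.95)
        model = PlanarLimbModel(muscles=(m, replace(m, name="e2")))
        sol = kl.static_optimization(_state(tau=60.0), model)
        assert sol.activations[0] == pytest.approx(sol.activations[1], abs=1e-9)

    def test_activation_bounds_respected_with_reserve_overflow(self):
        model = _single_muscle_model(r=0.04, f_max=1000.0, w=1000.0)
        sol = kl.static_optimization(_state(tau=500.0), model)  # over capacity
        assert 0.0 <= sol.activations[0] <= 1.0
        # reserve closes the moment balance exactly
        residual = 0.04 * 1000.0 * sol.activations[0] + sol.reserve_torque - 500.0
        assert abs(residual) < 1e-9

    def test_objective_matches_grid_search_oracle(self):
        """100 random <=3-muscle problems against exhaustive grid search."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(1, 4))
            muscles = tuple(
                Muscle(
                    f"m{i}",
                    f_max=float(rng.uniform(500, 5000)),
                    sagittal_moment_arm=float(rng.choice([-1, 1]) * rng.uniform(0.02, 0.06)),
                    compressive_fraction=float(rng.uniform(0.8, 1.0)),
                )
                for i in range(n)
            )
            w = float(rng.uniform(10, 2000))
            model = PlanarLimbModel(muscles=muscles, reserve_weight=w)
            tau = float(rng.uniform(-120, 120))
            sol = kl.static_optimization(_state(tau=tau), model)
            gains = [m.sagittal_moment_arm * m.f_max for m in muscles]
            oracle = grid_search_activation_objective(tau, gains, w)
            assert abs(sol.objective - oracle) < 1e-6

    def test_kkt_no_descent_direction(self):
        """Feasible single-coordinate perturbations cannot lower the cost."""
        rng = np.random.default_rng(7)
        model = default_model()
        w = model.reserve_weight

        def objective(a, tau):
            gains = np.array([m.sagittal_moment_arm * m.f_max for m in model.muscles])
            return float(a @ a + w * (tau - gains @ a) ** 2)

        for tau in rng.uniform(-100, 100, size=10):
            sol = kl.static_optimization(_state(tau=float(tau)), model)
            base = objective(sol.activations, tau)
            for i in range(len(model.muscles)):
                for delta in (1e-4, -1e-4):
                    a = sol.activations.copy()
                    a[i] = np.clip(a[i] + delta, 0.0, 1.0)
                    assert objective(a, tau) >= base - 1e-12

    def test_batch_solver_agrees_with_per_point_program(self):
        rng = np.random.default_rng(3)
        model = default_model()
        taus = rng.uniform(-150, 150, size=60)
        batch = solve_activations_batch(taus, model)
        for i, tau in enumerate(taus):
            sol = kl.static_optimization(_state(tau=float(tau)), model)
            np.testing.assert_allclose(batch[i], sol.activations, atol=1e-7)

    def test_model_without_muscles_rejected(self):
        with pytest.raises(ConfigurationError):
            kl.static_optimization(_state(tau=10.0), PlanarLimbModel())


class TestJointReaction:
    def test_null_load_gives_zero_force(self):
        model = default_model()
        sol = kl.ActivationSolution(
            activations=np.zeros(len(model.muscles)), reserve_torque=0.0,
            objective=0.0,
        )
        np.testing.assert_array_equal(
            kl.joint_reaction(_state(), sol, model), np.zeros(3)
        )

    def test_single_fully_compressive_muscle(self):
        model = _single_muscle_model(r=0.04, f_max=1000.0, cf=1.0)
        sol = kl.ActivationSolution(
            activations=np.array([1.0]), reserve_torque=0.0, objective=1.0
        )
        force = kl.joint_reaction(_state(), sol, model)
        assert force[1] == pytest.approx(1000.0)
        assert force[0] == pytest.approx(0.0)

    def test_muscle_cancels_equal_distraction(self):
        model = _single_muscle_model(r=0.04, f_max=1000.0, cf=1.0)
        sol = kl.ActivationSolution(
            activations=np.array([0.5]), reserve_torque=0.0, objective=0.25
        )
        state = _state(interseg=(0.0, -500.0, 0.0))
        assert kl.joint_reaction(state, sol, model)[1] == pytest.approx(0.0)


class TestSplitContact:
    def test_symmetric_split_without_frontal_moment(self):
        med, lat = kl.split_contact(np.array([0.0, 2000.0, 0.0]), 0.0,
                                    default_model())
        assert med[1] == pytest.approx(1000.0)
        assert lat[1] == pytest.approx(1000.0)

    def test_adduction_moment_shifts_load_medially_and_clamps(self):
        model = default_model()
        d = model.contact_spacing
        f_y = 2000.0
        med, lat = kl.split_contact(np.array([0.0, f_y, 0.0]),
                                    d / 2 * f_y, model)
        assert med[1] == pytest.approx(f_y)
        assert lat[1] == pytest.approx(0.0)

    def test_conservation_and_lateral_shear_zero(self):
        rng = np.random.default_rng(1)
        model = default_model()
        for _ in range(50):
            total = rng.uniform([-500, 0, -200], [500, 4000, 200])
            m_f = rng.uniform(-60, 60)
            med, lat = kl.split_contact(total, m_f, model)
            assert med[1] >= 0 and lat[1] >= 0
            assert med[1] + lat[1] == pytest.approx(max(total[1], 0.0), abs=1e-9)
            assert lat[0] == 0.0
            assert med[2] + lat[2] == pytest.approx(total[2], abs=1e-9)

    def test_preclamp_moment_balance(self):
        """Before clamping, the contact couple equals the frontal moment."""
        model = default_model()
        d = model.contact_spacing
        rng = np.random.default_rng(4)
        for _ in range(100):
            f_y = rng.uniform(0, 4000)
            m_f = rng.uniform(-d * f_y, d * f_y) / 2  # within clamp-free range
            med, lat = kl.split_contact(np.array([0.0, f_y, 0.0]), m_f, model)
            assert (d / 2) * (med[1] - lat[1]) - m_f == pytest.approx(0.0, abs=1e-9)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            PlanarLimbModel(contact_spacing=0.0)


class TestComputeKcf:
    def test_batch_split_matches_scalar_split(self):
        rng = np.random.default_rng(11)
        model = default_model()
        total = rng.uniform([-500, -200, -200], [500, 4000, 200], size=(40, 3)).T
        m_f = rng.uniform(-60, 60, size=40)
        batch = _split_contact_batch(total, m_f, model)
        for i in range(40):
            med, lat = kl.split_contact(total[:, i], m_f[i], model)
            np.testing.assert_allclose(batch[:3, i], med, atol=1e-9)
            np.testing.assert_allclose(batch[3:, i], lat, atol=1e-9)

    def test_zero_strength_muscles_leave_intersegmental_force(self, one_trial):
        base = default_model()
        weak = replace(
            base,
            muscles=tuple(replace(m, f_max=1e-9) for m in base.muscles),
        )
        kcf = kl.compute_kcf(one_trial, weak)
        from kneeload.msk import _inverse_dynamics_arrays
        from kneeload.preprocess import downsample_grf, lowpass

        angles = lowpass(one_trial.angles, 6.0, one_trial.angle_rate)
        grf = downsample_grf(one_trial)
        arrays = _inverse_dynamics_arrays(
            angles, grf, one_trial.angle_rate, "right",
            one_trial.subject.mass, one_trial.subject.height, weak,
        )
        bw = one_trial.subject.body_weight
        total_y = np.maximum(arrays["interseg"][1], 0.0) / bw
        np.testing.assert_allclose(
            kcf.channel("med_y") + kcf.channel("lat_y"), total_y, atol=1e-6
        )

    def test_kcf_series_invariants_hold_on_a_full_trial(self, small_trials):
        model = default_model()
        for trial in small_trials[:4]:
            kcf = kl.compute_kcf(trial, model)
            assert kcf.channel("med_y").min() >= 0.0
            assert kcf.channel("lat_y").min() >= 0.0
            assert np.all(np.isfinite(kcf.data))
            assert kcf.data.shape == (6, trial.angles.shape[1])

    def test_swing_phase_loads_are_small(self, one_trial):
        """With no GRF the knee carries only muscle and segment loads."""
        kcf = kl.compute_kcf(one_trial, default_model())
        grf_ds = one_trial.grf[1, ::10]
        swing = grf_ds == 0.0
        # interior swing samples (away from filter edge effects)
        total = kcf.channel("med_y") + kcf.channel("lat_y")
        assert np.median(total[swing]) < 0.8  # well below stance peaks ~4 BW
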