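import numpy as np
import pytest
from dataclasses import replace

from damperopt.device import DesignParams
from damperopt.gait_model import (
    Anthropometry,
    ControllerTheta,
    ScenarioConfig,
    default_anthropometry,
    fourier_eval,
    generate_kinematics,
    inverse_dynamics,
    knee_load,
    metabolic_power,
    simulate,
)
from damperopt.phases import GaitPhase

LEVEL = ScenarioConfig()


def _theta(**kw) -> ControllerTheta:
    defaults = dict(
        hip_coeffs=(0.0,),
        knee_coeffs=(0.3,),
        ankle_coeffs=(0.0,),
        stride_period=1.0,
        stride_length=1.2,
        pelvis_height=0.85,
        pelvis_vert_amp=0.0,
        pelvis_fore_amp=0.0,
    )
    defaults.update(kw)
    return ControllerTheta(**defaults)


class TestKinematics:
    def test_zero_harmonics_constant_posture(self):
        kin = generate_kinematics(_theta(), LEVEL)
        for joint in ("hip", "knee", "ankle"):
            assert np.ptp(kin.angles["right"][joint]) == 0.0
            np.testing.assert_allclose(kin.omegas["right"][joint], 0.0)

    def test_single_harmonic_range_is_twice_amplitude(self):
        amp = 0.2
        kin = generate_kinematics(_theta(knee_coeffs=(0.5, amp, 0.0)), LEVEL)
        assert np.ptp(kin.angles["right"]["knee"]) == pytest.approx(2 * amp, rel=1e-3)

    def test_periodicity(self):
        theta = _theta(
            hip_coeffs=(0.1, 0.3, -0.1, 0.05, 0.02),
            knee_coeffs=(0.4, -0.05, -0.3, 0.1, 0.05),
            stride_period=1.1,
        )
        scenario = replace(LEVEL, dt=0.0011)  # grid hits t and t+T exactly
        kin = generate_kinematics(theta, scenario)
        n_period = 1000
        a = kin.angles["right"]["knee"]
        np.testing.assert_allclose(a[:-n_period], a[n_period:], atol=1e-9)

    def test_left_leg_is_half_stride_shift(self):
        theta = _theta(knee_coeffs=(0.4, 0.2, 0.1), stride_period=1.0)
        scenario = replace(LEVEL, dt=0.005)
        kin = generate_kinematics(theta, scenario)
        shift = int(round(theta.stride_period / 2 / scenario.dt))
        right, left = kin.angles["right"]["knee"], kin.angles["left"]["knee"]
        np.testing.assert_allclose(left[:-shift], right[shift:], atol=1e-9)

    def test_non_finite_coeffs_rejected(self):
        with pytest.raises(ValueError):
            _theta(knee_coeffs=(np.nan,))

    def test_fourier_derivative_consistency(self):
        coeffs = (0.1, 0.4, -0.2, 0.15, 0.05)
        t = np.linspace(0, 2, 4001)
        f = fourier_eval(coeffs, t, 1.1, 0)
        df = fourier_eval(coeffs, t, 1.1, 1)
        num = np.gradient(f, t[1] - t[0])
        np.testing.assert_allclose(df[10:-10], num[10:-10], atol=1e-3)


class TestInverseDynamicsStatics:
    """Static oracles derived by hand from force balance."""

    def test_symmetric_standing_splits_body_weight(self):
        anthro = default_anthropometry()
        theta = _theta(knee_coeffs=(0.0,), stride_length=1e-3, stride_period=10.0)
        scenario = replace(LEVEL, duration=2.0, target_speed=0.0)
        kin = generate_kinematics(theta, scenario)
        kin.pelvis_vel[:] = 0.0
        kin.pelvis_acc[:] = 0.0
        kin.pelvis_pos[:, 0] = 0.0
        idr = inverse_dynamics(kin, anthro, scenario)
        expected = anthro.total_mass * scenario.gravity / 2.0
        mid = slice(50, -50)
        np.testing.assert_allclose(idr.grf["right"][mid, 1], expected, rtol=1e-6)
        np.testing.assert_allclose(idr.grf["left"][mid, 1], expected, atol=1e-6 * expected)
        np.testing.assert_allclose(idr.grf["right"][mid, 0], 0.0, atol=1e-6)

    def test_single_support_takes_full_weight(self):
        anthro = default_anthropometry()
        # left knee deeply flexed -> left foot far above ground
        theta = _theta(knee_coeffs=(0.0,), stride_length=1e-3, stride_period=10.0)
        scenario = replace(LEVEL, duration=2.0, target_speed=0.0)
        kin = generate_kinematics(theta, scenario)
        kin.pelvis_vel[:] = 0.0
        kin.pelvis_acc[:] = 0.0
        kin.pelvis_pos[:, 0] = 0.0
        kin.angles["left"]["knee"] = np.full_like(kin.angles["left"]["knee"], 1.5)
        idr = inverse_dynamics(kin, anthro, scenario)
        expected = anthro.total_mass * scenario.gravity
        mid = slice(50, -50)
        np.testing.assert_allclose(idr.grf["right"][mid, 1], expected, rtol=1e-4)
        np.testing.assert_allclose(idr.grf["left"][mid, 1], 0.0, atol=1e-4 * expected)

    def test_zero_gravity_zero_acceleration_gives_zero_forces(self):
        anthro = default_anthropometry()
        theta = _theta(stride_length=1e-3, stride_period=10.0)
        scenario = replace(LEVEL, duration=2.0, gravity=0.0, target_speed=0.0)
        kin = generate_kinematics(theta, scenario)
        kin.pelvis_vel[:] = 0.0
        kin.pelvis_acc[:] = 0.0
        kin.pelvis_pos[:, 0] = 0.0
        idr = inverse_dynamics(kin, anthro, scenario)
        mid = slice(50, -50)
        np.testing.assert_allclose(idr.grf_total[mid], 0.0, atol=1e-9)
        np.testing.assert_allclose(idr.knee_force["right"][mid], 0.0, atol=1e-9)
        np.testing.assert_allclose(idr.net_moment["right"]["knee"][mid], 0.0, atol=1e-9)


class TestKneeLoad:
    def test_zero_inputs(self):
        assert knee_load(0.0, 0.0, 0.04, 800.0) == 0.0

    def test_arithmetic_example(self):
        # (800 N + 40/0.04 N) / 800 N = 2.25
        assert knee_load(800.0, 40.0, 0.04, 800.0) == pytest.approx(2.25)

    def test_monotone_in_moment(self):
        full = knee_load(800.0, 40.0, 0.04, 800.0)
        halved = knee_load(800.0, 20.0, 0.04, 800.0)
        assert halved < full

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            knee_load(1.0, 1.0, 0.0, 800.0)
        with pytest.raises(ValueError):
            knee_load(1.0, 1.0, 0.04, 0.0)


class TestMetabolicPower:
    def test_all_zero_gives_basal(self):
        out = metabolic_power([np.zeros(10)], basal=90.0)
        np.testing.assert_allclose(out, 90.0)

    def test_single_positive_joint(self):
        out = metabolic_power([np.full(5, 100.0)], alpha_pos=4.0, basal=90.0)
        np.testing.assert_allclose(out, 90.0 + 400.0)

    def test_matches_brute_force_sum(self, rng):
        powers = [rng.normal(0, 50, 200) for _ in range(3)]
        out = metabolic_power(powers, alpha_pos=4.0, alpha_neg=0.8, basal=90.0)
        # independent per-sample summation
        expected = np.full(200, 90.0)
        for p in powers:
            for i, v in enumerate(p):
                expected[i] += 4.0 * max(v, 0.0) + 0.8 * max(-v, 0.0)
        np.testing.assert_allclose(out, expected)

    def test_never_below_basal(self, rng):
        powers = [rng.normal(0, 100, 500)]
        assert metabolic_power(powers, basal=90.0).min() >= 90.0

    def test_invalid_coefficients(self):
        with pytest.raises(ValueError):
            metabolic_power([np.zeros(3)], alpha_pos=0.0)


class TestSimulatePipeline:
    def test_baseline_vs_zero_damping_identical(self, level_preset):
        theta, anthro, scenario = level_preset
        none_res = simulate(None, theta, scenario, anthro)
        pattern = frozenset({GaitPhase.EARLY_STANCE, GaitPhase.LATE_STANCE})
        zero_res = simulate(DesignParams(0.0, pattern), theta, scenario, anthro)
        np.testing.assert_array_equal(
            none_res.bio_moment["right"]["knee"], zero_res.bio_moment["right"]["knee"]
        )
        np.testing.assert_array_equal(
            none_res.knee_load["left"], zero_res.knee_load["left"]
        )
        assert none_res.cost_of_transport == zero_res.cost_of_transport

    def test_disengaged_samples_have_zero_torque(self, level_preset):
        theta, anthro, scenario = level_preset
        design = DesignParams(3.0, frozenset({GaitPhase.EARLY_STANCE}))
        res = simulate(design, theta, scenario, anthro)
        for leg in ("right", "left"):
            disengaged = ~res.engaged_mask(leg)
            np.testing.assert_array_equal(res.exo_torque[leg][disengaged], 0.0)

    def test_bio_power_at_least_net_power_when_engaged(self, level_preset):
        theta, anthro, scenario = level_preset
        design = DesignParams(3.0, frozenset({GaitPhase.EARLY_STANCE, GaitPhase.LATE_STANCE}))
        res = simulate(design, theta, scenario, anthro)
        for leg in ("right", "left"):
            engaged = res.engaged_mask(leg)
            omega = res.omegas[leg]["knee"]
            p_net = res.net_moment[leg]["knee"] * omega
            p_bio = res.bio_moment[leg]["knee"] * omega
            assert np.all(p_bio[engaged] >= p_net[engaged] - 1e-9)

    def test_net_bio_exo_identity(self, level_preset):
        theta, anthro, scenario = level_preset
        design = DesignParams(2.0, frozenset({GaitPhase.LATE_STANCE}))
        res = simulate(design, theta, scenario, anthro)
        for leg in ("right", "left"):
            np.testing.assert_allclose(
                res.bio_moment[leg]["knee"],
                res.net_moment[leg]["knee"] - res.exo_torque[leg],
            )

    def test_vertical_grf_closure_over_strides(self, level_result):
        res = level_result
        i0 = res.strides["right"][0][0]
        i1 = res.strides["right"][-1][1]
        total_y = (res.grf["right"][:, 1] + res.grf["left"][:, 1])[i0:i1]
        assert abs(total_y.mean() / res.body_weight - 1.0) < 0.01

    def test_offloading_identity_in_negative_power_region(self, level_preset):
        """Damper subtracts exactly c|w| from the biological moment where
        net moment opposes knee velocity (the offloading mechanism)."""
        theta, anthro, scenario = level_preset
        c = 2.0
        design = DesignParams(
            c, frozenset({GaitPhase.EARLY_STANCE, GaitPhase.LATE_STANCE})
        )
        res = simulate(design, theta, scenario, anthro)
        checked = 0
        for leg in ("right", "left"):
            omega = res.omegas[leg]["knee"]
            net = res.net_moment[leg]["knee"]
            bio = res.bio_moment[leg]["knee"]
            mask = (
                res.engaged_mask(leg)
                & (net * omega < 0)
                & (c * np.abs(omega) <= np.abs(net))
            )
            checked += int(mask.sum())
            np.testing.assert_allclose(
                np.abs(bio[mask]), np.abs(net[mask]) - c * np.abs(omega[mask])
            )
        assert checked > 100

    def test_time_grid_refinement_stability(self, level_preset):
        theta, anthro, scenario = level_preset
        res_coarse = simulate(None, theta, scenario, anthro)
        res_fine = simulate(None, theta, replace(scenario, dt=scenario.dt / 2), anthro)
        assert res_fine.cost_of_transport == pytest.approx(
            res_coarse.cost_of_transport, rel=0.005
        )

    def test_speed_validity_flag(self, level_preset):
        theta, anthro, scenario = level_preset
        slow = replace(theta, stride_length=theta.stride_length * 0.7)
        res = simulate(None, slow, scenario, anthro)
        assert not res.valid
        assert "speed_off_target" in res.invalid_reasons

    def test_knee_limit_validity_flag(self, level_preset):
        theta, anthro, scenario = level_preset
        bad_coeffs = (theta.knee_coeffs[0] - 0.6,) + theta.knee_coeffs[1:]
        res = simulate(None, replace(theta, knee_coeffs=bad_coeffs), scenario, anthro)
        assert not res.valid
        assert any(r.startswith("knee_limit") for r in res.invalid_reasons)

    def test_shared_time_grid(self, level_result):
        res = level_result
        n = len(res.t)
        for leg in ("right", "left"):
            assert len(res.exo_torque[leg]) == n
            assert len(res.knee_load[leg]) == n
            assert len(res.phase_labels[leg]) == n
        assert len(res.metabolic_series) == n

    def test_result_round_trip(self, level_result, tmp_path):
        level_result.save(tmp_path / "sim.csv", tmp_path / "sim.json")
        import json
        import pandas as pd

        frame = pd.read_csv(tmp_path / "sim.csv")
        assert len(frame) == len(level_result.t)
        scalars = json.loads((tmp_path / "sim.json").read_text())
        assert scalars["valid"] is True


class TestAnthropometry:
    def test_mass_consistency_enforced(self):
        with pytest.raises(ValueError):
            Anthropometry(total_mass=70.0)  # default segments sum to 75

    def test_default_scaling(self):
        a = default_anthropometry(90.0)
        assert a.total_mass == 90.0
        assert a.body_weight == pytest.approx(90.0 * 9.81)

    def test_theta_vector_round_trip(self, level_preset):
        theta = level_preset[0]
        vec = theta.to_vector()
        back = theta.from_vector(vec)
        np.testing.assert_allclose(back.to_vector(), vec)
        assert back.stride_period == theta.stride_period


def test_theta_json_round_trip(level_preset, tmp_path):
    from damperopt.gait_model import theta_from_json, theta_to_json

    theta = level_preset[0]
    path = tmp_path / "theta.json"
    theta_to_json(theta, path)
    back = theta_from_json(path)
    np.testing.assert_allclose(back.to_vector(), theta.to_vector())
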