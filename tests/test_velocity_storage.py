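import math

import numpy as np
import pytest
from scipy.linalg import expm

from mddskit import (
    AmbiguousEigenvectorError,
    ComplexEigenvalueError,
    GainMatrices,
    OKSDirection,
    SystemMatrix,
    Vec3,
    adapt,
    build_system_matrix,
    eigenstructure,
    misalignment,
    simulate,
)

TAUS = (15.0, 8.0, 20.0)


class TestBuildSystemMatrix:
    def test_normal_state_is_diagonal(self):
        sm = build_system_matrix(TAUS, "forward", 0.0)
        np.testing.assert_allclose(
            sm.H, np.diag([-1 / 15, -1 / 8, -1 / 20]), atol=1e-12
        )

    def test_forward_tilt_couples_yaw_into_roll_only(self):
        sm = build_system_matrix(TAUS, "forward", 15.0)
        assert sm.h_yr != 0.0
        assert sm.h_yp == pytest.approx(0.0, abs=1e-15)

    def test_lateral_tilt_couples_yaw_into_pitch_only(self):
        sm = build_system_matrix(TAUS, "right", 15.0)
        assert sm.h_yp != 0.0
        assert sm.h_yr == pytest.approx(0.0, abs=1e-15)

    def test_right_tilt_eigenvector_recovered(self):
        sm = build_system_matrix(TAUS, "right", 15.0)
        es = eigenstructure(sm)
        s, c = math.sin(math.radians(15)), math.cos(math.radians(15))
        np.testing.assert_allclose(es.ev_yaw.as_array(), [0, -s, c], atol=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(time_constants=(0.0, 8, 20)),
            dict(time_constants=TAUS, yaw_tilt_angle_deg=90.0),
            dict(time_constants=TAUS, yaw_tilt_angle_deg=-1.0),
            dict(time_constants=TAUS, yaw_gain=0.0),
            dict(time_constants=TAUS, yaw_tilt_direction="sideways"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_system_matrix(**kwargs)

    def test_stability(self):
        sm = build_system_matrix(TAUS, "left", 40.0, 1.7)
        assert sm.is_stable()


class TestEigenstructure:
    def test_diagonal_time_constants(self):
        sm = SystemMatrix(np.diag([-1 / 15, -1 / 8, -1 / 20]), tau_ref=(15, 8, 20))
        es = eigenstructure(sm)
        assert es.tau_roll == pytest.approx(15)
        assert es.tau_pitch == pytest.approx(8)
        assert es.tau_yaw == pytest.approx(20)
        assert es.yaw_gain == pytest.approx(1.0)
        np.testing.assert_allclose(es.ev_yaw.as_array(), [0, 0, 1], atol=1e-12)

    def test_round_trip_recovers_parameters(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            direction = rng.choice(["forward", "back", "left", "right"])
            angle = rng.uniform(0.1, 45.0)
            gain = rng.uniform(0.5, 2.0)
            taus = tuple(rng.uniform(4.0, 30.0, 3))
            lam = [-1 / taus[0], -1 / taus[1], -gain / taus[2]]
            if min(abs(a - b) for a, b in
                   [(lam[0], lam[1]), (lam[0], lam[2]), (lam[1], lam[2])]) < 1e-4:
                continue  # keep eigenvalues distinct so the basis is unique
            sm = build_system_matrix(taus, direction, angle, gain)
            es = eigenstructure(sm)
            assert es.yaw_tilt_deg == pytest.approx(angle, abs=1e-9)
            assert es.yaw_gain == pytest.approx(gain, abs=1e-9)
            M, _ = misalignment(es)
            expected_azimuth = {
                "forward": Vec3(0, 1, 0),
                "back": Vec3(0, -1, 0),
                "left": Vec3(-1, 0, 0),
                "right": Vec3(1, 0, 0),
            }[direction]
            np.testing.assert_allclose(
                M.unit().as_array(), expected_azimuth.as_array(), atol=1e-9
            )

    def test_all_shifted_non_orthogonal_basis_accepted(self):
        # every eigenvector off its axis: a fully maladapted state
        from mddskit import system_matrix_from_yaw_vector

        sm = system_matrix_from_yaw_vector(
            TAUS,
            Vec3(0.2, 0.1, 0.97).unit(),
            ev_roll=Vec3(0.98, 0.1, 0.15).unit(),
            ev_pitch=Vec3(-0.1, 0.99, 0.1).unit(),
        )
        assert sm.h_yr != 0.0 and sm.h_yp != 0.0
        es = eigenstructure(sm)
        assert es.ev_roll.x > 0.9 and es.ev_pitch.y > 0.9 and es.ev_yaw.z > 0.9

    def test_complex_eigenvalues_rejected(self):
        H = np.array([[-0.1, 1.0, 0.0], [-1.0, -0.1, 0.0], [0.0, 0.0, -0.05]])
        with pytest.raises(ComplexEigenvalueError):
            eigenstructure(SystemMatrix(H))

    def test_repeated_eigenvalues_rejected(self):
        with pytest.raises(AmbiguousEigenvectorError):
            eigenstructure(SystemMatrix(np.diag([-0.1, -0.1, -0.05])))

    def test_unstable_rejected(self):
        with pytest.raises(ValueError):
            eigenstructure(SystemMatrix(np.diag([0.1, -0.2, -0.3])))


class TestMisalignment:
    def test_forward_tilt_vector_out_of_left_ear(self):
        es = eigenstructure(build_system_matrix(TAUS, "forward", 10.0))
        M, tilt = misalignment(es)
        assert M.y > 0 and abs(M.x) < 1e-12  # +Y: out of the left ear
        assert M.norm == pytest.approx(math.sin(math.radians(10)), abs=1e-9)
        assert tilt == pytest.approx(10.0, abs=1e-9)

    def test_back_tilt_vector_into_left_ear(self):
        es = eigenstructure(build_system_matrix(TAUS, "back", 10.0))
        M, _ = misalignment(es)
        assert M.y < 0

    def test_aligned_gives_zero(self):
        es = eigenstructure(build_system_matrix(TAUS))
        M, tilt = misalignment(es)
        assert M.norm == pytest.approx(0.0, abs=1e-12)
        assert tilt == pytest.approx(0.0, abs=1e-9)


class TestSimulate:
    def test_zero_input_stays_zero(self):
        df = simulate(build_system_matrix(TAUS), dt=0.01, duration=5.0)
        assert np.allclose(df[["x_roll", "x_pitch", "x_yaw"]], 0.0)
        assert np.allclose(df[["y_roll", "y_pitch", "y_yaw"]], 0.0)

    def test_okan_decays_with_storage_time_constant(self):
        # yaw OKS step, then darkness: stored velocity discharges as exp(-t/tau)
        sm = build_system_matrix((12.0, 8.0, 15.0), yaw_gain=1.0)
        df = simulate(
            sm, omega_oks=[(0.0, 20.0, Vec3(0, 0, 10.0))], dt=1e-3, duration=50.0
        )
        off = df[df.t >= 20.0]
        x0 = off.x_yaw.iloc[0]
        expected = x0 * np.exp(-(off.t.to_numpy() - 20.0) / 15.0)
        rel = np.max(np.abs(off.x_yaw.to_numpy() - expected)) / abs(x0)
        assert rel < 1e-3

    def test_cross_coupling_reaches_analytic_steady_state(self):
        # lateral maladaptation: pure yaw OKS charges roll/pitch storage
        sm = build_system_matrix(TAUS, "right", 20.0)
        assert sm.h_yp != 0.0
        w = np.array([0.0, 0.0, 10.0])
        df = simulate(sm, omega_oks=Vec3(*w), dt=1e-3, duration=300.0)
        xss = -np.linalg.solve(sm.H, np.eye(3) @ w)
        np.testing.assert_allclose(
            df[["x_roll", "x_pitch", "x_yaw"]].iloc[-1], xss, rtol=1e-4, atol=1e-6
        )
        assert abs(xss[1]) > 0.1  # genuinely cross-coupled

    def test_matches_matrix_exponential_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            taus = rng.uniform(5.0, 25.0, 3)
            sm = build_system_matrix(
                tuple(taus),
                rng.choice(["forward", "back", "left", "right"]),
                rng.uniform(0, 40),
                rng.uniform(0.5, 2.0),
            )
            w = rng.uniform(-10, 10, 3)
            t_off = 7.0
            df = simulate(
                sm, omega_oks=[(0.0, t_off, Vec3(*w))], dt=1e-3, duration=15.0
            )
            H = sm.H
            x_off = np.linalg.solve(H, (expm(H * t_off) - np.eye(3)) @ w)
            for tq in (3.0, t_off, 12.0):
                if tq <= t_off:
                    ref = np.linalg.solve(H, (expm(H * tq) - np.eye(3)) @ w)
                else:
                    ref = expm(H * (tq - t_off)) @ x_off
                got = df[np.isclose(df.t, tq)].iloc[0][
                    ["x_roll", "x_pitch", "x_yaw"]
                ].to_numpy(float)
                err = np.max(np.abs(got - ref)) / max(np.max(np.abs(ref)), 1e-12)
                assert err < 1e-6

    def test_direct_path_in_output(self):
        sm = build_system_matrix(TAUS)
        df = simulate(sm, omega_scc=Vec3(0, 0, 5.0), dt=0.01, duration=1.0)
        # y = G1 w + x: at t=0 the direct path is already present
        assert df.y_yaw.iloc[0] == pytest.approx(5.0)
        assert df.x_yaw.iloc[0] == 0.0

    def test_custom_gains_scale_charging(self):
        sm = build_system_matrix(TAUS)
        g = GainMatrices(G2=0.5 * np.eye(3))
        df_half = simulate(sm, gains=g, omega_oks=Vec3(0, 0, 10), dt=0.01, duration=5)
        df_full = simulate(sm, omega_oks=Vec3(0, 0, 10), dt=0.01, duration=5)
        assert df_half.x_yaw.iloc[-1] == pytest.approx(0.5 * df_full.x_yaw.iloc[-1])

    def test_unstable_matrix_rejected(self):
        with pytest.raises(ValueError):
            simulate(SystemMatrix(np.diag([0.1, -0.2, -0.3])), dt=0.01, duration=1.0)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate(build_system_matrix(TAUS), dt=0.0, duration=1.0)


class TestAdapt:
    PULL_CASES = {
        # tilt direction of the eigenvector -> prescribed OKS / antipode
        "forward": (OKSDirection.UP, OKSDirection.DOWN),
        "back": (OKSDirection.DOWN, OKSDirection.UP),
        "right": (OKSDirection.RIGHT, OKSDirection.LEFT),
        "left": (OKSDirection.LEFT, OKSDirection.RIGHT),
    }

    @pytest.mark.parametrize("tilt_dir", list(PULL_CASES))
    def test_prescribed_oks_shrinks_tilt_antipode_grows_it(self, tilt_dir):
        good, bad = self.PULL_CASES[tilt_dir]
        sm = build_system_matrix(TAUS, tilt_dir, 10.0)
        prev_good, prev_bad = 10.0, 10.0
        for dur in (1.0, 5.0, 15.0, 60.0):
            tg = eigenstructure(adapt(sm, good, dur)).yaw_tilt_deg
            tb = eigenstructure(adapt(sm, bad, dur)).yaw_tilt_deg
            assert tg < prev_good
            assert tb > prev_bad
            prev_good, prev_bad = tg, tb

    def test_azimuth_unchanged_by_adaptation(self):
        sm = build_system_matrix(TAUS, "forward", 12.0)
        es = eigenstructure(adapt(sm, OKSDirection.UP, 5.0))
        M, _ = misalignment(es)
        np.testing.assert_allclose(M.unit().as_array(), [0, 1, 0], atol=1e-9)

    @pytest.mark.parametrize("gain, good, bad", [(0.8, "up", "down"), (1.2, "down", "up")])
    def test_vertical_oks_corrects_gain(self, gain, good, bad):
        sm = build_system_matrix(TAUS, yaw_gain=gain)
        prev_g, prev_b = abs(gain - 1), abs(gain - 1)
        for dur in (1.0, 10.0, 60.0):
            gg = eigenstructure(adapt(sm, good, dur)).yaw_gain
            gb = eigenstructure(adapt(sm, bad, dur)).yaw_gain
            assert abs(gg - 1) < prev_g
            assert abs(gb - 1) > prev_b
            prev_g, prev_b = abs(gg - 1), abs(gb - 1)

    def test_aligned_state_returned_unchanged(self):
        sm = build_system_matrix(TAUS)
        out = adapt(sm, OKSDirection.LEFT, 10.0)
        np.testing.assert_allclose(out.H, sm.H, atol=1e-12)

    def test_orthogonal_oks_has_no_effect(self):
        sm = build_system_matrix(TAUS, "forward", 10.0)
        out = adapt(sm, OKSDirection.LEFT, 10.0)
        assert eigenstructure(out).yaw_tilt_deg == pytest.approx(10.0, abs=1e-9)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            adapt(build_system_matrix(TAUS), OKSDirection.UP, -1.0)
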