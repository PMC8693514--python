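"""Forward kinematics, scaling, filtering, registration."""

import numpy as np
import pytest

from macgrip.forces import moment_arms, muscle_length
from macgrip.kinematics import (
    JointTrajectory,
    MarkerTrajectorySet,
    differentiate_trajectory,
    filter_markers,
    forward_kinematics,
    index_finger_length,
    polyfit_trajectory,
    read_markers_csv,
    read_trc,
    register_frame,
    register_trial,
    scale_model,
    write_markers_csv,
    write_trc,
)
from macgrip.model import rot_axis
from macgrip.synth import SynthConfig, generate_joint_trajectory, synthesize_markers


class TestForwardKinematics:
    def test_reference_pose_is_identity_orientation(self, model):
        st = forward_kinematics(model, np.zeros(model.n_q))
        for d in (2, 3, 4, 5):
            assert np.allclose(st.R[f"{d}DP"], np.eye(3), atol=1e-12)

    def test_wrong_q_length_rejected(self, model):
        with pytest.raises(ValueError, match="length"):
            forward_kinematics(model, np.zeros(3))

    def test_hinge_rotation_chord_displacement(self, model):
        """A point at distance L from a hinge displaces by 2 L sin(theta/2)."""
        theta = 0.4
        q = np.zeros(model.n_q)
        st0 = forward_kinematics(model, q)
        q[model.q_index("2DIP", "fe")] = theta
        st1 = forward_kinematics(model, q)
        tip0 = st0.point(*model.landmarks["2DP_tip"])
        tip1 = st1.point(*model.landmarks["2DP_tip"])
        # distance of the tip from the DIP axis
        j = model.joint_for_child("2DP")
        c = st0.p["2MP"] + st0.R["2MP"] @ j.center_mm
        L = np.linalg.norm(np.delete(tip0 - c, 1))  # radial distance from y-axis
        assert np.linalg.norm(tip1 - tip0) == pytest.approx(
            2 * L * np.sin(theta / 2), rel=1e-9
        )

    def test_two_joint_planar_closed_form(self, model):
        """MCP+PIP flexion puts the DIP center at the planar two-link
        position (link lengths from the template)."""
        th1, th2 = -np.deg2rad(30), -np.deg2rad(45)
        q = np.zeros(model.n_q)
        q[model.q_index("2MCP", "fe")] = th1
        q[model.q_index("2PIP", "fe")] = th2
        st = forward_kinematics(model, q)
        st0 = forward_kinematics(model, np.zeros(model.n_q))
        jm = model.joint_for_child("2PP")
        mcp = st0.p["2MC"] + st0.R["2MC"] @ jm.center_mm
        l1 = np.linalg.norm((st0.p["2MP"] + st0.R["2MP"] @ model.joint_for_child("2DP").center_mm) - (st0.p["2PP"] + st0.R["2PP"] @ model.joint_for_child("2MP").center_mm))
        l1_ = np.linalg.norm((st0.p["2PP"] + st0.R["2PP"] @ model.joint_for_child("2MP").center_mm) - mcp)
        dip = st.p["2MP"] + st.R["2MP"] @ model.joint_for_child("2DP").center_mm
        # planar closed form in the x-z plane (positive rotation = extension,
        # rotation about +y tilts the distal direction toward +x)
        x = l1_ * np.sin(th1) + l1 * np.sin(th1 + th2)
        z = l1_ * np.cos(th1) + l1 * np.cos(th1 + th2)
        assert dip[0] - mcp[0] == pytest.approx(x, abs=1e-9)
        assert dip[2] - mcp[2] == pytest.approx(z, abs=1e-9)

    def test_base_pose_moves_everything_rigidly(self, model):
        q = np.zeros(model.n_q)
        R = rot_axis(np.array([0.0, 0.0, 1.0]), 0.3)
        p = np.array([5.0, -2.0, 1.0])
        st0 = forward_kinematics(model, q)
        st1 = forward_kinematics(model, q, base_pose=(R, p))
        tip0 = st0.point(*model.landmarks["2DP_tip"])
        tip1 = st1.point(*model.landmarks["2DP_tip"])
        assert np.allclose(tip1, p + R @ tip0, atol=1e-9)


class TestScaling:
    def test_identity_scale(self, model):
        m2 = scale_model(model, index_finger_length(model))
        assert index_finger_length(m2) == pytest.approx(index_finger_length(model))
        np.testing.assert_allclose(
            m2.joints[0].center_mm, model.joints[0].center_mm, rtol=1e-12
        )

    def test_double_scale_doubles_muscle_lengths(self, model):
        m2 = scale_model(model, 2.0 * index_finger_length(model))
        q = np.zeros(model.n_q)
        for name in ("FDS2", "EPL", "ADPt"):
            assert muscle_length(m2, q, name) == pytest.approx(
                2.0 * muscle_length(model, q, name), rel=1e-12
            )

    def test_double_scale_doubles_moment_arms(self, model, rng):
        q = rng.uniform(-0.2, 0.2, model.n_q)
        m2 = scale_model(model, 2.0 * index_finger_length(model))
        R1 = moment_arms(model, q).arms
        R2 = moment_arms(m2, q).arms
        np.testing.assert_allclose(R2, 2.0 * R1, rtol=1e-9, atol=1e-15)

    def test_masses_untouched(self, model):
        m2 = scale_model(model, 2.0 * index_finger_length(model))
        assert m2.segments["carpus"].mass_g == model.segments["carpus"].mass_g

    def test_nonpositive_target_rejected(self, model):
        with pytest.raises(ValueError):
            scale_model(model, 0.0)


class TestFiltering:
    def test_dc_preserved(self):
        x = np.full((200, 2), 7.5)
        y = filter_markers(x, 5.0, frame_rate=100.0)
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_passband_amplitude_preserved(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)[:, None]
        y = filter_markers(x, 5.0, frame_rate=100.0)
        mid = slice(200, 800)
        assert np.abs(y[mid, 0]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 20.0 * t)[:, None]
        y = filter_markers(x, 5.0, frame_rate=100.0)
        assert np.abs(y[200:800, 0]).max() < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            filter_markers(np.zeros((100, 3)), 60.0, frame_rate=100.0)


class TestPolynomialTrajectory:
    def test_cubic_data_reproduced_exactly(self):
        t = np.arange(50) / 10.0
        y = 2.0 - t + 0.5 * t**2 - 0.1 * t**3
        fit = polyfit_trajectory(y, 10.0, degree=3)
        assert fit.residual_rms(t, y) < 1e-10

    def test_analytic_derivative_of_quadratic(self):
        t = np.arange(50) / 10.0
        fit = polyfit_trajectory(t**2, 10.0, degree=2)
        np.testing.assert_allclose(fit.derivative(t, 1)[:, 0], 2 * t, atol=1e-9)

    def test_degree_must_be_below_sample_count(self):
        with pytest.raises(ValueError):
            polyfit_trajectory(np.zeros(4), 10.0, degree=5)


class TestDifferentiation:
    def test_linear_and_constant(self):
        q = np.outer(np.arange(100) * 0.01, [2.0, 0.0])
        traj = differentiate_trajectory(JointTrajectory(q=q, frame_rate=100.0))
        np.testing.assert_allclose(traj.qdot[:, 0], 2.0, atol=1e-9)
        np.testing.assert_allclose(traj.qddot[5:-5, 0], 0.0, atol=1e-7)
        np.testing.assert_allclose(traj.qdot[:, 1], 0.0, atol=1e-12)

    def test_sinusoid_second_derivative(self):
        w = 2 * np.pi * 2.0
        t = np.arange(300) / 100.0
        q = np.sin(w * t)[:, None]
        traj = differentiate_trajectory(JointTrajectory(q=q, frame_rate=100.0))
        mid = slice(10, 290)
        # two stacked central differences: relative error ~ (w h)^2 / 3
        bound = w**2 * (w / 100.0) ** 2 / 3.0 * 1.5
        np.testing.assert_allclose(traj.qddot[mid, 0], -(w**2) * q[mid, 0], atol=bound)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            differentiate_trajectory(JointTrajectory(q=np.zeros((2, 3)), frame_rate=10))


class TestRegistration:
    def _markers_at(self, model, q, base_pose=None):
        st = forward_kinematics(model, q, base_pose=base_pose)
        return {n: st.point(*model.landmarks[n]) for n in model.landmarks}

    def test_recovers_known_pose_from_perturbed_start(self, model):
        q_true = np.zeros(model.n_q)
        q_true[model.q_index("2MCP", "fe")] = -0.3
        q_true[model.q_index("2PIP", "fe")] = 0.12
        q_true[model.q_index("1CMC", "rud")] = 0.2
        markers = self._markers_at(model, q_true)
        q0 = q_true + np.deg2rad(5.0)
        q, dists = register_frame(model, markers, q0)
        # only landmark-observable coordinates are solved; unobserved digits
        # (no markers on rays 3-5) stay at their initial values
        from macgrip.kinematics import _solvable_axes

        mask = _solvable_axes(model, list(model.landmarks))
        assert np.abs(q[mask] - q_true[mask]).max() < 1e-6
        np.testing.assert_allclose(q[~mask], q0[~mask])
        assert dists.max() < 1e-6

    def test_one_dof_grid_search_oracle(self, model):
        """LM optimum matches a dense grid search over a single hinge."""
        q_true = np.zeros(model.n_q)
        idx = model.q_index("2DIP", "fe")
        q_true[idx] = -0.27
        markers = self._markers_at(model, q_true)
        mask = np.zeros(model.n_q, dtype=bool)
        mask[idx] = True

        def sumsq(v):
            q = np.zeros(model.n_q)
            q[idx] = v
            st = forward_kinematics(model, q)
            return sum(
                np.sum((st.point(*model.landmarks[n]) - markers[n]) ** 2)
                for n in markers
            )

        grid = np.linspace(-0.5, 0.5, 2001)
        best = grid[np.argmin([sumsq(v) for v in grid])]
        q, _ = register_frame(model, markers, np.zeros(model.n_q), solve_mask=mask)
        assert q[idx] == pytest.approx(best, abs=6e-4)  # grid spacing
        assert q[idx] == pytest.approx(-0.27, abs=1e-8)

    def test_noise_free_trial_bias_vanishes(self, model, short_config, short_trial):
        res = register_trial(model, short_trial.markers)
        assert res.mean_bias_mm < 1e-6
        np.testing.assert_allclose(
            res.trajectory.q, short_trial.truth_trajectory.q, atol=1e-8
        )

    def test_single_frame_sd_is_zero(self, model):
        markers = self._markers_at(model, np.zeros(model.n_q))
        mts = MarkerTrajectorySet(
            names=list(markers),
            positions=np.array([list(markers.values())]),
            frame_rate=100.0,
        )
        res = register_trial(model, mts)
        assert res.sd_bias_mm == 0.0

    def test_noisy_bias_scales_with_noise(self, model):
        """Mean bias under isotropic noise lands between 0.5 and 1.5 sigma
        (the LS fit absorbs part of the noise into the pose)."""
        sigma = 1.4
        cfg = SynthConfig(
            seed=5, duration_s=0.6, grip_onset_s=0.1, peak_s=0.3, release_s=0.5,
            marker_noise_mm=sigma,
        )
        traj = generate_joint_trajectory(model, cfg)
        markers = synthesize_markers(model, traj, sigma, seed=99)
        res = register_trial(model, markers)
        assert 0.5 * sigma < res.mean_bias_mm < 1.5 * sigma

    def test_bias_invariant_under_joint_rigid_transform(self, model):
        q_true = np.zeros(model.n_q)
        q_true[model.q_index("2MCP", "fe")] = -0.2
        rngl = np.random.default_rng(3)
        markers = self._markers_at(model, q_true)
        noisy = {n: p + rngl.normal(0, 1.0, 3) for n, p in markers.items()}
        _, d0 = register_frame(model, noisy, np.zeros(model.n_q))
        R = rot_axis(np.array([1.0, 2.0, 0.5]) / np.linalg.norm([1.0, 2.0, 0.5]), 0.8)
        p = np.array([10.0, -4.0, 2.0])
        moved = {n: p + R @ v for n, v in noisy.items()}
        _, d1 = register_frame(
            model, moved, np.zeros(model.n_q), base_pose=(R, p)
        )
        np.testing.assert_allclose(np.sort(d0), np.sort(d1), atol=1e-6)

    def test_reversed_time_gives_reversed_trajectory(self, model, short_trial):
        markers = short_trial.markers
        rev = MarkerTrajectorySet(
            names=list(markers.names),
            positions=markers.positions[::-1].copy(),
            frame_rate=markers.frame_rate,
        )
        fwd = register_trial(model, markers)
        bwd = register_trial(model, rev)
        np.testing.assert_allclose(
            bwd.trajectory.q[::-1], fwd.trajectory.q, atol=1e-6
        )


class TestMarkerIO:
    def _mts(self):
        rngl = np.random.default_rng(0)
        return MarkerTrajectorySet(
            names=["a", "b", "c"],
            positions=rngl.normal(0, 10, (20, 3, 3)),
            frame_rate=100.0,
        )

    def test_trc_round_trip(self, tmp_path):
        mts = self._mts()
        path = tmp_path / "m.trc"
        write_trc(mts, path)
        back = read_trc(path)
        assert back.names == mts.names
        assert back.frame_rate == mts.frame_rate
        np.testing.assert_allclose(back.positions, mts.positions, atol=1e-5)

    def test_csv_round_trip(self, tmp_path):
        mts = self._mts()
        path = tmp_path / "m.csv"
        write_markers_csv(mts, path)
        back = read_markers_csv(path)
        assert back.names == mts.names
        np.testing.assert_allclose(back.positions, mts.positions, atol=1e-9)
        assert back.frame_rate == pytest.approx(100.0)

    def test_nan_positions_rejected(self):
        pos = np.zeros((5, 2, 3))
        pos[2, 1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            MarkerTrajectorySet(names=["a", "b"], positions=pos, frame_rate=100.0)
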