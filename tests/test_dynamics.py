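"""Newton-Euler inverse dynamics against closed-form oracles."""

import numpy as np
import pytest

from macgrip.dynamics import (
    ExternalLoad,
    inverse_dynamics,
    lever_load_from_gauge,
    partition_torques,
)
from macgrip.kinematics import JointTrajectory
from macgrip.model import BoneSegment, HandModel, Joint, JointAxis


def _planar_two_link(m1=2.0, m2=1.0, l1=30.0, l2=20.0, i1=50.0, i2=20.0):
    """A planar 2-link pendulum chain built in the hand-model vocabulary:
    links along +z, rotating about y (so motion stays in the x-z plane).
    Masses g, lengths mm, inertias g*mm^2 (about the y-axis)."""
    segs = {
        "base": BoneSegment("base", None, 0.0, np.zeros(3), np.zeros(3)),
        "l1": BoneSegment("l1", "base", m1, np.array([0.0, i1, 0.0]), np.array([0.0, 0.0, l1 / 2])),
        "l2": BoneSegment("l2", "l1", m2, np.array([0.0, i2, 0.0]), np.array([0.0, 0.0, l2 / 2])),
    }
    y = np.array([0.0, 1.0, 0.0])
    joints = [
        Joint("j1", "base", "l1", "hinge", np.zeros(3), axes=[JointAxis(y, True, "fe")]),
        # joint 2 sits at the distal end of link 1, i.e. +l1/2 from the
        # mid-link frame origin of l1
        Joint("j2", "l1", "l2", "hinge", np.array([0.0, 0.0, l1 / 2]), axes=[JointAxis(y, True, "fe")]),
    ]
    return HandModel(segments=segs, joints=joints, muscles=[], extensor_nets=[],
                     gravity=(0.0, 0.0, 0.0))


def _two_link_lagrangian_tau(model, q, qd, qdd, g_vec):
    """Textbook planar two-link equations of motion (oracle).

    Angles measured from the +z axis, positive rotation about +y tilts the
    links toward +x; com at mid-link.  SI units."""
    m1 = model.segments["l1"].mass_g * 1e-3
    m2 = model.segments["l2"].mass_g * 1e-3
    l1 = model.segments["l1"].origin_offset_mm[2] * 2e-3
    lc1 = l1 / 2
    l2m = model.segments["l2"].origin_offset_mm[2] * 2e-3
    lc2 = l2m / 2
    I1 = model.segments["l1"].inertia_gmm2[1] * 1e-9
    I2 = model.segments["l2"].inertia_gmm2[1] * 1e-9
    gx = g_vec[0]  # gravity along +x (the flexion plane)
    th1, th2 = q
    d11 = I1 + I2 + m1 * lc1**2 + m2 * (l1**2 + lc2**2 + 2 * l1 * lc2 * np.cos(th2))
    d12 = I2 + m2 * (lc2**2 + l1 * lc2 * np.cos(th2))
    d22 = I2 + m2 * lc2**2
    h = -m2 * l1 * lc2 * np.sin(th2)
    c1 = h * qd[1] ** 2 + 2 * h * qd[0] * qd[1]
    c2 = -h * qd[0] ** 2
    # potential: com height along -gx direction; torque = dV/dth
    g1 = -gx * (m1 * lc1 + m2 * l1) * np.cos(th1) - gx * m2 * lc2 * np.cos(th1 + th2)
    g2 = -gx * m2 * lc2 * np.cos(th1 + th2)
    tau1 = d11 * qdd[0] + d12 * qdd[1] + c1 + g1
    tau2 = d12 * qdd[0] + d22 * qdd[1] + c2 + g2
    return np.array([tau1, tau2])


class TestStatics:
    def test_rest_without_load_or_gravity_gives_zero_torque(self, model):
        traj = JointTrajectory(q=np.zeros((1, model.n_q)), frame_rate=100.0)
        torq = inverse_dynamics(model, traj, gravity=(0, 0, 0))
        assert np.abs(torq.torques_Nm).max() < 1e-15

    def test_point_load_moment_arm(self, model):
        """A 1.5 N force perpendicular to a hinge at 20 mm lever arm loads
        that hinge with 0.030 N*m."""
        traj = JointTrajectory(q=np.zeros((1, model.n_q)), frame_rate=100.0)
        j = model.joint_for_child("2MP")  # 2PIP center at z = L/2 in 2PP
        pp = model.segments["2PP"]
        # application point 20 mm distal of the PIP center on the 2MP axis
        point = np.array([0.0, 0.0, 20.0 - pp.origin_offset_mm[2] + j.center_mm[2] - pp.origin_offset_mm[2]])
        load = ExternalLoad("2MP", np.array([0.0, 0.0, 20.0 - model.segments["2MP"].origin_offset_mm[2]]), np.array([[1.5, 0.0, 0.0]]))
        torq = inverse_dynamics(model, traj, loads=[load], gravity=(0, 0, 0))
        i = model.q_index("2PIP", "fe")
        assert torq.torques_Nm[0, i] == pytest.approx(-0.030, rel=1e-9)

    def test_linearity_in_external_loads(self, model, rng):
        q = rng.uniform(-0.2, 0.2, model.n_q)[None, :]
        traj = JointTrajectory(q=q, frame_rate=100.0)
        f1 = ExternalLoad("2DP", np.array([0, 0, 5.0]), np.array([[1.0, 0.5, 0.0]]))
        f2 = ExternalLoad("1DP", np.array([0, 2.0, 5.0]), np.array([[-0.5, 1.0, 0.2]]))
        both = inverse_dynamics(model, traj, loads=[f1, f2], gravity=(0, 0, 0))
        t1 = inverse_dynamics(model, traj, loads=[f1], gravity=(0, 0, 0))
        t2 = inverse_dynamics(model, traj, loads=[f2], gravity=(0, 0, 0))
        np.testing.assert_allclose(
            both.torques_Nm, t1.torques_Nm + t2.torques_Nm, atol=1e-12
        )

    def test_reversed_load_negates_torques(self, model):
        traj = JointTrajectory(q=np.zeros((1, model.n_q)), frame_rate=100.0)
        f = ExternalLoad("2DP", np.array([0, 0, 5.0]), np.array([[1.0, 0.2, -0.3]]))
        fneg = ExternalLoad("2DP", np.array([0, 0, 5.0]), -np.array([[1.0, 0.2, -0.3]]))
        t1 = inverse_dynamics(model, traj, loads=[f], gravity=(0, 0, 0))
        t2 = inverse_dynamics(model, traj, loads=[fneg], gravity=(0, 0, 0))
        np.testing.assert_allclose(t2.torques_Nm, -t1.torques_Nm, atol=1e-15)


class TestTwoLinkOracle:
    @pytest.mark.parametrize("gx", [0.0, -9.81])
    def test_newton_euler_matches_lagrangian_closed_form(self, gx):
        chain = _planar_two_link()
        chain.gravity = np.array([gx, 0.0, 0.0])
        t = np.arange(200) / 100.0
        q = np.column_stack(
            [0.6 * np.sin(2 * np.pi * 1.3 * t), 0.9 * np.sin(2 * np.pi * 0.7 * t + 0.4)]
        )
        qd = np.column_stack(
            [
                0.6 * 2 * np.pi * 1.3 * np.cos(2 * np.pi * 1.3 * t),
                0.9 * 2 * np.pi * 0.7 * np.cos(2 * np.pi * 0.7 * t + 0.4),
            ]
        )
        qdd = np.column_stack(
            [
                -0.6 * (2 * np.pi * 1.3) ** 2 * np.sin(2 * np.pi * 1.3 * t),
                -0.9 * (2 * np.pi * 0.7) ** 2 * np.sin(2 * np.pi * 0.7 * t + 0.4),
            ]
        )
        traj = JointTrajectory(q=q, frame_rate=100.0, qdot=qd, qddot=qdd)
        torq = inverse_dynamics(chain, traj)
        for i in range(0, 200, 17):
            oracle = _two_link_lagrangian_tau(chain, q[i], qd[i], qdd[i], chain.gravity)
            np.testing.assert_allclose(torq.torques_Nm[i], oracle, rtol=1e-9, atol=1e-15)

    def test_zero_motion_zero_gravity_zero_torque(self):
        chain = _planar_two_link()
        traj = JointTrajectory(q=np.zeros((3, 2)), frame_rate=100.0)
        torq = inverse_dynamics(chain, traj)
        assert np.abs(torq.torques_Nm).max() < 1e-18


class TestPartition:
    def test_free_vector_has_fourteen_axes(self, model):
        traj = JointTrajectory(q=np.zeros((2, model.n_q)), frame_rate=100.0)
        torq = inverse_dynamics(model, traj)
        part = partition_torques(torq, model)
        assert part.free_Nm.shape == (2, 14)
        assert part.reaction_Nm.shape == (2, 7)

    def test_all_axes_free_empties_reaction_report(self, model):
        m = model.copy()
        for j in m.joints:
            for ax in j.axes:
                ax.free = True
        traj = JointTrajectory(q=np.zeros((1, m.n_q)), frame_rate=100.0)
        part = partition_torques(inverse_dynamics(m, traj), m)
        assert part.reaction_Nm.shape[1] == 0
        assert len(part.reaction_report()) == 0

    def test_thumb_load_confines_torques_to_thumb_joints(self, model):
        traj = JointTrajectory(q=np.zeros((1, model.n_q)), frame_rate=100.0)
        load = ExternalLoad("1DP", np.array([0.0, 2.0, 5.0]), np.array([[0.0, -2.0, 0.0]]))
        torq = inverse_dynamics(model, traj, loads=[load], gravity=(0, 0, 0))
        for k, (joint, _axis) in enumerate(torq.labels):
            if not joint.startswith("1"):
                assert abs(torq.torques_Nm[0, k]) < 1e-15, joint


class TestLeverLoad:
    def test_zero_magnitudes_zero_load(self, model):
        load = lever_load_from_gauge(np.zeros(5), (1, 0, 0), model.levers["index"])
        assert np.abs(load.force_N).max() == 0.0

    def test_constant_magnitude_fixed_direction(self, model):
        load = lever_load_from_gauge(np.full(4, 2.0), (1.0, 0.0, 0.0), model.levers["index"])
        np.testing.assert_allclose(load.force_N, np.tile([2.0, 0, 0], (4, 1)))

    def test_non_unit_direction_normalized_with_warning(self, model):
        with pytest.warns(UserWarning, match="normaliz"):
            load = lever_load_from_gauge(np.ones(2), (2.0, 0.0, 0.0), model.levers["index"])
        np.testing.assert_allclose(load.force_N[0], [1.0, 0, 0])

    def test_negative_magnitudes_rejected(self, model):
        with pytest.raises(ValueError):
            lever_load_from_gauge(np.array([-1.0]), (1, 0, 0), model.levers["index"])
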