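"""Muscle lengths, moment arms, extensor-net transmission, static optimization."""

import numpy as np
import pytest

from macgrip.dynamics import TorqueTrajectory, inverse_dynamics
from macgrip.forces import (
    effective_moment_arms,
    extensor_branch_tensions,
    moment_arms,
    muscle_length,
    solve_frame,
    solve_trial,
    transmission_matrix,
)
from macgrip.kinematics import JointTrajectory, forward_kinematics
from macgrip.model import (
    BoneSegment,
    HandModel,
    Joint,
    JointAxis,
    MusclePath,
)


def _one_hinge_model(a=10.0, b=15.0):
    """Single hinge with a two-point muscle: origin at distance a proximal,
    insertion at distance b distal of the joint center, both on the axis
    plane (law-of-cosines geometry)."""
    segs = {
        "base": BoneSegment("base", None, 0.0, np.zeros(3), np.zeros(3)),
        "link": BoneSegment("link", "base", 1.0, np.ones(3), np.zeros(3)),
    }
    y = np.array([0.0, 1.0, 0.0])
    joints = [
        Joint("j", "base", "link", "hinge", np.array([0.0, 0.0, 0.0]),
              axes=[JointAxis(y, True, "fe")])
    ]
    muscles = [
        MusclePath("mu", "mu", 1.0,
                   [("base", (0.0, 0.0, -a)), ("link", (0.0, 0.0, b))])
    ]
    return HandModel(segments=segs, joints=joints, muscles=muscles, extensor_nets=[])


class TestMuscleLength:
    def test_law_of_cosines_over_a_hinge(self):
        a, b = 10.0, 15.0
        m = _one_hinge_model(a, b)
        for theta in (0.0, 0.3, -0.5, 1.2):
            L = muscle_length(m, np.array([theta]), "mu")
            expected = np.sqrt(a**2 + b**2 - 2 * a * b * np.cos(np.pi - theta))
            assert L == pytest.approx(expected, rel=1e-12)

    def test_reference_lengths_positive(self, model):
        q = np.zeros(model.n_q)
        for m in model.muscles:
            assert muscle_length(model, q, m.name) > 0

    def test_unknown_muscle_rejected(self, model):
        with pytest.raises(KeyError):
            muscle_length(model, np.zeros(model.n_q), "nope")


class TestMomentArms:
    def test_path_through_joint_center_has_zero_arm(self):
        m = _one_hinge_model()
        m.muscles[0].points = [("base", np.array([0.0, 0.0, -10.0])),
                               ("link", np.array([0.0, 0.0, 0.0]))]
        m._index()
        R = moment_arms(m, np.array([0.4]))
        assert abs(R.arms[0, 0]) < 1e-12

    def test_planar_arm_is_perpendicular_distance(self):
        # straight path offset x=-4 mm from a y-axis hinge: arm = 4 mm
        m = _one_hinge_model()
        m.muscles[0].points = [("base", np.array([-4.0, 0.0, -10.0])),
                               ("link", np.array([-4.0, 0.0, 12.0]))]
        m._index()
        R = moment_arms(m, np.array([0.0]))
        assert R.arms[0, 0] == pytest.approx(-4e-3, rel=1e-12)  # flexor side

    @pytest.mark.parametrize("seed", [0, 1])
    def test_geometric_equals_finite_difference_excursion(self, model, seed):
        """R[i, j] == -dL_j/dq_i by central differences, random poses."""
        rng = np.random.default_rng(seed)
        q = rng.uniform(-0.25, 0.25, model.n_q)
        R = moment_arms(model, q)
        dq = 1e-6
        free_idx = [model.q_index(j, a) for j, a in model.free_axes]
        for jcol, mus in enumerate(model.muscles[::7]):
            col = R.arms[:, model.muscle_names.index(mus.name)]
            for row, i in enumerate(free_idx):
                qp, qm = q.copy(), q.copy()
                qp[i] += dq
                qm[i] -= dq
                fd = -(muscle_length(model, qp, mus.name)
                       - muscle_length(model, qm, mus.name)) / (2 * dq) * 1e-3
                assert col[row] == pytest.approx(fd, abs=1e-6)


class TestExtensorNet:
    def test_unit_edc_tension_splits_per_published_coefficients(self, model):
        net = next(n for n in model.extensor_nets if n.digit == 2)
        out = extensor_branch_tensions(net, {"EDC2": 1.0})
        assert out["RB"] == pytest.approx(0.167, abs=1e-12)
        assert out["UB"] == pytest.approx(0.167, abs=1e-12)
        assert out["TE"] == pytest.approx(0.334, abs=1e-12)
        assert out["ES"] == pytest.approx(0.167, abs=1e-12)

    def test_all_four_contributors_at_unit_tension(self, model):
        net = next(n for n in model.extensor_nets if n.digit == 2)
        out = extensor_branch_tensions(
            net, {"EDC2": 1.0, "1PIO": 1.0, "1DIOr": 1.0, "1DIOu": 1.0}
        )
        assert out["ES"] == pytest.approx(1.166, abs=1e-12)
        assert out["TE"] == pytest.approx(out["RB"] + out["UB"], abs=1e-12)

    def test_zero_inputs_zero_branches(self, model):
        net = model.extensor_nets[0]
        out = extensor_branch_tensions(net, {m: 0.0 for m in net.muscles})
        assert all(v == 0.0 for v in out.values())

    def test_negative_tension_rejected(self, model):
        with pytest.raises(ValueError):
            extensor_branch_tensions(model.extensor_nets[0], {"EDC2": -1.0})

    def test_zero_coefficients_leave_direct_arms(self, model):
        q = np.zeros(model.n_q)
        R = moment_arms(model, q)
        m = model.copy()
        for net in m.extensor_nets:
            net.coefficients = {b: {} for b in net.coefficients}
        R_eff = effective_moment_arms(R, m.extensor_nets)
        np.testing.assert_allclose(R_eff.arms, R.arms, atol=1e-18)

    def test_two_route_torque_consistency(self, model, rng):
        """Folding branch arms through T equals computing branch tensions
        and applying branch arms directly (unit EDC2 tension)."""
        q = rng.uniform(-0.2, 0.2, model.n_q)
        R = moment_arms(model, q)
        net = next(n for n in model.extensor_nets if n.digit == 2)
        R_eff = effective_moment_arms(R, model.extensor_nets)
        jm = R.muscle_names.index("EDC2")
        route_a = R_eff.arms[:, jm]  # torque per unit EDC2 tension
        branch_t = extensor_branch_tensions(net, {"EDC2": 1.0})
        route_b = R.arms[:, jm].copy()
        for b, ten in branch_t.items():
            bi = R.branch_labels.index((2, b))
            route_b += R.branch_arms[:, bi] * ten
        np.testing.assert_allclose(route_a, route_b, atol=1e-15)


class TestSolveFrame:
    def test_zero_torque_gives_zero_forces(self):
        R = np.array([[1.0, 1.0]]) * 1e-3
        fs = solve_frame(R, np.zeros(1), np.array([1.0, 1.0]))
        assert np.abs(fs.forces_N).max() < 1e-9
        assert fs.objective == pytest.approx(0.0, abs=1e-20)
        assert fs.status == "optimal"

    def test_identical_muscles_share_equally(self):
        R = np.array([[1.0, 1.0]])
        fs = solve_frame(R, np.array([4.0]), np.array([1.0, 1.0]),
                         sigma_max=1e9, bounded=False)
        np.testing.assert_allclose(fs.forces_N, [2.0, 2.0], atol=1e-8)

    def test_stationarity_ratio_closed_form(self):
        """PCSA (1, 4) cm^2, unit arms, tau = 9: stationarity of the cubed
        stress gives f1/f2 = (p1/p2)^(3/2) hence f = (1, 8) N."""
        R = np.array([[1.0, 1.0]])
        fs = solve_frame(R, np.array([9.0]), np.array([1.0, 4.0]),
                         sigma_max=1e9, bounded=False)
        np.testing.assert_allclose(fs.forces_N, [1.0, 8.0], atol=1e-6)
        assert fs.residual_Nm < 1e-8
        assert fs.stationarity < 1e-6

    def test_zero_pcsa_muscle_pinned_to_zero(self):
        R = np.array([[1.0, 1.0]])
        fs = solve_frame(R, np.array([2.0]), np.array([1.0, 0.0]), sigma_max=100.0)
        assert fs.forces_N[1] == 0.0
        assert fs.forces_N[0] == pytest.approx(2.0, abs=1e-8)

    def test_force_bounds_respected(self):
        R = np.array([[1.0, 1.0]])
        pcsa = np.array([1.0, 1.0])
        fmax = pcsa * 23.0
        fs = solve_frame(R, np.array([30.0]), pcsa, fmax=fmax, sigma_max=23.0)
        assert (fs.forces_N <= 23.0 + 1e-8).all()
        assert fs.status == "optimal"

    def test_infeasible_demand_reported_with_axes(self):
        R = np.array([[1.0, 1.0], [0.0, 0.0]])
        fs = solve_frame(R, np.array([1.0, 5.0]), np.array([1.0, 1.0]),
                         sigma_max=23.0)
        assert fs.status == "infeasible"
        assert 1 in fs.violated_axes

    def test_optimum_unique_across_warm_starts(self, model, rng):
        n = model.n_paths
        q = rng.uniform(-0.2, 0.2, model.n_q)
        R = effective_moment_arms(moment_arms(model, q), model.extensor_nets).arms
        pcsa = model.pcsa_vector()
        tau = R[:, model.muscle_names.index("FDP2")] * 5.0  # feasible by construction
        a = solve_frame(R, tau, pcsa, sigma_max=model.sigma_max)
        b = solve_frame(R, tau, pcsa, sigma_max=model.sigma_max,
                        warm_start=rng.uniform(0, 5, n))
        assert a.status == b.status == "optimal"
        np.testing.assert_allclose(a.forces_N, b.forces_N, atol=1e-6)
        assert a.objective == pytest.approx(b.objective, rel=1e-6, abs=1e-12)

    def test_sublinear_scaling_of_optimal_forces(self):
        """Scaling tau by lambda scales the unbounded-optimum objective by
        lambda^3 (forces scale linearly when no bound is active and the
        active set is fixed)."""
        R = np.array([[1.0, 0.5]])
        pcsa = np.array([1.0, 2.0])
        base = solve_frame(R, np.array([4.0]), pcsa, sigma_max=1e9, bounded=False)
        for lam in (0.5, 0.25):
            scaled = solve_frame(R, np.array([4.0 * lam]), pcsa,
                                 sigma_max=1e9, bounded=False)
            assert scaled.objective == pytest.approx(
                lam**3 * base.objective, rel=1e-6
            )


class TestSolveTrial:
    def test_zero_torques_give_zero_forces(self, model):
        n = 3
        traj = JointTrajectory(q=np.zeros((n, model.n_q)), frame_rate=100.0)
        torq = inverse_dynamics(model, traj, gravity=(0, 0, 0))
        sol = solve_trial(model, traj, torq)
        assert np.abs(sol.forces_N).max() < 1e-9
        assert all(s == "optimal" for s in sol.statuses)

    def test_absent_muscles_never_carry_force(self, short_trial):
        sol = short_trial.truth_forces
        assert np.abs(sol.force("FDP1")).max() == 0.0
        assert np.abs(sol.force("CD2")).max() == 0.0

    def test_flexor_forces_peak_with_the_lever_force(self, short_trial, short_config):
        sol = short_trial.truth_forces
        peak_frame = int(round(short_config.peak_s * short_config.frame_rate_hz))
        for mus in ("FDS2", "FDP2"):
            f = sol.force(mus)
            assert abs(int(np.argmax(f)) - peak_frame) <= 2
            assert f.max() > 0.3

    def test_resolving_produced_torques_returns_same_forces(self, model, short_trial):
        """Re-solving the torques generated by a known solution returns the
        identical unique optimum."""
        from macgrip.kinematics import differentiate_trajectory

        traj = differentiate_trajectory(short_trial.truth_trajectory)
        torq = inverse_dynamics(
            model, traj,
            loads=__import__("macgrip.synth", fromlist=["lever_loads"]).lever_loads(
                model, short_trial.lever_forces
            ),
        )
        sol2 = solve_trial(model, traj, torq)
        np.testing.assert_allclose(
            sol2.forces_N, short_trial.truth_forces.forces_N, atol=1e-8
        )

    def test_branch_tensions_follow_transmission_matrix(self, model, short_trial):
        sol = short_trial.truth_forces
        net = next(n for n in model.extensor_nets if n.digit == 2)
        T = transmission_matrix(net, sol.muscle_names)
        i = sol.forces_N.shape[0] // 2
        expected = T @ sol.forces_N[i]
        for bi, b in enumerate(net.branches):
            assert sol.branch_tensions[(2, b)][i] == pytest.approx(
                expected[bi], abs=1e-12
            )

    def test_torque_balance_residual_within_tolerance(self, short_trial):
        assert short_trial.truth_forces.residual_Nm.max() <= 1e-8
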