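"""Muscle paths, moment arms and static optimization of muscle redundancy.

Moment arms follow the tendon-excursion definition R[i, j] = -dL_j/dq_i,
computed geometrically: the world-frame derivative of each via-point under a
joint axis is axis x (point - center), so each straight path segment that
crosses an axis contributes its lever about that axis exactly.  Extensor-
mechanism branches are inextensible transmitters: branch tension is a fixed
linear map T of the contributing muscle tensions, so branch moment arms fold
into the contributing muscles as R_eff = R_direct + R_branch @ T.

The muscle redundancy of each frame is resolved by minimizing the sum of
cubed muscle stresses sum_i (f_i / PCSA_i)^3 subject to torque balance
R_eff f = tau on the muscle-balanced axes and 0 <= f_i <= PCSA_i * sigma_max.
In stress variables s_i = f_i / PCSA_i the objective is smooth and strictly
convex on the positive orthant, so the solution is unique; muscles with zero
PCSA (absent in this species) are pinned to zero force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize, nnls

from .dynamics import TorqueTrajectory, partition_torques
from .kinematics import JointTrajectory, KinematicState, forward_kinematics
from .model import ExtensorNet, HandModel
from .units import MM_TO_M

EQUALITY_TOL_NM = 1e-8  # absolute torque-balance tolerance
BOUND_SLACK_N = 1e-8


# ---------------------------------------------------------------------------
# lengths and moment arms


def _path_points_world(state: KinematicState, points) -> np.ndarray:
    return np.array([state.point(seg, xyz) for seg, xyz in points])


def _path_length_mm(state: KinematicState, points) -> float:
    pw = _path_points_world(state, points)
    return float(np.linalg.norm(np.diff(pw, axis=0), axis=1).sum())


def muscle_length(model: HandModel, q: np.ndarray, muscle: str) -> float:
    """Musculotendon path length (mm) at configuration q: summed Euclidean
    distances between consecutive via points."""
    m = model.muscle(muscle)
    state = forward_kinematics(model, q)
    return _path_length_mm(state, m.points)


def _path_excursion_row(model, state, points, axis_indices) -> np.ndarray:
    """dL/dq_i (mm/rad) for the given axes, geometric route (vectorized)."""
    pw = _path_points_world(state, points)
    segs = np.diff(pw, axis=0)
    norms = np.linalg.norm(segs, axis=1)
    # guard zero-length segments (coincident via points)
    unit = np.where(norms[:, None] > 1e-12, segs / np.maximum(norms, 1e-12)[:, None], 0.0)
    idx = np.asarray(axis_indices, dtype=int)
    masks = np.array([model.ancestor_mask(seg)[idx] for seg, _ in points])  # (k, n_ax)
    S = state.axis_world[idx]  # (n_ax, 3)
    C = state.center_world[idx]
    rel = pw[:, None, :] - C[None, :, :]  # (k, n_ax, 3)
    dp = np.cross(S[None, :, :], rel) * masks[:, :, None]
    d = dp[1:] - dp[:-1]  # (k-1, n_ax, 3)
    return np.einsum("kd,kid->i", unit, d)


@dataclass
class MomentArmMatrix:
    """Tendon-excursion moment arms (m) at one configuration.

    Rows are the muscle-balanced joint axes, columns muscle paths;
    ``branch_arms`` holds the extensor-net branch polylines as pseudo-columns
    prior to folding.
    """

    arms: np.ndarray  # (n_free, n_paths)
    axis_labels: list
    muscle_names: list
    branch_arms: np.ndarray  # (n_free, n_branches)
    branch_labels: list  # (digit, branch name)
    effective: bool = False

    def column(self, muscle: str) -> np.ndarray:
        return self.arms[:, self.muscle_names.index(muscle)]


def moment_arms(model: HandModel, q: np.ndarray, state: Optional[KinematicState] = None) -> MomentArmMatrix:
    """Geometric moment arms of every muscle path and net branch about every
    muscle-balanced axis, R = -dL/dq in meters."""
    if state is None:
        state = forward_kinematics(model, q)
    free_idx = [model.q_index(j, a) for j, a in model.free_axes]
    arms = np.zeros((len(free_idx), len(model.muscles)))
    for jcol, m in enumerate(model.muscles):
        arms[:, jcol] = -_path_excursion_row(model, state, m.points, free_idx) * MM_TO_M
    branch_labels = []
    cols = []
    for net in model.extensor_nets:
        for b, pts in net.branches.items():
            branch_labels.append((net.digit, b))
            cols.append(-_path_excursion_row(model, state, pts, free_idx) * MM_TO_M)
    branch_arms = np.array(cols).T if cols else np.zeros((len(free_idx), 0))
    return MomentArmMatrix(
        arms=arms,
        axis_labels=[tuple(lbl) for lbl in model.free_axes],
        muscle_names=model.muscle_names,
        branch_arms=branch_arms,
        branch_labels=branch_labels,
    )


# ---------------------------------------------------------------------------
# extensor-net transmission


def extensor_branch_tensions(net: ExtensorNet, tensions: dict) -> dict:
    """Branch tensions (N) from contributing muscle tensions (N): the linear
    load-transmission map of the dorsal aponeurosis (e.g. for the index,
    f_RB = 0.167 f_EDC2, f_UB = 0.167 f_EDC2 + 0.333 f_1PIO, f_TE = f_RB +
    f_UB)."""
    for m, t in tensions.items():
        if t < 0:
            raise ValueError(f"negative tension for {m}: {t}")
    out = {}
    for b, row in net.coefficients.items():
        out[b] = float(sum(c * tensions.get(m, 0.0) for m, c in row.items()))
    return out


def transmission_matrix(net: ExtensorNet, muscle_names: list) -> np.ndarray:
    """T with one row per branch (net.branches order) and one column per
    muscle in ``muscle_names``."""
    branches = list(net.branches.keys())
    T = np.zeros((len(branches), len(muscle_names)))
    for bi, b in enumerate(branches):
        for m, c in net.coefficients.get(b, {}).items():
            if m in muscle_names:
                T[bi, muscle_names.index(m)] = c
    return T


def effective_moment_arms(arm_matrix: MomentArmMatrix, nets: list) -> MomentArmMatrix:
    """Fold branch moment arms into the contributing muscles:
    R_eff = R_direct + R_branch @ T."""
    R_eff = arm_matrix.arms.copy()
    for net in nets:
        branches = list(net.branches.keys())
        bidx = [arm_matrix.branch_labels.index((net.digit, b)) for b in branches]
        if arm_matrix.branch_arms.shape[1] == 0:
            raise ValueError("arm matrix carries no branch pseudo-columns")
        Rb = arm_matrix.branch_arms[:, bidx]
        T = transmission_matrix(net, arm_matrix.muscle_names)
        R_eff += Rb @ T
    return MomentArmMatrix(
        arms=R_eff,
        axis_labels=arm_matrix.axis_labels,
        muscle_names=arm_matrix.muscle_names,
        branch_arms=arm_matrix.branch_arms,
        branch_labels=arm_matrix.branch_labels,
        effective=True,
    )


# ---------------------------------------------------------------------------
# static optimization


@dataclass
class FrameSolution:
    forces_N: np.ndarray
    objective: float  # sum of cubed stresses, (N/cm^2)^3
    residual_Nm: float  # max abs torque-balance violation
    status: str  # "optimal" | "infeasible" | "failed"
    stationarity: float
    violated_axes: list = field(default_factory=list)
    multipliers: Optional[np.ndarray] = None  # equality (torque) multipliers


def _dual_solve(A, tau, ub, lam0=None, max_iter=100):
    """Solve the cubed-stress program through its dual.

    On the positive orthant the KKT conditions give s_i(lam) =
    sqrt(max(a_i'lam, 0)/3) clipped to [0, ub]; the equality multipliers lam
    are then the root of A s(lam) = tau, found by damped semismooth Newton.
    Returns (s, lam, residual, converged).
    """
    n_ax = A.shape[0]
    if lam0 is None:
        # cold start: multipliers fitted to the stationarity of a
        # non-negative least-squares heuristic solution
        s0, _ = nnls(A, tau)
        s0 = np.minimum(s0, ub)
        interior = (s0 > 1e-12) & (s0 < ub - 1e-12)
        if interior.any():
            lam = np.linalg.lstsq(A[:, interior].T, 3.0 * s0[interior] ** 2, rcond=None)[0]
        else:
            lam = np.zeros(n_ax)
    else:
        lam = np.asarray(lam0, float).copy()
    s, sigma = _dual_s(A, lam, ub)
    Fn = np.linalg.norm(A @ s - tau)
    for _ in range(max_iter):
        if np.abs(A @ s - tau).max() < 1e-13:
            break
        responsive = (sigma > 0) & (s < ub)
        d = np.where(
            responsive, 1.0 / (2.0 * np.sqrt(3.0 * np.clip(sigma, 1e-14, None))), 0.0
        )
        J = (A * d) @ A.T
        rhs = tau - A @ s
        improved = False
        jscale = max(float(np.abs(J).max()), 1e-30)
        for mu in (1e-12, 1e-8 * jscale, 1e-4 * jscale, 1e-1 * jscale):
            try:
                step = np.linalg.solve(J + mu * np.eye(n_ax), rhs)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(J, rhs, rcond=None)
            t = 1.0
            while t > 1e-9:
                lam_t = lam + t * step
                s_t, sigma_t = _dual_s(A, lam_t, ub)
                Fn_t = np.linalg.norm(A @ s_t - tau)
                if Fn_t < Fn * (1.0 - 1e-4 * t) or Fn_t < 1e-13:
                    lam, s, sigma, Fn = lam_t, s_t, sigma_t, Fn_t
                    improved = True
                    break
                t *= 0.5
            if improved:
                break
        if not improved:
            break
    # canonicalize: the equality leaves lam free along the numerical null
    # space of J (directions that move no torque); zero those components so
    # the returned optimum does not depend on the iteration path
    res = float(np.abs(A @ s - tau).max())
    if res < 1e-11:
        for _ in range(2):
            responsive = (sigma > 0) & (s < ub)
            d = np.where(
                responsive,
                1.0 / (2.0 * np.sqrt(3.0 * np.clip(sigma, 1e-14, None))),
                0.0,
            )
            J = (A * d) @ A.T
            w, V = np.linalg.eigh(J)
            keep = w > max(float(w.max()), 1e-300) * 1e-9
            if keep.all():
                break
            Vk = V[:, keep]
            r = tau - A @ s
            lam_c = Vk @ (Vk.T @ lam) + Vk @ ((Vk.T @ r) / w[keep])
            s_c, sigma_c = _dual_s(A, lam_c, ub)
            res_c = float(np.abs(A @ s_c - tau).max())
            if res_c < 1e-11:
                lam, s, sigma, res = lam_c, s_c, sigma_c, res_c
            else:
                break
    return s, lam, res, res < 1e-10


def solve_frame(
    R_eff: np.ndarray,
    tau: np.ndarray,
    pcsa: np.ndarray,
    fmax: Optional[np.ndarray] = None,
    sigma_max: float = 23.0,
    warm_start: Optional[np.ndarray] = None,
    warm_multipliers: Optional[np.ndarray] = None,
    bounded: bool = True,
) -> FrameSolution:
    """Minimize sum((f_i/PCSA_i)^3) s.t. R_eff f = tau, 0 <= f <= Fmax.

    Solved in stress variables (uniform bounds [0, sigma_max]) through the
    dual Newton characterization of the unique optimum, falling back to
    SLSQP with a dual polish when the Newton iteration stalls; muscles with
    zero PCSA are pinned to zero force.  Infeasible torque demands are
    reported with the violated axes.
    """
    R_eff = np.asarray(R_eff, dtype=float)
    tau = np.asarray(tau, dtype=float).ravel()
    pcsa = np.asarray(pcsa, dtype=float).ravel()
    n_ax, n_mus = R_eff.shape
    if tau.shape[0] != n_ax:
        raise ValueError(f"tau length {tau.shape[0]} != {n_ax} axes")
    act = np.nonzero(pcsa > 0)[0]
    A = R_eff[:, act] * pcsa[act]  # torque per unit stress
    if bounded:
        ub = np.full(len(act), sigma_max)
        if fmax is not None:
            ub = np.minimum(ub, np.asarray(fmax, float)[act] / pcsa[act])
    else:
        ub = np.full(len(act), np.inf)

    # primary route: dual Newton on the KKT characterization
    lam0 = warm_multipliers
    if lam0 is None and warm_start is not None:
        sw = np.clip(np.asarray(warm_start, float)[act] / pcsa[act], 0.0, ub)
        interior = (sw > 1e-12) & (sw < ub - 1e-12)
        if interior.any():
            lam0, *_ = np.linalg.lstsq(
                A[:, interior].T, 3.0 * sw[interior] ** 2, rcond=None
            )
    s_d, lam_d, res_d, ok = _dual_solve(A, tau, ub, lam0=lam0)
    if res_d > 1e-12 and lam0 is not None:
        s_c, lam_c, res_c, ok_c = _dual_solve(A, tau, ub, lam0=None)
        if res_c < res_d:
            s_d, lam_d, res_d, ok = s_c, lam_c, res_c, ok_c
    if ok:
        forces = np.zeros(n_mus)
        forces[act] = s_d * pcsa[act]
        return FrameSolution(
            forces_N=forces,
            objective=float(np.sum(s_d**3)),
            residual_Nm=res_d,
            status="optimal",
            stationarity=_kkt_stationarity(A, s_d, ub),
            multipliers=lam_d,
        )

    # the dual iteration stalls on infeasible demands (no actuator on the
    # required side of an axis): project tau onto the attainable set and
    # solve the projected problem, reporting the unattainable remainder
    feasible, violated, slack = _feasibility_probe(A, tau, ub)
    if not feasible:
        tau_adj = tau - slack
        s_p, lam_p, res_p, ok_p = _dual_solve(A, tau_adj, ub, lam0=lam_d)
        if not ok_p:
            s_c, lam_c, res_c, ok_p = _dual_solve(A, tau_adj, ub, lam0=None)
            if res_c < res_p:
                s_p, lam_p, res_p = s_c, lam_c, res_c
        if ok_p:
            forces = np.zeros(n_mus)
            forces[act] = s_p * pcsa[act]
            return FrameSolution(
                forces_N=forces,
                objective=float(np.sum(s_p**3)),
                residual_Nm=float(np.abs(A @ s_p - tau).max()),
                status="infeasible",
                stationarity=_kkt_stationarity(A, s_p, ub),
                violated_axes=violated,
                multipliers=lam_p,
            )

    s0 = None
    if warm_start is not None:
        s0 = np.clip(np.asarray(warm_start, float)[act] / pcsa[act], 0.0, ub)
    if s0 is None:
        s0, _ = nnls(A, tau)
        s0 = np.clip(s0, 0.0, ub)

    def obj(s):
        return float(np.sum(s**3))

    def grad(s):
        return 3.0 * s**2

    bnds = [(0.0, ub[k]) for k in range(len(act))]
    sol = minimize(
        obj,
        s0,
        jac=grad,
        method="SLSQP",
        bounds=bnds,
        constraints=[{"type": "eq", "fun": lambda s: A @ s - tau, "jac": lambda s: A}],
        options={"maxiter": 400, "ftol": 1e-14},
    )
    s = np.clip(sol.x, 0.0, ub)
    resid = float(np.abs(A @ s - tau).max()) if n_ax else 0.0
    if resid > EQUALITY_TOL_NM:
        # retry from the non-negative least-squares start
        s1, _ = nnls(A, tau)
        sol2 = minimize(
            obj,
            np.clip(s1, 0.0, ub),
            jac=grad,
            method="SLSQP",
            bounds=bnds,
            constraints=[
                {"type": "eq", "fun": lambda s: A @ s - tau, "jac": lambda s: A}
            ],
            options={"maxiter": 400, "ftol": 1e-14},
        )
        s_alt = np.clip(sol2.x, 0.0, ub)
        if np.abs(A @ s_alt - tau).max() < resid:
            s = s_alt
            resid = float(np.abs(A @ s - tau).max())
    s = _newton_polish(A, tau, s, ub)
    resid = float(np.abs(A @ s - tau).max()) if n_ax else 0.0
    if res_d < resid:
        s, resid = s_d, res_d
    status = "optimal"
    violated = []
    if resid > EQUALITY_TOL_NM:
        feas, violated, _slack = _feasibility_probe(A, tau, ub)
        status = "infeasible" if not feas else "failed"
    forces = np.zeros(n_mus)
    forces[act] = s * pcsa[act]
    stationarity = _kkt_stationarity(A, s, ub)
    return FrameSolution(
        forces_N=forces,
        objective=float(np.sum(s**3)),
        residual_Nm=resid,
        status=status,
        stationarity=stationarity,
        violated_axes=violated,
    )


def _dual_s(A, lam, ub):
    """Primal stresses implied by equality multipliers lam: the unique
    stationary point s_i = sqrt(max(a_i'lam, 0)/3) clipped to the bounds."""
    sigma = A.T @ lam
    s = np.sqrt(np.clip(sigma, 0.0, None) / 3.0)
    return np.minimum(s, ub), sigma


def _newton_polish(A, tau, s, ub, max_iter=80):
    """Dual semismooth-Newton refinement of the cubed-stress optimum.

    The optimum is fully characterized by the equality multipliers lam via
    s_i = sqrt(max(a_i'lam, 0)/3) clipped to [0, ub]; driving the equality
    residual A s(lam) = tau to machine precision therefore lands exactly on
    the unique KKT point, making solves reproducible across warm starts.
    Falls back to the input if it cannot improve the residual (e.g. for an
    infeasible torque demand).
    """
    n_ax = A.shape[0]
    interior = (s > 1e-12) & (s < ub - 1e-12)
    if interior.any():
        lam, *_ = np.linalg.lstsq(A[:, interior].T, 3.0 * s[interior] ** 2, rcond=None)
    else:
        lam = np.zeros(n_ax)
    best_s, best_res = s, float(np.abs(A @ s - tau).max())
    cur, sigma = _dual_s(A, lam, ub)
    Fn = np.linalg.norm(A @ cur - tau)
    for _ in range(max_iter):
        res = float(np.abs(A @ cur - tau).max())
        if res < best_res:
            best_s, best_res = cur, res
        if res < 1e-13:
            break
        responsive = (sigma > 0) & (cur < ub)
        d = np.where(
            responsive, 1.0 / (2.0 * np.sqrt(3.0 * np.clip(sigma, 1e-14, None))), 0.0
        )
        J = (A * d) @ A.T
        try:
            step = np.linalg.solve(J + 1e-12 * np.eye(n_ax), tau - A @ cur)
        except np.linalg.LinAlgError:
            break
        improved = False
        t = 1.0
        while t > 1e-8:
            lam_t = lam + t * step
            s_t, sigma_t = _dual_s(A, lam_t, ub)
            Fn_t = np.linalg.norm(A @ s_t - tau)
            if Fn_t < Fn * (1.0 - 1e-4 * t) or Fn_t < 1e-13:
                lam, cur, sigma, Fn = lam_t, s_t, sigma_t, Fn_t
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    res = float(np.abs(A @ cur - tau).max())
    if res < best_res:
        best_s, best_res = cur, res
    return best_s


def _feasibility_probe(A, tau, ub):
    """Linear-programming feasibility of {A s = tau, 0 <= s <= ub}.

    Returns (feasible, violated axis indices, slack vector) where slack is
    the unattainable torque remainder per axis (zero when feasible).
    """
    n_ax, n = A.shape
    ubv = np.full(n, ub) if np.isscalar(ub) else np.asarray(ub, float)
    finite_ub = np.where(np.isfinite(ubv), ubv, None)
    c = np.concatenate([np.zeros(n), np.ones(2 * n_ax)])
    A_eq = np.hstack([A, np.eye(n_ax), -np.eye(n_ax)])
    bounds = [(0.0, u) for u in finite_ub] + [(0.0, None)] * (2 * n_ax)
    res = linprog(c, A_eq=A_eq, b_eq=tau, bounds=bounds, method="highs")
    if not res.success:
        return False, list(range(n_ax)), np.zeros(n_ax)
    slack = res.x[n : n + n_ax] - res.x[n + n_ax :]
    violated = [i for i in range(n_ax) if abs(slack[i]) > EQUALITY_TOL_NM]
    return res.fun <= n_ax * EQUALITY_TOL_NM, violated, slack


def _kkt_stationarity(A, s, ub) -> float:
    """Max stationarity violation over strictly interior variables after a
    least-squares fit of the equality multipliers."""
    interior = (s > 1e-9) & (s < ub - 1e-9)
    if not interior.any():
        return 0.0
    g = 3.0 * s**2
    At = A[:, interior].T
    lam, *_ = np.linalg.lstsq(At, g[interior], rcond=None)
    return float(np.abs(At @ lam - g[interior]).max())


# ---------------------------------------------------------------------------
# trial-level solve


@dataclass
class MuscleForceSolution:
    """Per-frame muscle tensions and solve diagnostics for a whole trial."""

    muscle_names: list
    forces_N: np.ndarray  # (n_frames, n_paths)
    objective: np.ndarray
    residual_Nm: np.ndarray
    statuses: list
    branch_tensions: dict  # (digit, branch) -> (n_frames,)
    frame_rate: float
    fmax_N: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.forces_N.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def force(self, muscle: str) -> np.ndarray:
        return self.forces_N[:, self.muscle_names.index(muscle)]

    def activation(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(self.fmax_N > 0, self.forces_N / self.fmax_N, 0.0)
        return a

    def to_frame(self) -> pd.DataFrame:
        act = self.activation()
        rec = []
        for i in range(self.n_frames):
            for k, m in enumerate(self.muscle_names):
                rec.append(
                    (
                        i,
                        m,
                        self.forces_N[i, k],
                        act[i, k],
                        self.objective[i],
                        self.residual_Nm[i],
                    )
                )
        return pd.DataFrame(
            rec,
            columns=["frame", "muscle", "force_N", "activation", "objective", "residual"],
        )


def solve_trial(
    model: HandModel,
    trajectory: JointTrajectory,
    torques: TorqueTrajectory,
    bounded: bool = True,
) -> MuscleForceSolution:
    """Per-frame static optimization over a trial: per-frame effective moment
    arms, warm-started cubed-stress solves, extensor-branch tensions."""
    if torques.n_frames != trajectory.n_frames:
        raise ValueError("trajectory and torque frame counts differ")
    part = partition_torques(torques, model)
    expected = [tuple(lbl) for lbl in model.free_axes]
    if part.free_labels != expected:
        raise ValueError("torque free-axis labels do not match the model")
    pcsa = model.pcsa_vector()
    fmax = model.fmax_vector()
    n = trajectory.n_frames
    forces = np.zeros((n, len(model.muscles)))
    objective = np.zeros(n)
    residual = np.zeros(n)
    statuses = []
    warm = None
    warm_lam = None
    for i in range(n):
        st = forward_kinematics(model, trajectory.q[i])
        arms = moment_arms(model, trajectory.q[i], state=st)
        R_eff = effective_moment_arms(arms, model.extensor_nets)
        fs = solve_frame(
            R_eff.arms,
            part.free_Nm[i],
            pcsa,
            fmax=fmax,
            sigma_max=model.sigma_max,
            warm_start=warm,
            warm_multipliers=warm_lam,
            bounded=bounded,
        )
        forces[i] = fs.forces_N
        objective[i] = fs.objective
        residual[i] = fs.residual_Nm
        statuses.append(fs.status)
        warm = fs.forces_N
        warm_lam = fs.multipliers
    branch = {}
    for net in model.extensor_nets:
        names = list(net.branches.keys())
        T = transmission_matrix(net, model.muscle_names)
        vals = forces @ T.T
        for bi, b in enumerate(names):
            branch[(net.digit, b)] = vals[:, bi]
    return MuscleForceSolution(
        muscle_names=model.muscle_names,
        forces_N=forces,
        objective=objective,
        residual_Nm=residual,
        statuses=statuses,
        branch_tensions=branch,
        frame_rate=trajectory.frame_rate,
        fmax_N=fmax,
    )
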