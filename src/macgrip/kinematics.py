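"""Forward kinematics, model scaling, marker processing and registration.

Motion reconstruction follows the standard model-based matching pipeline:
markers are low-pass filtered (5 Hz default), the model is uniformly scaled
to the subject from the index-finger length, and the generalized coordinates
q are found per frame by least squares, minimizing the summed squared
distances between each digitized landmark and the corresponding point on the
model (damped Gauss-Newton with the analytic chain Jacobian, warm-started
from the previous frame).  The matching bias of a trial is the mean over
markers and frames of the marker-to-model-point Euclidean distance.

Axes immobilized for inverse dynamics remain kinematic degrees of freedom
here; they are only excluded from muscle balance later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import least_squares

from .model import HandModel, rot_axis


# ---------------------------------------------------------------------------
# forward kinematics


class KinematicState:
    """Segment poses and joint-axis geometry at one configuration q.

    Positions are world mm; rotations world-from-segment.  ``axis_world`` and
    ``center_world`` give, per kinematic coordinate, the instantaneous world
    rotation axis and a point on it, which is all that point Jacobians and
    tendon-excursion moment arms need.
    """

    def __init__(self, model: HandModel, q: np.ndarray, R, p, axis_world, center_world):
        self.model = model
        self.q = q
        self.R = R
        self.p = p
        self.axis_world = axis_world
        self.center_world = center_world

    def point(self, segment: str, xyz_mm) -> np.ndarray:
        return self.p[segment] + self.R[segment] @ np.asarray(xyz_mm, dtype=float)

    def point_jacobian(self, segment: str, xyz_mm) -> np.ndarray:
        """d(world point)/dq, shape (3, n_q), mm per rad."""
        pw = self.point(segment, xyz_mm)
        J = np.zeros((3, self.model.n_q))
        idx = np.nonzero(self.model.ancestor_mask(segment))[0]
        if idx.size:
            J[:, idx] = np.cross(self.axis_world[idx], pw - self.center_world[idx]).T
        return J


def forward_kinematics(
    model: HandModel, q: np.ndarray, base_pose=None
) -> KinematicState:
    """Compose segment poses parent-to-child for configuration q (radians).

    ``base_pose`` is an optional (R, p_mm) pose of the root; identity by
    default (the hand is stationary in the grip task).
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_q,):
        raise ValueError(f"q has length {q.shape}, model expects ({model.n_q},)")
    R = {}
    p = {}
    axis_world = np.zeros((model.n_q, 3))
    center_world = np.zeros((model.n_q, 3))
    root = model.root
    if base_pose is None:
        R0, p0 = np.eye(3), np.zeros(3)
    else:
        R0, p0 = np.asarray(base_pose[0], float), np.asarray(base_pose[1], float)
    R[root] = R0
    p[root] = p0 + R0 @ model.segments[root].origin_offset_mm
    for j in model.joints:
        Rp, pp_ = R[j.parent], p[j.parent]
        c = pp_ + Rp @ j.center_mm
        Rj = Rp @ j.base_orientation
        sl = model._q_slice[j.name]
        for k, ax in enumerate(j.axes):
            i = sl.start + k
            axis_world[i] = Rj @ ax.vector
            center_world[i] = c
            Rj = Rj @ rot_axis(ax.vector, q[i])
        R[j.child] = Rj
        p[j.child] = c + Rj @ model.segments[j.child].origin_offset_mm
    return KinematicState(model, q, R, p, axis_world, center_world)


def index_finger_length(model: HandModel) -> float:
    """Index-finger length (mm): summed joint-center-to-joint-center spans
    MCP->PIP->DIP->fingertip at the reference pose.  Used for model scaling;
    the measurement is a documented package convention."""
    st = forward_kinematics(model, np.zeros(model.n_q))
    centers = {}
    for j in model.joints:
        centers[j.name] = st.p[j.parent] + st.R[j.parent] @ j.center_mm
    tip_seg, tip_xyz = model.landmarks["2DP_tip"]
    tip = st.point(tip_seg, tip_xyz)
    return float(
        np.linalg.norm(centers["2PIP"] - centers["2MCP"])
        + np.linalg.norm(centers["2DIP"] - centers["2PIP"])
        + np.linalg.norm(tip - centers["2DIP"])
    )


def scale_model(model: HandModel, target_index_length_mm: float) -> HandModel:
    """Uniformly scale all model geometry so the index finger has the target
    length.  Masses and inertias are left at their measured values (scaling
    is geometric registration, not a new cadaver)."""
    if not target_index_length_mm > 0:
        raise ValueError("target index-finger length must be positive")
    s = target_index_length_mm / index_finger_length(model)
    m = model.copy()
    for seg in m.segments.values():
        seg.origin_offset_mm = seg.origin_offset_mm * s
        seg.com_offset_mm = seg.com_offset_mm * s
    for j in m.joints:
        j.center_mm = j.center_mm * s
    for mus in m.muscles:
        mus.points = [(seg, xyz * s) for seg, xyz in mus.points]
    for net in m.extensor_nets:
        net.branches = {
            b: [(seg, xyz * s) for seg, xyz in pts] for b, pts in net.branches.items()
        }
    m.landmarks = {k: (seg, xyz * s) for k, (seg, xyz) in m.landmarks.items()}
    for lv in m.levers.values():
        lv.point_mm = lv.point_mm * s
    m._index()
    return m


# ---------------------------------------------------------------------------
# trajectories and marker sets


@dataclass
class MarkerTrajectorySet:
    """Named landmark trajectories: positions (n_frames, n_markers, 3) mm."""

    names: list
    positions: np.ndarray
    frame_rate: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1] != len(self.names):
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if not self.frame_rate > 0:
            raise ValueError("frame rate must be positive")
        if np.isnan(self.positions).any():
            raise ValueError("marker positions contain NaN (fill gaps first)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> dict:
        return {n: self.positions[i, k] for k, n in enumerate(self.names)}


@dataclass
class JointTrajectory:
    """Generalized coordinates over time, with derivatives.

    Sign convention: positive is extension (and adduction for the thumb CMC
    and the MCPs); trial-relative angles (zero at t = 0) are obtained with
    :meth:`relative_to_first_frame`.
    """

    q: np.ndarray
    frame_rate: float
    labels: list = field(default_factory=list)
    qdot: Optional[np.ndarray] = None
    qddot: Optional[np.ndarray] = None

    def __post_init__(self):
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if not self.frame_rate > 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.q.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def relative_to_first_frame(self) -> "JointTrajectory":
        return JointTrajectory(
            q=self.q - self.q[0],
            frame_rate=self.frame_rate,
            labels=self.labels,
            qdot=self.qdot,
            qddot=self.qddot,
        )


@dataclass
class RegistrationResult:
    trajectory: JointTrajectory
    bias_per_frame: np.ndarray  # mean marker distance per frame, mm
    distances: np.ndarray  # (n_frames, n_markers) mm

    @property
    def mean_bias_mm(self) -> float:
        return float(np.mean(self.bias_per_frame))

    @property
    def sd_bias_mm(self) -> float:
        return float(np.std(self.bias_per_frame, ddof=0))


# ---------------------------------------------------------------------------
# filtering / smoothing


def _butter_filtfilt(x: np.ndarray, cutoff: float, rate: float, btype="low"):
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz is not below Nyquist ({rate / 2} Hz)")
    sos = signal.butter(4, cutoff, btype=btype, fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def filter_markers(markers, cutoff_hz: float = 5.0, frame_rate: Optional[float] = None):
    """Zero-phase 4th-order Butterworth low-pass along time (DC preserved)."""
    if isinstance(markers, MarkerTrajectorySet):
        flat = markers.positions.reshape(markers.n_frames, -1)
        out = _butter_filtfilt(flat, cutoff_hz, markers.frame_rate)
        return MarkerTrajectorySet(
            names=list(markers.names),
            positions=out.reshape(markers.positions.shape),
            frame_rate=markers.frame_rate,
        )
    if frame_rate is None:
        raise ValueError("frame_rate required for raw arrays")
    return _butter_filtfilt(np.asarray(markers, float), cutoff_hz, frame_rate)


class PolynomialTrajectory:
    """Least-squares polynomial approximation with analytic derivatives."""

    def __init__(self, t: np.ndarray, series: np.ndarray, degree: int = 5):
        t = np.asarray(t, dtype=float)
        series = np.atleast_2d(np.asarray(series, dtype=float))
        if series.shape[0] != t.shape[0]:
            series = series.T
        if t.shape[0] <= degree:
            raise ValueError(
                f"need more than degree={degree} samples, got {t.shape[0]}"
            )
        self.degree = degree
        self._polys = []
        # mapped-domain Vandermonde conditioning (scaled Chebyshev-like fit
        # domains keep this small; warn if the fit is numerically doubtful)
        tm = np.interp(t, (t.min(), t.max()), (-1.0, 1.0)) if t.max() > t.min() else t
        cond = np.linalg.cond(np.vander(tm, degree + 1))
        if cond > 1e8:
            warnings.warn(
                f"polynomial degree {degree} is ill-conditioned "
                f"(condition estimate {cond:.2e})",
                stacklevel=2,
            )
        for col in series.T:
            self._polys.append(np.polynomial.Polynomial.fit(t, col, degree))

    def __call__(self, t):
        return np.column_stack([p(t) for p in self._polys])

    def derivative(self, t, order: int = 1):
        return np.column_stack([p.deriv(order)(t) for p in self._polys])

    def residual_rms(self, t, series) -> float:
        series = np.atleast_2d(np.asarray(series, float))
        if series.shape[0] != np.asarray(t).shape[0]:
            series = series.T
        return float(np.sqrt(np.mean((self(t) - series) ** 2)))


def polyfit_trajectory(series, frame_rate: float, degree: int = 5) -> PolynomialTrajectory:
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] == 1:
        series = series.T
    t = np.arange(series.shape[0]) / frame_rate
    return PolynomialTrajectory(t, series, degree)


def differentiate_trajectory(traj: JointTrajectory, mode: str = "central") -> JointTrajectory:
    """Fill qdot / qddot.

    "central": second-order central differences (one-sided at the ends);
    "polynomial": analytic derivatives of a degree-5 least-squares polynomial
    fitted per coordinate.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    dt = 1.0 / traj.frame_rate
    if mode == "central":
        qdot = np.gradient(traj.q, dt, axis=0)
        qddot = np.gradient(qdot, dt, axis=0)
    elif mode == "polynomial":
        fit = polyfit_trajectory(traj.q, traj.frame_rate)
        t = traj.times
        qdot = fit.derivative(t, 1)
        qddot = fit.derivative(t, 2)
    else:
        raise ValueError(f"unknown differentiation mode {mode!r}")
    return JointTrajectory(
        q=traj.q, frame_rate=traj.frame_rate, labels=traj.labels, qdot=qdot, qddot=qddot
    )


# ---------------------------------------------------------------------------
# registration (inverse kinematics)


def _solvable_axes(model: HandModel, names) -> np.ndarray:
    """Axes observable from the given landmarks: those proximal to at least
    one landmark-bearing segment."""
    mask = np.zeros(model.n_q, dtype=bool)
    for n in names:
        seg, _ = model.landmarks[n]
        mask |= model.ancestor_mask(seg)
    return mask


def register_frame(
    model: HandModel,
    markers: dict,
    q_init: np.ndarray,
    solve_mask: Optional[np.ndarray] = None,
    base_pose=None,
):
    """Fit q to one frame of markers by damped least squares.

    Returns (q, distances) where distances[k] is the residual Euclidean
    distance of marker k.  Coordinates outside ``solve_mask`` stay at q_init.
    """
    names = [n for n in markers if n in model.landmarks]
    if not names:
        raise ValueError("no markers correspond to model landmarks")
    q_init = np.asarray(q_init, dtype=float).copy()
    if solve_mask is None:
        solve_mask = _solvable_axes(model, names)
    idx = np.nonzero(solve_mask)[0]
    if 3 * len(names) < len(idx):
        raise ValueError(
            f"{len(names)} markers cannot determine {len(idx)} coordinates"
        )
    target = np.concatenate([np.asarray(markers[n], float) for n in names])

    def residual(x):
        q = q_init.copy()
        q[idx] = x
        st = forward_kinematics(model, q, base_pose=base_pose)
        pts = np.concatenate(
            [st.point(*model.landmarks[n]) for n in names]
        )
        return pts - target

    def jacobian(x):
        q = q_init.copy()
        q[idx] = x
        st = forward_kinematics(model, q, base_pose=base_pose)
        J = np.vstack([st.point_jacobian(*model.landmarks[n]) for n in names])
        return J[:, idx]

    sol = least_squares(
        residual,
        q_init[idx],
        jac=jacobian,
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success and np.linalg.norm(sol.grad, ord=np.inf) > 1e-6:
        raise RuntimeError(
            f"registration did not converge: {sol.message}; "
            f"residual norm {np.linalg.norm(sol.fun):.3g}"
        )
    q = q_init.copy()
    q[idx] = sol.x
    dists = np.linalg.norm(sol.fun.reshape(-1, 3), axis=1)
    return q, dists


def register_trial(
    model: HandModel,
    markers: MarkerTrajectorySet,
    q_init: Optional[np.ndarray] = None,
    solve_mask: Optional[np.ndarray] = None,
    base_pose=None,
) -> RegistrationResult:
    """Frame-sequential registration, warm-started from the previous frame."""
    names = [n for n in markers.names if n in model.landmarks]
    if solve_mask is None:
        solve_mask = _solvable_axes(model, names)
    q = np.zeros(model.n_q) if q_init is None else np.asarray(q_init, float).copy()
    qs = np.zeros((markers.n_frames, model.n_q))
    dists = np.zeros((markers.n_frames, len(names)))
    for i in range(markers.n_frames):
        frame = {n: markers.frame(i)[n] for n in names}
        q, d = register_frame(model, frame, q, solve_mask=solve_mask, base_pose=base_pose)
        qs[i] = q
        dists[i] = d
    traj = JointTrajectory(q=qs, frame_rate=markers.frame_rate, labels=list(model.q_labels))
    return RegistrationResult(
        trajectory=traj, bias_per_frame=dists.mean(axis=1), distances=dists
    )


# ---------------------------------------------------------------------------
# marker file I/O (TRC and long CSV)


def write_trc(markers: MarkerTrajectorySet, path) -> None:
    n_frames, n_mark, _ = markers.positions.shape
    rate = markers.frame_rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n_frames}\t{n_mark}\tmm\t{rate:g}\t1\t{n_frames}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(markers.names) + "\t\t\t\n")
        fh.write(
            "\t\t"
            + "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(n_mark))
            + "\n"
        )
        for i in range(n_frames):
            vals = "\t".join(f"{v:.6f}" for v in markers.positions[i].ravel())
            fh.write(f"{i + 1}\t{i / rate:.6f}\t{vals}\n")


def read_trc(path) -> MarkerTrajectorySet:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    meta = lines[2].split("\t")
    rate = float(meta[0])
    names = [n for n in lines[3].split("\t")[2:] if n]
    rows = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        rows.append([float(v) for v in parts[2 : 2 + 3 * len(names)]])
    positions = np.asarray(rows).reshape(len(rows), len(names), 3)
    return MarkerTrajectorySet(names=names, positions=positions, frame_rate=rate)


def write_markers_csv(markers: MarkerTrajectorySet, path, trial: str = "trial1") -> None:
    rec = []
    for i in range(markers.n_frames):
        t = i / markers.frame_rate
        for k, n in enumerate(markers.names):
            x, y, z = markers.positions[i, k]
            rec.append((trial, i, t, n, x, y, z))
    pd.DataFrame(
        rec, columns=["trial", "frame", "time_s", "landmark", "x_mm", "y_mm", "z_mm"]
    ).to_csv(path, index=False)


def read_markers_csv(path) -> MarkerTrajectorySet:
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["landmark"]))
    frames = sorted(df["frame"].unique())
    pos = np.zeros((len(frames), len(names), 3))
    for k, n in enumerate(names):
        sub = df[df["landmark"] == n].sort_values("frame")
        pos[:, k, :] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
    times = np.sort(df["time_s"].unique())
    rate = 1.0 / np.mean(np.diff(times)) if len(times) > 1 else 100.0
    return MarkerTrajectorySet(names=names, positions=pos, frame_rate=float(rate))
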