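"""Newton-Euler inverse dynamics of the hand chain with fingertip loads.

Net joint torques are computed by the recursive Newton-Euler algorithm over
the segment tree: an outward pass propagates angular velocity/acceleration
and linear acceleration (gravity folded into the base acceleration), and an
inward pass accumulates segment wrenches, external lever forces included.
The torque about each joint axis is the projection of the inter-segment
torque onto that axis.

Axes flagged immobile (MCP radio-ulnar deviation, both thumb-CMC axes) carry
their torque as a structural reaction and are excluded from muscle balance;
:func:`partition_torques` separates the two sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kinematics import JointTrajectory, forward_kinematics
from .model import HandModel, LeverContact
from .units import GMM2_TO_KGM2, G_TO_KG, MM_TO_M


@dataclass
class ExternalLoad:
    """A force applied to one segment: fixed application point (segment
    frame, mm), force vector per frame in the global frame (N)."""

    segment: str
    point_mm: np.ndarray
    force_N: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.point_mm = np.asarray(self.point_mm, dtype=float)
        self.force_N = np.atleast_2d(np.asarray(self.force_N, dtype=float))
        if not np.isfinite(self.force_N).all():
            raise ValueError("external load contains non-finite forces")

    @property
    def n_frames(self) -> int:
        return self.force_N.shape[0]


@dataclass
class TorqueTrajectory:
    """Net joint torque (N*m) about every kinematic axis, per frame."""

    torques_Nm: np.ndarray  # (n_frames, n_q)
    labels: list  # (joint, axis label) per column
    partition: list  # "free" | "immobilized" per column
    frame_rate: float
    gravity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_frames(self) -> int:
        return self.torques_Nm.shape[0]


@dataclass
class PartitionedTorques:
    free_Nm: np.ndarray  # (n_frames, n_free)
    free_labels: list
    reaction_Nm: np.ndarray
    reaction_labels: list

    def reaction_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "joint": [j for j, _ in self.reaction_labels],
                "axis": [a for _, a in self.reaction_labels],
                "peak_abs_torque_Nm": np.abs(self.reaction_Nm).max(axis=0)
                if self.reaction_Nm.size
                else [],
                "rms_torque_Nm": np.sqrt(np.mean(self.reaction_Nm**2, axis=0))
                if self.reaction_Nm.size
                else [],
            }
        )


def lever_load_from_gauge(
    magnitudes_N: np.ndarray,
    direction,
    contact: LeverContact | tuple,
) -> ExternalLoad:
    """Build an :class:`ExternalLoad` from a uniaxial gauge: the fingertip
    force is the measured magnitude along a fixed (global, horizontal) lever
    direction, applied at the configured contact point."""
    mags = np.asarray(magnitudes_N, dtype=float).ravel()
    if (mags < 0).any():
        raise ValueError("gauge magnitudes must be non-negative")
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if abs(n - 1.0) > 1e-9:
        warnings.warn(f"lever direction norm {n:.6g} != 1; normalizing", stacklevel=2)
        d = d / n
    if isinstance(contact, LeverContact):
        seg, pt = contact.segment, contact.point_mm
    else:
        seg, pt = contact
    return ExternalLoad(
        segment=seg,
        point_mm=pt,
        force_N=mags[:, None] * d[None, :],
        provenance="lever gauge",
    )


def _rnea(model: HandModel, q, qd, qdd, loads, gravity):
    """One-frame recursive Newton-Euler; returns torques per kinematic axis."""
    st = forward_kinematics(model, q)
    root = model.root
    # world-frame kinematic propagation (positions in m)
    omega = {root: np.zeros(3)}
    domega = {root: np.zeros(3)}
    acc = {root: -np.asarray(gravity, float)}  # base acceleration trick
    pos = {name: st.p[name] * MM_TO_M for name in model.segments}
    centers = {}
    for j in model.joints:
        c = (st.p[j.parent] + st.R[j.parent] @ j.center_mm) * MM_TO_M
        centers[j.name] = c
        r = c - pos[j.parent]
        w, dw = omega[j.parent], domega[j.parent]
        a_c = acc[j.parent] + np.cross(dw, r) + np.cross(w, np.cross(w, r))
        sl = model._q_slice[j.name]
        for k in range(len(j.axes)):
            i = sl.start + k
            s = st.axis_world[i]
            dw = dw + s * qdd[i] + np.cross(w, s) * qd[i]
            w = w + s * qd[i]
        omega[j.child], domega[j.child] = w, dw
        ro = pos[j.child] - c
        acc[j.child] = a_c + np.cross(dw, ro) + np.cross(w, np.cross(w, ro))

    loads_by_seg: dict = {}
    for ld, fvec in loads:
        loads_by_seg.setdefault(ld.segment, []).append((ld.point_mm, fvec))

    # inward pass: wrench transmitted at each child's proximal joint center
    f_joint = {}
    n_joint = {}
    children = {name: [] for name in model.segments}
    for j in model.joints:
        children[j.parent].append(j)
    order = [j for j in model.joints]
    for j in reversed(order):
        seg = model.segments[j.child]
        name = j.child
        c = centers[j.name]
        R = st.R[name]
        com = pos[name] + R @ (seg.com_offset_mm * MM_TO_M)
        w, dw = omega[name], domega[name]
        a_com = (
            acc[name]
            + np.cross(dw, com - pos[name])
            + np.cross(w, np.cross(w, com - pos[name]))
        )
        m = seg.mass_g * G_TO_KG
        I_w = R @ np.diag(seg.inertia_gmm2 * GMM2_TO_KGM2) @ R.T
        F = m * a_com
        N = I_w @ dw + np.cross(w, I_w @ w)
        f = F.copy()
        n = N + np.cross(com - c, F)
        for pt_mm, fvec in loads_by_seg.get(name, []):
            p_app = pos[name] + R @ (pt_mm * MM_TO_M)
            f -= fvec
            n -= np.cross(p_app - c, fvec)
        for jc in children[name]:
            f += f_joint[jc.name]
            n += n_joint[jc.name] + np.cross(centers[jc.name] - c, f_joint[jc.name])
        f_joint[j.name] = f
        n_joint[j.name] = n

    tau = np.zeros(model.n_q)
    for j in model.joints:
        sl = model._q_slice[j.name]
        for k in range(len(j.axes)):
            i = sl.start + k
            tau[i] = float(np.dot(st.axis_world[i], n_joint[j.name]))
    return tau


def inverse_dynamics(
    model: HandModel,
    trajectory: JointTrajectory,
    loads: Optional[list] = None,
    gravity=None,
) -> TorqueTrajectory:
    """Net joint torques from motion and external (lever) forces.

    ``trajectory`` must carry qdot/qddot (zeros assumed if absent: static).
    ``gravity`` defaults to the model's gravity vector (m/s^2); pass zeros to
    disable gravity.
    """
    loads = loads or []
    g = model.gravity if gravity is None else np.asarray(gravity, dtype=float)
    q = trajectory.q
    n = trajectory.n_frames
    qd = trajectory.qdot if trajectory.qdot is not None else np.zeros_like(q)
    qdd = trajectory.qddot if trajectory.qddot is not None else np.zeros_like(q)
    if qd.shape != q.shape or qdd.shape != q.shape:
        raise ValueError("q, qdot, qddot must have matching shapes")
    for ld in loads:
        if ld.segment not in model.segments:
            raise ValueError(f"external load references unknown segment {ld.segment}")
        if ld.n_frames not in (1, n):
            raise ValueError(
                f"load on {ld.segment} has {ld.n_frames} frames, trajectory has {n}"
            )
    out = np.zeros((n, model.n_q))
    for i in range(n):
        frame_loads = [
            (ld, ld.force_N[i] if ld.n_frames == n else ld.force_N[0]) for ld in loads
        ]
        out[i] = _rnea(model, q[i], qd[i], qdd[i], frame_loads, g)
    partition = []
    for j in model.joints:
        for ax in j.axes:
            partition.append("free" if ax.free else "immobilized")
    return TorqueTrajectory(
        torques_Nm=out,
        labels=list(model.q_labels),
        partition=partition,
        frame_rate=trajectory.frame_rate,
        gravity=g,
    )


def partition_torques(torques: TorqueTrajectory, model: HandModel) -> PartitionedTorques:
    """Split axis torques into the muscle-balanced (free) vector and the
    reaction-balanced (immobilized) report."""
    free_idx = [i for i, p in enumerate(torques.partition) if p == "free"]
    imm_idx = [i for i, p in enumerate(torques.partition) if p == "immobilized"]
    return PartitionedTorques(
        free_Nm=torques.torques_Nm[:, free_idx],
        free_labels=[torques.labels[i] for i in free_idx],
        reaction_Nm=torques.torques_Nm[:, imm_idx],
        reaction_labels=[torques.labels[i] for i in imm_idx],
    )
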