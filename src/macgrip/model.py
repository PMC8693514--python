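"""Musculoskeletal hand model: domain types, default macaque model, file I/O.

The hand skeleton is a chain of 20 bone segments (carpus, five metacarpals,
fourteen phalanges) connected by revolute joints: interphalangeal joints are
1-DOF hinges, metacarpophalangeal joints and the first carpometacarpal joint
are 2-DOF universal joints, and carpometacarpal joints 2-5 are fused with the
carpus (their mobility is negligible in precision grip), leaving an open
chain of 16 rigid links.  Muscle-tendon units are via-point paths (straight
line segments between points fixed in bone frames); maximum isometric force
is PCSA times the maximum muscle stress sigma_max (23 N/cm^2).  The dorsal
extensor mechanism of each long finger is a tendon network whose branch
tensions are linear in the contributing muscle tensions.

Frame conventions
-----------------
Each bone frame sits at the bone centroid with z along the shaft (distal),
x dorsal and y pointing radial-to-ulnar; so +y is every flexion/extension
rotation axis and positive rotation about +y is extension.  The carpus frame
(x dorsal, y ulnar, z distal) is the root.  Coordinates in model files are mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import yaml

from ._tables import MUSCLE_TABLE, SEGMENT_INERTIA, SIGMA_MAX

SCHEMA = "handmodel-v1"

ROOT_SEGMENT = "carpus"

FINGERS = (2, 3, 4, 5)
DIGITS = (1, 2, 3, 4, 5)

#: extensor-mechanism branch names (terminal extensor, ulnar/radial bands,
#: extensor slip, ulnar/central/radial slips, interosseous tendon)
NET_BRANCHES = ("TE", "UB", "RB", "ES", "US", "CS", "RS", "IT")


# ---------------------------------------------------------------------------
# small rotation helpers


def rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    ax = np.asarray(axis, dtype=float)
    k = ax / np.linalg.norm(ax)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)


def rot_z(angle: float) -> np.ndarray:
    return rot_axis(np.array([0.0, 0.0, 1.0]), angle)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class BoneSegment:
    """A rigid bone segment.

    ``origin_offset_mm`` is the position of the segment frame origin (the bone
    centroid) relative to the segment's proximal joint center, expressed in
    the segment's own frame.  ``inertia_gmm2`` are the principal moments about
    the frame axes; the center of mass sits at ``com_offset_mm`` from the
    origin (zero in the default model).
    """

    name: str
    parent: Optional[str]
    mass_g: float
    inertia_gmm2: np.ndarray
    origin_offset_mm: np.ndarray
    com_offset_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.inertia_gmm2 = np.asarray(self.inertia_gmm2, dtype=float)
        self.origin_offset_mm = np.asarray(self.origin_offset_mm, dtype=float)
        self.com_offset_mm = np.asarray(self.com_offset_mm, dtype=float)


@dataclass
class JointAxis:
    """One rotational axis of a joint.

    ``free`` distinguishes axes balanced by muscles from axes that remain
    kinematically mobile but are treated as instantaneously immobile during
    inverse dynamics (balanced by reaction torques).
    """

    vector: np.ndarray
    free: bool
    label: str  # "fe" flexion/extension, "rud" radio-ulnar deviation

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)


@dataclass
class Joint:
    """Connection between a parent and child segment.

    type: "hinge" (1 DOF), "universal" (2 DOF) or "fixed" (0 DOF, fused).
    The child reference orientation relative to the parent is
    ``base_orientation``; the joint rotation is composed intrinsically,
    R = R0 @ Rot(axis_1, q_1) @ Rot(axis_2, q_2).
    """

    name: str
    parent: str
    child: str
    type: str
    center_mm: np.ndarray
    base_orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    axes: list = field(default_factory=list)

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        self.base_orientation = np.asarray(self.base_orientation, dtype=float)

    @property
    def dof(self) -> int:
        return {"hinge": 1, "universal": 2, "fixed": 0}[self.type]


@dataclass
class MusclePath:
    """A muscle-tendon unit as an ordered series of via points.

    Each via point is ``(segment_name, xyz_mm)`` in that segment's frame.
    ``insertion`` is "bone" or "net" (the terminal point is an entry node of
    the digit's extensor mechanism).  ``group`` is the named muscle this path
    belongs to (split muscles such as FDP contribute several paths).
    """

    name: str
    group: str
    pcsa_cm2: float
    points: list
    insertion: str = "bone"
    net_digit: Optional[int] = None
    numbered: bool = True

    def __post_init__(self):
        self.points = [(seg, np.asarray(xyz, dtype=float)) for seg, xyz in self.points]

    def max_force_N(self, sigma: float = SIGMA_MAX) -> float:
        return max_force(self.pcsa_cm2, sigma)


@dataclass
class ExtensorNet:
    """Extensor mechanism (dorsal aponeurosis) of one finger.

    ``branches`` maps branch name -> via-point polyline; ``coefficients``
    maps branch name -> {muscle name: transmission coefficient}.  Branch
    tension is the coefficient-weighted sum of contributing muscle tensions;
    the terminal extensor tendon satisfies TE = RB + UB.
    """

    digit: int
    branches: dict
    coefficients: dict

    def __post_init__(self):
        self.branches = {
            b: [(seg, np.asarray(xyz, dtype=float)) for seg, xyz in pts]
            for b, pts in self.branches.items()
        }

    @property
    def muscles(self) -> list:
        names: list = []
        for row in self.coefficients.values():
            for m in row:
                if m not in names:
                    names.append(m)
        return names


@dataclass
class LeverContact:
    """Where and in which (global) direction a pinch-lever force acts."""

    segment: str
    point_mm: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.point_mm = np.asarray(self.point_mm, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)


class HandModel:
    """Complete musculoskeletal description of the hand."""

    def __init__(
        self,
        segments: dict,
        joints: list,
        muscles: list,
        extensor_nets: list,
        sigma_max: float = SIGMA_MAX,
        gravity: np.ndarray = (-9.81, 0.0, 0.0),
        landmarks: Optional[dict] = None,
        levers: Optional[dict] = None,
    ):
        self.segments = dict(segments)
        self.joints = list(joints)
        self.muscles = list(muscles)
        self.extensor_nets = list(extensor_nets)
        self.sigma_max = float(sigma_max)
        self.gravity = np.asarray(gravity, dtype=float)
        self.landmarks = {
            k: (seg, np.asarray(xyz, dtype=float))
            for k, (seg, xyz) in (landmarks or {}).items()
        }
        self.levers = dict(levers or {})
        self._index()

    # -- topology ----------------------------------------------------------
    def _index(self):
        self._joint_by_child = {j.child: j for j in self.joints}
        self._muscle_by_name = {m.name: m for m in self.muscles}
        # q layout: every axis of every non-fixed joint, in joint order
        self.q_labels = []
        self._q_slice = {}
        for j in self.joints:
            start = len(self.q_labels)
            for ax in j.axes:
                self.q_labels.append((j.name, ax.label))
            self._q_slice[j.name] = slice(start, len(self.q_labels))
        self.n_q = len(self.q_labels)
        # free (muscle-balanced) axes, in joint order
        self.free_axes = []
        for j in self.joints:
            for k, ax in enumerate(j.axes):
                if ax.free:
                    self.free_axes.append((j.name, ax.label))
        # ancestry: segment -> boolean mask over q of axes that move it
        self._ancestor_mask = {}
        for name in self.segments:
            mask = np.zeros(self.n_q, dtype=bool)
            seg = name
            while self.segments[seg].parent is not None:
                j = self._joint_by_child[seg]
                mask[self._q_slice[j.name]] = True
                seg = self.segments[seg].parent
            self._ancestor_mask[name] = mask

    def joint_for_child(self, child: str) -> Joint:
        return self._joint_by_child[child]

    def muscle(self, name: str) -> MusclePath:
        try:
            return self._muscle_by_name[name]
        except KeyError:
            raise KeyError(f"unknown muscle {name!r}") from None

    def q_index(self, joint: str, label: str) -> int:
        return self.q_labels.index((joint, label))

    def ancestor_mask(self, segment: str) -> np.ndarray:
        return self._ancestor_mask[segment]

    @property
    def root(self) -> str:
        roots = [s.name for s in self.segments.values() if s.parent is None]
        return roots[0] if roots else ROOT_SEGMENT

    @property
    def muscle_names(self) -> list:
        return [m.name for m in self.muscles]

    @property
    def muscle_groups(self) -> list:
        """The named muscles (numbered table entries); split paths collapse."""
        groups: list = []
        for m in self.muscles:
            if m.numbered and m.group not in groups:
                groups.append(m.group)
        return groups

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_links(self) -> int:
        """Rigid links of the kinematic chain after fusing fixed joints."""
        return len(self.segments) - sum(1 for j in self.joints if j.type == "fixed")

    @property
    def n_muscles(self) -> int:
        return len(self.muscle_groups)

    @property
    def n_paths(self) -> int:
        return len(self.muscles)

    @property
    def n_free_axes(self) -> int:
        return len(self.free_axes)

    def pcsa_vector(self) -> np.ndarray:
        return np.array([m.pcsa_cm2 for m in self.muscles])

    def fmax_vector(self) -> np.ndarray:
        return np.array([m.max_force_N(self.sigma_max) for m in self.muscles])

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        return _model_to_dict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "HandModel":
        return _model_from_dict(data)

    def copy(self) -> "HandModel":
        return _model_from_dict(_model_to_dict(self))


# ---------------------------------------------------------------------------
# PCSA -> force


def max_force(pcsa: float, sigma: float = SIGMA_MAX) -> float:
    """Maximum isometric force (N) from PCSA (cm^2) and muscle stress (N/cm^2)."""
    if pcsa < 0:
        raise ValueError(f"PCSA must be non-negative, got {pcsa}")
    if sigma <= 0:
        raise ValueError(f"muscle stress must be positive, got {sigma}")
    return pcsa * sigma


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, exactly in decimal arithmetic."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def table_max_force(pcsa: float, sigma: float = SIGMA_MAX) -> float:
    """PCSA x sigma rounded half-away-from-zero to one decimal (N).

    Computed in decimal arithmetic so printed-precision inputs round the way
    a printed table does (e.g. 0.45 x 23 = 10.35 -> 10.4, not 10.3 as binary
    floating point would give).
    """
    if pcsa < 0:
        raise ValueError(f"PCSA must be non-negative, got {pcsa}")
    value = Decimal(repr(pcsa)) * Decimal(repr(sigma))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# default model geometry template


@dataclass
class GeometryParams:
    """Parametric template geometry for the default model.

    The published model's joint centers and via points are not available, so
    the default model uses this documented, non-anatomical template: straight
    digit columns along +z, spaced along y, with via points at fixed dorsal /
    palmar offsets that set the tendon moment arms.  Lengths are loosely
    macaque-hand-proportioned, in mm.
    """

    mc_length: dict = field(
        default_factory=lambda: {1: 28.0, 2: 36.0, 3: 38.0, 4: 35.0, 5: 30.0}
    )
    pp_length: dict = field(
        default_factory=lambda: {1: 22.0, 2: 25.0, 3: 28.0, 4: 26.0, 5: 20.0}
    )
    mp_length: dict = field(
        default_factory=lambda: {2: 15.0, 3: 17.0, 4: 16.0, 5: 12.0}
    )
    dp_length: dict = field(
        default_factory=lambda: {1: 10.0, 2: 10.0, 3: 11.0, 4: 10.0, 5: 9.0}
    )
    digit_offset_y: dict = field(
        default_factory=lambda: {1: -22.0, 2: -12.0, 3: -4.0, 4: 4.0, 5: 12.0}
    )
    carpus_half_length: float = 10.0
    #: thumb column rotation about z (palmar face turned toward the index)
    thumb_rotation_deg: float = -90.0
    palmar_offset: float = 4.0  # long flexor via offset (flexion moment arms)
    dorsal_offset: float = 4.0  # extrinsic extensor via offset
    es_offset: float = 3.0  # extensor-slip dorsal offset at the PIP
    te_offset: float = 2.5  # terminal-tendon dorsal offset at the DIP
    band_lateral: float = 2.0  # radial/ulnar band lateral offset
    io_palmar_offset: float = 3.0  # interosseous palmar via offset at the MCP
    epl_mcp_offset: float = 8.0  # EPL dorsal offset at the thumb MCP
    epl_ip_offset: float = 2.0  # EPL dorsal offset at the thumb IP
    #: thumb lever obliquity (deg): angle between the lever line and the
    #: pinch axis; gives the thumb load a dorso-palmar component so the
    #: extensor-side demand at the thumb IP stays balanceable (FDP1 is absent)
    thumb_lever_angle_deg: float = 10.0

    def validate(self) -> list:
        problems = []
        for fname in ("mc_length", "pp_length", "dp_length", "mp_length"):
            for d, L in getattr(self, fname).items():
                if not (L > 0):
                    problems.append(f"{fname}[{d}] must be positive, got {L}")
        for fname in (
            "palmar_offset",
            "dorsal_offset",
            "es_offset",
            "te_offset",
            "io_palmar_offset",
            "epl_mcp_offset",
            "epl_ip_offset",
            "carpus_half_length",
        ):
            if not (getattr(self, fname) > 0):
                problems.append(f"{fname} must be positive")
        return problems


def _seg_names(digit: int) -> dict:
    names = {"MC": f"{digit}MC", "PP": f"{digit}PP", "DP": f"{digit}DP"}
    if digit != 1:
        names["MP"] = f"{digit}MP"
    return names


def build_default_model(geometry: Optional[GeometryParams] = None, seed=None) -> HandModel:
    """Construct the default macaque hand model.

    Masses, inertias and PCSAs are the published values verbatim; joint
    centers and muscle via points come from the parametric template (the
    source tables print no coordinates).  ``seed`` is accepted for interface
    symmetry; the construction is deterministic.
    """
    g = geometry or GeometryParams()
    problems = g.validate()
    if problems:
        raise ValueError("invalid geometry parameters: " + "; ".join(problems))

    segments: dict = {}
    joints: list = []

    def add_segment(name, parent, origin_offset):
        mass, ix, iy, iz = SEGMENT_INERTIA[name]
        segments[name] = BoneSegment(
            name=name,
            parent=parent,
            mass_g=mass,
            inertia_gmm2=np.array([ix, iy, iz]),
            origin_offset_mm=np.asarray(origin_offset, dtype=float),
        )

    add_segment(ROOT_SEGMENT, None, (0.0, 0.0, 0.0))

    x_axis = np.array([1.0, 0.0, 0.0])
    y_axis = np.array([0.0, 1.0, 0.0])

    for d in DIGITS:
        mc, pp, dp = f"{d}MC", f"{d}PP", f"{d}DP"
        Lmc, Lpp, Ldp = g.mc_length[d], g.pp_length[d], g.dp_length[d]
        cmc_center = np.array([0.0, g.digit_offset_y[d], g.carpus_half_length])
        if d == 1:
            base = rot_z(math.radians(g.thumb_rotation_deg))
            joints.append(
                Joint(
                    name="1CMC",
                    parent=ROOT_SEGMENT,
                    child=mc,
                    type="universal",
                    center_mm=cmc_center,
                    base_orientation=base,
                    axes=[
                        JointAxis(x_axis.copy(), free=False, label="rud"),
                        JointAxis(y_axis.copy(), free=False, label="fe"),
                    ],
                )
            )
        else:
            joints.append(
                Joint(
                    name=f"{d}CMC",
                    parent=ROOT_SEGMENT,
                    child=mc,
                    type="fixed",
                    center_mm=cmc_center,
                )
            )
        add_segment(mc, ROOT_SEGMENT, (0.0, 0.0, Lmc / 2.0))

        joints.append(
            Joint(
                name=f"{d}MCP",
                parent=mc,
                child=pp,
                type="universal",
                center_mm=np.array([0.0, 0.0, Lmc / 2.0]),
                axes=[
                    JointAxis(x_axis.copy(), free=False, label="rud"),
                    JointAxis(y_axis.copy(), free=True, label="fe"),
                ],
            )
        )
        add_segment(pp, mc, (0.0, 0.0, Lpp / 2.0))

        if d == 1:
            joints.append(
                Joint(
                    name="1IP",
                    parent=pp,
                    child=dp,
                    type="hinge",
                    center_mm=np.array([0.0, 0.0, Lpp / 2.0]),
                    axes=[JointAxis(y_axis.copy(), free=True, label="fe")],
                )
            )
            add_segment(dp, pp, (0.0, 0.0, Ldp / 2.0))
        else:
            mp = f"{d}MP"
            Lmp = g.mp_length[d]
            joints.append(
                Joint(
                    name=f"{d}PIP",
                    parent=pp,
                    child=mp,
                    type="hinge",
                    center_mm=np.array([0.0, 0.0, Lpp / 2.0]),
                    axes=[JointAxis(y_axis.copy(), free=True, label="fe")],
                )
            )
            add_segment(mp, pp, (0.0, 0.0, Lmp / 2.0))
            joints.append(
                Joint(
                    name=f"{d}DIP",
                    parent=mp,
                    child=dp,
                    type="hinge",
                    center_mm=np.array([0.0, 0.0, Lmp / 2.0]),
                    axes=[JointAxis(y_axis.copy(), free=True, label="fe")],
                )
            )
            add_segment(dp, mp, (0.0, 0.0, Ldp / 2.0))

    # reorder joints: thumb first, then fingers (canonical order)
    order = {"1CMC": 0, "1MCP": 1, "1IP": 2}
    n = 3
    for d in FINGERS:
        for jn in (f"{d}CMC", f"{d}MCP", f"{d}PIP", f"{d}DIP"):
            order[jn] = n
            n += 1
    joints.sort(key=lambda j: order[j.name])

    muscles = _build_muscles(g)
    nets = [_build_net(d, g) for d in FINGERS]
    landmarks = _build_landmarks(g)
    levers = _build_levers(g)

    model = HandModel(
        segments=segments,
        joints=joints,
        muscles=muscles,
        extensor_nets=nets,
        sigma_max=SIGMA_MAX,
        landmarks=landmarks,
        levers=levers,
    )
    diag = validate_model(model)
    if diag:
        raise AssertionError("default model failed validation: " + "; ".join(diag))
    return model


def _mk(name, points, insertion="bone", net_digit=None):
    group, pcsa, _printed, numbered = MUSCLE_TABLE[name]
    return MusclePath(
        name=name,
        group=group,
        pcsa_cm2=pcsa,
        points=points,
        insertion=insertion,
        net_digit=net_digit,
        numbered=numbered,
    )


def _build_muscles(g: GeometryParams) -> list:
    p = g.palmar_offset
    e = g.dorsal_offset
    io = g.io_palmar_offset
    y1 = g.digit_offset_y[1]
    ms: list = []

    for d in FINGERS:
        mc, pp, mp, dp = f"{d}MC", f"{d}PP", f"{d}MP", f"{d}DP"
        Lmc, Lpp = g.mc_length[d], g.pp_length[d]
        Lmp, Ldp = g.mp_length[d], g.dp_length[d]
        yd = g.digit_offset_y[d]
        # long flexors: palmar route, flexion arms ~= palmar offset
        fds_pts = [
            (ROOT_SEGMENT, (-6.0, yd, 0.0)),
            (mc, (-p, 0.0, Lmc / 2 - 3.0)),
            (pp, (-p, 0.0, -Lpp / 2 + 3.0)),
            (pp, (-p, 0.0, Lpp / 2 - 3.0)),
            (mp, (-p, 0.0, -Lmp / 2 + 4.0)),
        ]
        ms.append(_mk(f"FDS{d}", fds_pts))
        fdp_pts = fds_pts[:-1] + [
            (mp, (-p, 0.0, -Lmp / 2 + 3.0)),
            (mp, (-p, 0.0, Lmp / 2 - 3.0)),
            (dp, (-p, 0.0, -Ldp / 2 + 3.0)),
        ]
        ms.append(_mk(f"FDP{d}", fdp_pts))
        # extrinsic extensors feed the extensor mechanism at the PP dorsum
        ms.append(
            _mk(
                f"EDC{d}",
                [
                    (ROOT_SEGMENT, (6.0, yd, -5.0)),
                    (mc, (e, 0.0, Lmc / 2 - 3.0)),
                    (pp, (e, 0.0, -Lpp / 2 + 3.0)),
                    (pp, (e, 0.0, -Lpp / 2 + 6.0)),
                ],
                insertion="net",
                net_digit=d,
            )
        )
        ms.append(
            _mk(
                f"ED{d}P",
                [
                    (ROOT_SEGMENT, (6.0, yd + 2.0, -5.0)),
                    (mc, (e, 1.0, Lmc / 2 - 3.0)),
                    (pp, (e, 1.0, -Lpp / 2 + 3.0)),
                    (pp, (e, 1.0, -Lpp / 2 + 6.0)),
                ],
                insertion="net",
                net_digit=d,
            )
        )
        # interossei: palmar to the MCP axis, terminating at the net entry
        dio = d - 1  # dorsal interosseous index feeding this digit's net
        for head, sy in (("r", -1.0), ("u", 1.0)):
            ms.append(
                _mk(
                    f"{dio}DIO{head}",
                    [
                        (mc, (-1.0, 4.0 * sy, 0.0)),
                        (mc, (-io, 2.0 * sy, Lmc / 2 - 1.0)),
                        (pp, (-io, 2.0 * sy, -Lpp / 2 + 2.0)),
                        (pp, (2.0, 2.5 * sy, -Lpp / 2 + 6.0)),
                    ],
                    insertion="net",
                    net_digit=d,
                )
            )
        if d in (2, 3, 4):  # palmar interosseous feeding this digit's net
            ms.append(
                _mk(
                    f"{d - 1}PIO",
                    [
                        (mc, (-1.0, 3.0, -2.0)),
                        (mc, (-io, 1.5, Lmc / 2 - 1.0)),
                        (pp, (-io, 1.5, -Lpp / 2 + 2.0)),
                        (pp, (2.0, 1.5, -Lpp / 2 + 6.0)),
                    ],
                    insertion="net",
                    net_digit=d,
                )
            )

    # thumb
    Lmc1, Lpp1, Ldp1 = g.mc_length[1], g.pp_length[1], g.dp_length[1]
    ms.append(
        _mk(
            "FDP1",
            [
                (ROOT_SEGMENT, (-4.0, y1, 0.0)),
                (f"1MC", (-p, 0.0, Lmc1 / 2 - 3.0)),
                ("1PP", (-p, 0.0, -Lpp1 / 2 + 3.0)),
                ("1PP", (-p, 0.0, Lpp1 / 2 - 3.0)),
                ("1DP", (-p, 0.0, -Ldp1 / 2 + 3.0)),
            ],
        )
    )
    ms.append(
        _mk(
            "EPL",
            [
                (ROOT_SEGMENT, (6.0, y1, 0.0)),
                ("1MC", (4.0, 0.0, 0.0)),
                ("1MC", (g.epl_mcp_offset, 0.0, Lmc1 / 2 - 1.0)),
                ("1PP", (g.epl_mcp_offset, 0.0, -Lpp1 / 2 + 2.0)),
                ("1PP", (g.epl_ip_offset, 0.0, Lpp1 / 2 - 1.0)),
                ("1DP", (g.epl_ip_offset, 0.0, -Ldp1 / 2 + 2.0)),
            ],
        )
    )
    ms.append(
        _mk(
            "ABPL",
            [(ROOT_SEGMENT, (2.0, y1 - 2.0, -8.0)), ("1MC", (0.0, -3.0, -Lmc1 / 2 + 2.0))],
        )
    )
    ms.append(
        _mk(
            "ABPB",
            [
                (ROOT_SEGMENT, (-4.0, y1, 4.0)),
                ("1MC", (-3.0, -2.0, Lmc1 / 2 - 1.0)),
                ("1PP", (-2.5, -2.0, -Lpp1 / 2 + 3.0)),
            ],
        )
    )
    ms.append(
        _mk(
            "FPB",
            [
                (ROOT_SEGMENT, (-4.0, y1 + 4.0, 5.0)),
                ("1MC", (-p, 1.0, Lmc1 / 2 - 1.0)),
                ("1PP", (-p, 1.0, -Lpp1 / 2 + 3.0)),
            ],
        )
    )
    ms.append(_mk("OP", [(ROOT_SEGMENT, (-4.0, y1, 0.0)), ("1MC", (-3.0, -1.0, 0.0))]))
    ms.append(
        _mk(
            "ADPo",
            [
                (ROOT_SEGMENT, (-5.0, y1 + 6.0, 2.0)),
                ("1MC", (-p, 2.0, Lmc1 / 2 - 1.0)),
                ("1PP", (-p, 2.0, -Lpp1 / 2 + 4.0)),
            ],
        )
    )
    ms.append(
        _mk(
            "ADPt",
            [
                ("3MC", (-4.0, 0.0, 0.0)),
                ("1MC", (-p, 2.0, Lmc1 / 2 - 1.0)),
                ("1PP", (-p, 2.0, -Lpp1 / 2 + 3.0)),
            ],
        )
    )
    # hypothenar
    Lpp5 = g.pp_length[5]
    ms.append(
        _mk(
            "ABDM",
            [(ROOT_SEGMENT, (-2.0, 16.0, -2.0)), ("5PP", (-1.5, 3.0, -Lpp5 / 2 + 3.0))],
        )
    )
    ms.append(
        _mk(
            "FDMB",
            [(ROOT_SEGMENT, (-3.0, 14.0, 2.0)), ("5PP", (-3.0, 2.0, -Lpp5 / 2 + 3.0))],
        )
    )
    ms.append(
        _mk("ODM", [(ROOT_SEGMENT, (-3.0, 15.0, 0.0)), ("5MC", (-2.0, 2.0, 0.0))])
    )
    # contrahentes (adductors toward the third ray)
    ms.append(
        _mk(
            "CD2",
            [("3MC", (-4.0, -1.0, -g.mc_length[3] / 2 + 5.0)),
             ("2PP", (-3.0, 2.0, -g.pp_length[2] / 2 + 3.0))],
        )
    )
    ms.append(
        _mk(
            "CD4",
            [("3MC", (-4.0, 1.0, -g.mc_length[3] / 2 + 5.0)),
             ("4PP", (-3.0, -2.0, -g.pp_length[4] / 2 + 3.0))],
        )
    )
    ms.append(
        _mk(
            "CD5",
            [("3MC", (-4.0, 1.5, -g.mc_length[3] / 2 + 5.0)),
             ("5PP", (-3.0, -2.0, -Lpp5 / 2 + 3.0))],
        )
    )
    return ms


def _build_net(d: int, g: GeometryParams) -> ExtensorNet:
    pp, mp, dp, mc = f"{d}PP", f"{d}MP", f"{d}DP", f"{d}MC"
    Lpp, Lmp, Ldp, Lmc = g.pp_length[d], g.mp_length[d], g.dp_length[d], g.mc_length[d]
    es, te, lat = g.es_offset, g.te_offset, g.band_lateral
    branches = {
        "ES": [(pp, (es, 0.0, Lpp / 2 - 3.0)), (mp, (es, 0.0, -Lmp / 2 + 3.0))],
        "RB": [
            (pp, (es, -lat, Lpp / 2 - 3.0)),
            (mp, (es, -lat, 0.0)),
            (mp, (te, -1.0, Lmp / 2 - 3.0)),
        ],
        "UB": [
            (pp, (es, lat, Lpp / 2 - 3.0)),
            (mp, (es, lat, 0.0)),
            (mp, (te, 1.0, Lmp / 2 - 3.0)),
        ],
        "TE": [(mp, (te, 0.0, Lmp / 2 - 3.0)), (dp, (te, 0.0, -Ldp / 2 + 3.0))],
        "CS": [(pp, (es, 0.0, 0.0)), (mp, (es, 0.0, -Lmp / 2 + 2.0))],
        "RS": [(mc, (es, -lat, Lmc / 2 - 2.0)), (pp, (es, -lat, -Lpp / 2 + 2.0))],
        "US": [(mc, (es, lat, Lmc / 2 - 2.0)), (pp, (es, lat, -Lpp / 2 + 2.0))],
        "IT": [(pp, (-1.0, -3.0, -Lpp / 2 + 2.0)), (pp, (2.0, -2.0, Lpp / 2 - 3.0))],
    }
    edc, edp = f"EDC{d}", f"ED{d}P"
    dio = d - 1
    dior, diou = f"{dio}DIOr", f"{dio}DIOu"
    pio = f"{d - 1}PIO" if d in (2, 3, 4) else None
    cE, cI = 0.167, 0.333
    rb = {edc: cE, edp: cE}
    ub = {edc: cE, edp: cE}
    es_row = {edc: cE, edp: cE, dior: cI, diou: cI}
    if pio:
        ub[pio] = cI
        es_row[pio] = cI
    te_row = {m: rb.get(m, 0.0) + ub.get(m, 0.0) for m in set(rb) | set(ub)}
    coefficients = {
        "TE": te_row,
        "UB": ub,
        "RB": rb,
        "ES": es_row,
        "US": {},
        "CS": {},
        "RS": {},
        "IT": {},
    }
    return ExtensorNet(digit=d, branches=branches, coefficients=coefficients)


def _build_landmarks(g: GeometryParams) -> dict:
    # "head" markers sit on the dorsal surface over the bone head (as a
    # digitized skin point does), not at the joint center: the dorsal offset
    # breaks the planar two-link mirror ambiguity of chain registration
    lm = {
        "1DP_tip": ("1DP", (0.0, 0.0, g.dp_length[1] / 2)),
        "1PP_head": ("1PP", (2.5, 0.0, g.pp_length[1] / 2)),
        "1MC_head": ("1MC", (2.5, 0.0, g.mc_length[1] / 2)),
        "1CMC": (ROOT_SEGMENT, (0.0, g.digit_offset_y[1], g.carpus_half_length)),
        "2DP_tip": ("2DP", (0.0, 0.0, g.dp_length[2] / 2)),
        "2MP_head": ("2MP", (2.5, 0.0, g.mp_length[2] / 2)),
        "2DP_head": ("2DP", (1.5, 0.0, g.dp_length[2] / 2 - 2.5)),
        "2MC_head": ("2MC", (0.0, 0.0, g.mc_length[2] / 2)),
        "3MC_head": ("3MC", (0.0, 0.0, g.mc_length[3] / 2)),
        "4MC_head": ("4MC", (0.0, 0.0, g.mc_length[4] / 2)),
        "5MC_head": ("5MC", (0.0, 0.0, g.mc_length[5] / 2)),
        "ulnar_styloid": (ROOT_SEGMENT, (0.0, 10.0, -g.carpus_half_length - 3.0)),
    }
    return lm


def _build_levers(g: GeometryParams) -> dict:
    # index lever: horizontal reaction along the global dorsal (+x) axis at
    # the fingertip pad; thumb lever: horizontal, tilted by the lever angle
    # off the pinch axis, applied at the ulnar-distal thumb tip
    th = math.radians(g.thumb_lever_angle_deg)
    return {
        "index": LeverContact(
            segment="2DP",
            point_mm=(-2.0, 0.0, g.dp_length[2] / 2),
            direction=(1.0, 0.0, 0.0),
        ),
        "thumb": LeverContact(
            segment="1DP",
            point_mm=(0.0, 2.5, g.dp_length[1] / 2),
            direction=(-math.cos(th), math.sin(th), 0.0),
        ),
    }


# ---------------------------------------------------------------------------
# validation


def validate_model(model: HandModel) -> list:
    """Return a list of violated invariants (empty list = valid model)."""
    diag: list = []
    segs = model.segments
    roots = [s.name for s in segs.values() if s.parent is None]
    if len(roots) != 1:
        diag.append(f"model must have exactly one root segment, found {roots}")
    for s in segs.values():
        if s.parent is not None and s.parent not in segs:
            diag.append(f"segment {s.name}: unknown parent {s.parent}")
        if s.mass_g < 0:
            diag.append(f"segment {s.name}: negative mass")
        ix, iy, iz = s.inertia_gmm2
        if min(ix, iy, iz) < 0:
            diag.append(f"segment {s.name}: negative principal moment")
        tol = 1e-9 * max(ix, iy, iz, 1.0)
        if ix + iy < iz - tol or iy + iz < ix - tol or iz + ix < iy - tol:
            diag.append(
                f"segment {s.name}: principal moments violate realizability "
                f"(each pair must sum to at least the third)"
            )
    # tree structure (no cycles)
    for s in segs.values():
        seen = set()
        cur = s.name
        while cur is not None:
            if cur in seen:
                diag.append(f"segment {s.name}: cycle in parent links")
                break
            seen.add(cur)
            cur = segs[cur].parent if cur in segs else None

    joint_children = set()
    for j in model.joints:
        if j.parent not in segs:
            diag.append(f"joint {j.name}: unknown parent segment {j.parent}")
        if j.child not in segs:
            diag.append(f"joint {j.name}: unknown child segment {j.child}")
        joint_children.add(j.child)
        if len(j.axes) != j.dof:
            diag.append(f"joint {j.name}: {len(j.axes)} axes for type {j.type}")
        for ax in j.axes:
            n = np.linalg.norm(ax.vector)
            if abs(n - 1.0) > 1e-9:
                diag.append(f"joint {j.name}: axis {ax.label} not unit norm ({n})")
        if j.type == "universal" and len(j.axes) == 2:
            dot = abs(float(np.dot(j.axes[0].vector, j.axes[1].vector)))
            if dot > 1e-9:
                diag.append(f"joint {j.name}: universal axes not orthogonal")
        if sum(1 for ax in j.axes if ax.free) > j.dof:
            diag.append(f"joint {j.name}: more free axes than DOF")
        R = j.base_orientation
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9 or np.linalg.det(R) < 0:
            diag.append(f"joint {j.name}: base orientation not a rotation")
    for s in segs.values():
        if s.parent is not None and s.name not in joint_children:
            diag.append(f"segment {s.name}: has a parent but no connecting joint")

    net_digits = {net.digit for net in model.extensor_nets}
    for m in model.muscles:
        if len(m.points) < 2:
            diag.append(f"muscle {m.name}: fewer than 2 via points")
        else:
            if m.points[0][0] == m.points[-1][0]:
                diag.append(
                    f"muscle {m.name}: origin and insertion on the same segment"
                )
        for seg, _ in m.points:
            if seg not in segs:
                diag.append(f"muscle {m.name}: via point on unknown segment {seg}")
        if m.pcsa_cm2 < 0:
            diag.append(f"muscle {m.name}: negative PCSA")
        if m.insertion == "net" and m.net_digit not in net_digits:
            diag.append(f"muscle {m.name}: inserts into missing net {m.net_digit}")

    for net in model.extensor_nets:
        for b, pts in net.branches.items():
            for seg, _ in pts:
                if seg not in segs:
                    diag.append(
                        f"net digit {net.digit} branch {b}: unknown segment {seg}"
                    )
        for b, row in net.coefficients.items():
            for mname, c in row.items():
                if c < 0:
                    diag.append(
                        f"net digit {net.digit}: negative coefficient {b}/{mname}"
                    )
        te = net.coefficients.get("TE", {})
        rb = net.coefficients.get("RB", {})
        ub = net.coefficients.get("UB", {})
        for mname in set(te) | set(rb) | set(ub):
            lhs = te.get(mname, 0.0)
            rhs = rb.get(mname, 0.0) + ub.get(mname, 0.0)
            if abs(lhs - rhs) > 1e-12:
                diag.append(
                    f"net digit {net.digit}: TE row != RB + UB for {mname} "
                    f"({lhs} vs {rhs})"
                )

    for lname, (seg, _) in model.landmarks.items():
        if seg not in segs:
            diag.append(f"landmark {lname}: unknown segment {seg}")
    return diag


# ---------------------------------------------------------------------------
# model file (YAML, schema handmodel-v1)


class ModelFileError(ValueError):
    pass


def _model_to_dict(model: HandModel) -> dict:
    return {
        "schema": SCHEMA,
        "sigma_max_N_per_cm2": model.sigma_max,
        "gravity_m_per_s2": [float(v) for v in model.gravity],
        "segments": [
            {
                "name": s.name,
                "parent": s.parent,
                "mass_g": float(s.mass_g),
                "inertia_gmm2": [float(v) for v in s.inertia_gmm2],
                "origin_offset_mm": [float(v) for v in s.origin_offset_mm],
                "com_offset_mm": [float(v) for v in s.com_offset_mm],
            }
            for s in model.segments.values()
        ],
        "joints": [
            {
                "name": j.name,
                "parent": j.parent,
                "child": j.child,
                "type": j.type,
                "center_mm": [float(v) for v in j.center_mm],
                "base_orientation": [[float(v) for v in row] for row in j.base_orientation],
                "axes": [
                    {
                        "vector": [float(v) for v in ax.vector],
                        "free": bool(ax.free),
                        "label": ax.label,
                    }
                    for ax in j.axes
                ],
            }
            for j in model.joints
        ],
        "muscles": [
            {
                "name": m.name,
                "group": m.group,
                "pcsa_cm2": float(m.pcsa_cm2),
                "insertion": m.insertion,
                "net_digit": m.net_digit,
                "numbered": bool(m.numbered),
                "points": [
                    {"segment": seg, "xyz_mm": [float(v) for v in xyz]}
                    for seg, xyz in m.points
                ],
            }
            for m in model.muscles
        ],
        "extensor_nets": [
            {
                "digit": net.digit,
                "branches": {
                    b: [
                        {"segment": seg, "xyz_mm": [float(v) for v in xyz]}
                        for seg, xyz in pts
                    ]
                    for b, pts in net.branches.items()
                },
                "coefficients": {
                    b: {m: float(c) for m, c in row.items()}
                    for b, row in net.coefficients.items()
                },
            }
            for net in model.extensor_nets
        ],
        "landmarks": {
            k: {"segment": seg, "xyz_mm": [float(v) for v in xyz]}
            for k, (seg, xyz) in model.landmarks.items()
        },
        "levers": {
            k: {
                "segment": lv.segment,
                "point_mm": [float(v) for v in lv.point_mm],
                "direction": [float(v) for v in lv.direction],
            }
            for k, lv in model.levers.items()
        },
    }


def _model_from_dict(data: dict) -> HandModel:
    if data.get("schema") != SCHEMA:
        raise ModelFileError(
            f"schema: expected {SCHEMA!r}, got {data.get('schema')!r}"
        )
    for key in ("segments", "joints", "muscles"):
        if key not in data:
            raise ModelFileError(f"missing required key {key!r}")
    segments = {}
    for i, s in enumerate(data["segments"]):
        try:
            segments[s["name"]] = BoneSegment(
                name=s["name"],
                parent=s.get("parent"),
                mass_g=float(s["mass_g"]),
                inertia_gmm2=s["inertia_gmm2"],
                origin_offset_mm=s["origin_offset_mm"],
                com_offset_mm=s.get("com_offset_mm", (0.0, 0.0, 0.0)),
            )
        except (KeyError, TypeError) as exc:
            raise ModelFileError(f"segments[{i}]: {exc}") from exc
    joints = []
    for i, j in enumerate(data["joints"]):
        try:
            axes = []
            for ax in j.get("axes", []):
                v = np.asarray(ax["vector"], dtype=float)
                if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                    raise ModelFileError(
                        f"joints[{i}].axes: axis {ax.get('label')} is not unit norm"
                    )
                axes.append(JointAxis(v, free=bool(ax["free"]), label=ax["label"]))
            joints.append(
                Joint(
                    name=j["name"],
                    parent=j["parent"],
                    child=j["child"],
                    type=j["type"],
                    center_mm=j["center_mm"],
                    base_orientation=np.asarray(
                        j.get("base_orientation", np.eye(3).tolist()), dtype=float
                    ),
                    axes=axes,
                )
            )
        except (KeyError, TypeError) as exc:
            raise ModelFileError(f"joints[{i}]: {exc}") from exc
    muscles = []
    for i, m in enumerate(data["muscles"]):
        try:
            muscles.append(
                MusclePath(
                    name=m["name"],
                    group=m.get("group", m["name"]),
                    pcsa_cm2=float(m["pcsa_cm2"]),
                    points=[(pt["segment"], pt["xyz_mm"]) for pt in m["points"]],
                    insertion=m.get("insertion", "bone"),
                    net_digit=m.get("net_digit"),
                    numbered=bool(m.get("numbered", True)),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ModelFileError(f"muscles[{i}]: {exc}") from exc
    nets = []
    for i, n in enumerate(data.get("extensor_nets", [])):
        try:
            nets.append(
                ExtensorNet(
                    digit=int(n["digit"]),
                    branches={
                        b: [(pt["segment"], pt["xyz_mm"]) for pt in pts]
                        for b, pts in n.get("branches", {}).items()
                    },
                    coefficients={
                        b: dict(row) for b, row in n.get("coefficients", {}).items()
                    },
                )
            )
        except (KeyError, TypeError) as exc:
            raise ModelFileError(f"extensor_nets[{i}]: {exc}") from exc
    landmarks = {
        k: (v["segment"], v["xyz_mm"]) for k, v in data.get("landmarks", {}).items()
    }
    levers = {
        k: LeverContact(v["segment"], v["point_mm"], v["direction"])
        for k, v in data.get("levers", {}).items()
    }
    return HandModel(
        segments=segments,
        joints=joints,
        muscles=muscles,
        extensor_nets=nets,
        sigma_max=float(data.get("sigma_max_N_per_cm2", SIGMA_MAX)),
        gravity=data.get("gravity_m_per_s2", (-9.81, 0.0, 0.0)),
        landmarks=landmarks,
        levers=levers,
    )


def save_model(model: HandModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def load_model(path) -> HandModel:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ModelFileError("model file does not contain a mapping")
    return _model_from_dict(data)
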