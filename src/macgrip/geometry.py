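"""Articular-surface primitive fits and inertial properties from bone meshes.

Joint centers and axes of the skeletal model come from geometric primitives
fitted to articular surface patches: a sphere for metacarpal heads (MCP
center), a cylinder for phalangeal heads (IP center and hinge axis) and an
elliptic paraboloid for the saddle-shaped trapezium facet (thumb CMC center
at the apex, axes from the paraboloid orientation).  All fits are algebraic
or PCA initializations refined by geometric (orthogonal-distance) least
squares, so they are translation/rotation equivariant and scale covariant.

Segment inertia assumes homogeneous composition (density 1.0 g/cm^3 for the
published model): phalanges use exact polyhedral integrals of a closed
surface mesh, metacarpals and carpus a rectangular-solid approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.optimize import least_squares


@dataclass
class SurfacePatch:
    """A digitized articular-surface point set (mm)."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if not np.isfinite(self.points).all():
            raise ValueError("patch contains non-finite coordinates")


class DegenerateFitError(ValueError):
    pass


def _as_points(patch) -> np.ndarray:
    if isinstance(patch, SurfacePatch):
        return patch.points
    return SurfacePatch(np.asarray(patch)).points


# ---------------------------------------------------------------------------
# sphere


def fit_sphere(patch):
    """Least-squares sphere: returns (center (3,), radius, rms_residual), mm.

    Algebraic linear initialization followed by geometric Gauss-Newton on
    the radial residuals ||p - c|| - r.
    """
    P = _as_points(patch)
    if P.shape[0] < 4:
        raise DegenerateFitError("sphere fit needs at least 4 points")
    A = np.hstack([2.0 * P, np.ones((P.shape[0], 1))])
    b = np.sum(P**2, axis=1)
    if np.linalg.matrix_rank(A) < 4:
        raise DegenerateFitError("degenerate (coplanar/collinear) sphere patch")
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = x[:3]
    r0 = float(np.sqrt(max(x[3] + c0 @ c0, 0.0)))
    if r0 <= 0:
        raise DegenerateFitError("degenerate sphere patch (zero radius)")

    def res(v):
        return np.linalg.norm(P - v[:3], axis=1) - v[3]

    sol = least_squares(res, np.append(c0, r0), method="lm", xtol=1e-14, ftol=1e-14)
    center, radius = sol.x[:3], float(sol.x[3])
    rms = float(np.sqrt(np.mean(res(sol.x) ** 2)))
    return center, radius, rms


# ---------------------------------------------------------------------------
# cylinder


def _axis_from_angles(theta, phi):
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def fit_cylinder(patch):
    """Least-squares circular cylinder.

    Returns (axis_point, axis_dir, radius, rms_residual); axis_point is the
    on-axis point nearest the patch centroid (the joint center), axis_dir the
    hinge axis (sign not meaningful).
    """
    P = _as_points(patch)
    if P.shape[0] < 6:
        raise DegenerateFitError("cylinder fit needs at least 6 points")
    centroid = P.mean(axis=0)
    Q = P - centroid
    _, svals, Vt = np.linalg.svd(Q, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise DegenerateFitError("collinear cylinder patch")

    def residual(v):
        theta, phi, ox, oy, r = v
        a = _axis_from_angles(theta, phi)
        # axis passes through centroid + offset in the plane orthogonal to a
        e1, e2 = _orthonormal_complement(a)
        p0 = centroid + ox * e1 + oy * e2
        d = np.linalg.norm(np.cross(P - p0, a), axis=1)
        return d - r

    best = None
    for a0 in Vt:  # PCA directions as axis initializations
        theta0 = float(np.arccos(np.clip(a0[2], -1, 1)))
        phi0 = float(np.arctan2(a0[1], a0[0]))
        d0 = np.linalg.norm(np.cross(Q, a0), axis=1)
        v0 = np.array([theta0, phi0, 0.0, 0.0, max(np.mean(d0), 1e-3)])
        try:
            sol = least_squares(residual, v0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        cost = float(np.sum(sol.fun**2))
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise DegenerateFitError("cylinder fit failed to converge")
    sol = best[1]
    theta, phi, ox, oy, r = sol.x
    if r <= 0:
        raise DegenerateFitError("degenerate cylinder (non-positive radius)")
    a = _axis_from_angles(theta, phi)
    e1, e2 = _orthonormal_complement(a)
    p0 = centroid + ox * e1 + oy * e2
    # joint center: axis point nearest the centroid
    center = p0 + a * ((centroid - p0) @ a)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    extent = np.linalg.norm(P - centroid, axis=1).max()
    if r > 50.0 * extent:
        raise DegenerateFitError("degenerate (planar) cylinder patch")
    return center, a, float(r), rms


def _orthonormal_complement(a):
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# paraboloid


def fit_paraboloid(patch):
    """Least-squares elliptic paraboloid z' = kx x'^2 + ky y'^2.

    Returns (apex (3,), frame (3x3, columns x', y', z'), curvatures (kx, ky)).
    The apex models the thumb-CMC joint center and the frame its rotation
    axes (x'/y' along the principal curvature directions; which maps to
    flexion/extension vs deviation is a configuration choice).
    """
    P = _as_points(patch)
    if P.shape[0] < 9:
        raise DegenerateFitError("paraboloid fit needs at least 9 points")
    centroid = P.mean(axis=0)
    Q = P - centroid
    _, svals, Vt = np.linalg.svd(Q, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise DegenerateFitError("patch does not span two surface directions")
    n = Vt[2]
    e1, e2 = Vt[0], Vt[1]
    xy = Q @ np.stack([e1, e2], axis=1)
    z = Q @ n
    # quadratic initialization z = c0 + c1 x + c2 y + c3 x^2 + c4 xy + c5 y^2
    X = np.column_stack(
        [np.ones_like(z), xy[:, 0], xy[:, 1], xy[:, 0] ** 2, xy[:, 0] * xy[:, 1], xy[:, 1] ** 2]
    )
    # points concentrated on a curve make the quadratic design rank-deficient
    sv = np.linalg.svd(X / max(np.abs(X).max(), 1e-30), compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        raise DegenerateFitError(
            "patch is (near-)degenerate: points do not span a 2D surface"
        )
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    H = np.array([[coef[3], coef[4] / 2.0], [coef[4] / 2.0, coef[5]]])
    evals, evecs = np.linalg.eigh(H)
    if abs(evals).min() < 1e-12:
        k_init = np.where(np.abs(evals) < 1e-12, 1e-6, evals)
    else:
        k_init = evals
    # apex of the initialized quadric
    try:
        xy0 = np.linalg.solve(2.0 * H, -coef[1:3])
    except np.linalg.LinAlgError:
        xy0 = np.zeros(2)
    z0 = float(X[0, 0] * coef[0] + coef[1] * xy0[0] + coef[2] * xy0[1]
               + coef[3] * xy0[0] ** 2 + coef[4] * xy0[0] * xy0[1] + coef[5] * xy0[1] ** 2)
    R0 = np.column_stack([e1, e2, n]) @ np.block(
        [[evecs, np.zeros((2, 1))], [np.zeros((1, 2)), np.ones((1, 1))]]
    )
    apex0 = centroid + np.column_stack([e1, e2]) @ xy0 + n * z0

    def pack_residual(v):
        rvec, apex, kx, ky = v[:3], v[3:6], v[6], v[7]
        R = _rotvec_to_matrix(rvec) @ R0
        L = (P - apex) @ R
        return L[:, 2] - kx * L[:, 0] ** 2 - ky * L[:, 1] ** 2

    v0 = np.concatenate([np.zeros(3), apex0, k_init])
    sol = least_squares(pack_residual, v0, method="lm", xtol=1e-14, ftol=1e-14)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    spread = np.linalg.norm(P - centroid, axis=1).std() + 1e-9
    if not sol.success and rms > 0.5 * spread:
        raise DegenerateFitError(
            f"paraboloid fit did not converge (rms residual {rms:.4g} mm)"
        )
    R = _rotvec_to_matrix(sol.x[:3]) @ R0
    apex = sol.x[3:6]
    kx, ky = float(sol.x[6]), float(sol.x[7])
    # deterministic orientation: open along +z', kx the larger curvature
    if kx + ky < 0:
        R = R @ np.diag([1.0, -1.0, -1.0])
        kx, ky = -kx, -ky
    if ky > kx:
        R = R @ np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        kx, ky = ky, kx
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    return apex, R, (kx, ky)


def _rotvec_to_matrix(rvec):
    angle = float(np.linalg.norm(rvec))
    if angle < 1e-12:
        return np.eye(3)
    from .model import rot_axis

    return rot_axis(np.asarray(rvec) / angle, angle)


# ---------------------------------------------------------------------------
# inertia


def load_mesh(path) -> trimesh.Trimesh:
    """Load an OBJ/STL/PLY surface mesh (coordinates mm)."""
    mesh = trimesh.load_mesh(path)
    if isinstance(mesh, trimesh.Scene):
        mesh = mesh.to_mesh()
    return mesh


class OpenMeshError(ValueError):
    pass


def mesh_inertial_properties(mesh, density_g_per_cm3: float = 1.0):
    """Exact polyhedral mass properties of a closed surface mesh.

    Returns (mass g, center of mass mm, principal moments g*mm^2 ascending,
    principal axes as columns of a right-handed rotation).  Divergence-
    theorem volume integrals; no voxelization, so the result is
    mesh-resolution independent up to the surface discretization itself.
    """
    if not isinstance(mesh, trimesh.Trimesh):
        mesh = load_mesh(mesh)
    if not mesh.is_watertight or not mesh.is_winding_consistent:
        boundary = len(getattr(mesh, "edges_boundary", []))
        raise OpenMeshError(
            f"mesh is not closed/consistently oriented ({boundary} boundary edges)"
        )
    if density_g_per_cm3 <= 0:
        raise ValueError("density must be positive")
    m = mesh.copy()
    if m.volume < 0:
        m.invert()
    m.density = density_g_per_cm3 / 1000.0  # g/cm^3 -> g/mm^3
    mass = float(m.mass)
    com = np.asarray(m.center_mass, dtype=float)
    inertia = np.asarray(m.moment_inertia, dtype=float)  # about com, g*mm^2
    evals, evecs = np.linalg.eigh(inertia)
    if np.linalg.det(evecs) < 0:
        evecs[:, 0] = -evecs[:, 0]
    return mass, com, evals, evecs


def box_inertial_properties(dims_mm, density_g_per_cm3: float = 1.0):
    """Rectangular-solid mass and principal moments: m = rho*a*b*c,
    Ix = m (b^2 + c^2)/12 etc.  Used for metacarpal and carpal segments."""
    a, b, c = (float(v) for v in dims_mm)
    if min(a, b, c) <= 0:
        raise ValueError(f"box dimensions must be positive, got {dims_mm}")
    if density_g_per_cm3 <= 0:
        raise ValueError("density must be positive")
    rho = density_g_per_cm3 / 1000.0
    m = rho * a * b * c
    I = np.array(
        [m * (b**2 + c**2) / 12.0, m * (a**2 + c**2) / 12.0, m * (a**2 + b**2) / 12.0]
    )
    return m, I


def principal_axes_frame(mesh, distal_reference=None):
    """Bone frame from the principal axes of inertia.

    Origin at the centroid; z along the shaft (the minimum-inertia axis of
    an elongated bone), x the maximum-inertia axis, y completing a
    right-handed frame.  ``distal_reference`` (a point, mm) disambiguates the
    +z sign toward the distal end; without it the sign is a deterministic
    tie-break (largest-magnitude component positive).
    """
    mass, com, evals, evecs = mesh_inertial_properties(mesh, 1.0)
    order = np.argsort(evals)  # ascending: [shaft, mid, max]
    z = evecs[:, order[0]]
    x = evecs[:, order[2]]
    rel = (evals[order[1]] - evals[order[0]]) / max(evals[order[2]], 1e-30)
    if rel < 1e-3:
        warnings.warn(
            "near-spherical inertia: principal axes are weakly determined; "
            "applying deterministic tie-break",
            stacklevel=2,
        )
    if distal_reference is not None:
        d = np.asarray(distal_reference, dtype=float) - com
        if d @ z < 0:
            z = -z
    elif z[np.argmax(np.abs(z))] < 0:
        z = -z
    if x[np.argmax(np.abs(x))] < 0:
        x = -x
    x = x - (x @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return com, R
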