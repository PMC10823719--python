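"""Dense surface sampling, rigid registration, and the reference symmetry plane.

The reference midsagittal plane is estimated without landmarks: mirror the
mesh across a trial plane, rigidly align the mirror back onto the original
with a robust (Tukey-biweight IRLS) iterative-closest-point registration,
and extract the invariant plane of the composite reflection-then-rigid map,
which is an improper isometry.  Iterating this to a fixed point yields the
plane across which the shape best matches its own mirror image — the
original–mirror alignment construction used throughout craniofacial
symmetry analysis.

Closest-point queries are exact: candidate triangles are pruned with a
k-d tree over triangle centroids using the bound that any triangle closer
than the current best must have its centroid within (best + R_max), where
R_max is the largest centroid-to-vertex distance in the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .meshcore import mirror_mesh, require_closed
from .plane import Plane

__all__ = [
    "QuasiLandmarkCloud",
    "RigidTransform",
    "RobustAlignmentResult",
    "DegenerateSymmetryError",
    "SurfaceDistanceQuery",
    "sample_quasi_landmarks",
    "nearest_surface_distance",
    "closest_points_on_surface",
    "procrustes_rigid",
    "robust_procrustes_icp",
    "reference_symmetry_plane",
]

#: default dense correspondence count (quasi-landmarks per surface)
DEFAULT_QUASI_LANDMARKS = 17_415
DEFAULT_SEED = 20240129


class DegenerateSymmetryError(RuntimeError):
    """Raised when the original-mirror alignment has no reflection component."""


@dataclass(frozen=True)
class QuasiLandmarkCloud:
    """Ordered dense surface samples; the order is the correspondence key."""

    points: np.ndarray
    face_index: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``x -> R x + t`` (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def angle_degrees(self) -> float:
        """Rotation angle of the map, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class RobustAlignmentResult:
    """Diagnostics of a robust ICP run."""

    transform: RigidTransform
    weights: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))


# ---------------------------------------------------------------------------
# surface sampling and exact closest-point queries


def sample_quasi_landmarks(
    mesh: trimesh.Trimesh,
    n: int = DEFAULT_QUASI_LANDMARKS,
    seed: int = DEFAULT_SEED,
) -> QuasiLandmarkCloud:
    """Area-weighted uniform random samples on the mesh surface.

    Deterministic for a given seed; the resulting ordered cloud stands in
    for the dense homologous quasi-landmarks of template mapping.
    """
    if n < 1:
        raise ValueError("sample count must be >= 1")
    if mesh.area <= 0:
        raise ValueError("cannot sample a zero-area mesh")
    points, fidx = trimesh.sample.sample_surface(mesh, n, seed=seed)
    return QuasiLandmarkCloud(points=np.asarray(points, dtype=float),
                              face_index=np.asarray(fidx), seed=seed)


def _point_triangle_closest(P: np.ndarray, T: np.ndarray):
    """Closest point on triangle T[i] to point P[i], exactly, vectorised.

    The in-plane projection is used when its barycentric coordinates are all
    nonnegative; otherwise the closest of the three clamped edge points.
    """
    A, B, C = T[:, 0], T[:, 1], T[:, 2]
    e0, e1, w = B - A, C - A, P - A
    a = np.einsum("ij,ij->i", e0, e0)
    b = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)
    d0 = np.einsum("ij,ij->i", e0, w)
    d1 = np.einsum("ij,ij->i", e1, w)
    det = a * c - b * b
    safe = det > 1e-30
    det_s = np.where(safe, det, 1.0)
    s = (c * d0 - b * d1) / det_s
    t = (a * d1 - b * d0) / det_s
    inside = safe & (s >= 0) & (t >= 0) & (s + t <= 1)
    proj = A + s[:, None] * e0 + t[:, None] * e1

    def seg(P0, Q0, Q1):
        d = Q1 - Q0
        dd = np.einsum("ij,ij->i", d, d)
        u = np.einsum("ij,ij->i", P0 - Q0, d) / np.where(dd > 0, dd, 1.0)
        u = np.clip(u, 0.0, 1.0)
        return Q0 + u[:, None] * d

    cands = np.stack([
        np.where(inside[:, None], proj, np.inf),
        seg(P, A, B),
        seg(P, B, C),
        seg(P, C, A),
    ])  # (4, n, 3)
    dists = np.linalg.norm(np.where(np.isfinite(cands), cands, 1e30) - P, axis=2)
    best = np.argmin(dists, axis=0)
    idx = np.arange(len(P))
    closest = cands[best, idx]
    return closest, dists[best, idx]


class SurfaceDistanceQuery:
    """Reusable exact closest-point structure for one mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise ValueError("mesh has no faces")
        tris = np.asarray(mesh.triangles, dtype=float)
        face_of = np.arange(len(tris))
        # oversized triangles inflate the candidate radius (u + R_max); split
        # them 1->4 for the query structure only — the union surface, hence
        # every distance, is unchanged
        radii = np.linalg.norm(tris - tris.mean(axis=1, keepdims=True), axis=2).max(axis=1)
        limit = max(2.0 * float(np.median(radii)), 1e-9)
        for _ in range(6):
            big = radii > limit
            if not big.any():
                break
            A, B, C = tris[big, 0], tris[big, 1], tris[big, 2]
            ab, bc, ca = (A + B) / 2, (B + C) / 2, (C + A) / 2
            quads = np.concatenate([
                np.stack([A, ab, ca], axis=1), np.stack([ab, B, bc], axis=1),
                np.stack([ca, bc, C], axis=1), np.stack([ab, bc, ca], axis=1),
            ])
            tris = np.concatenate([tris[~big], quads])
            face_of = np.concatenate([face_of[~big], np.tile(face_of[big], 4)])
            radii = np.linalg.norm(tris - tris.mean(axis=1, keepdims=True), axis=2).max(axis=1)
        self.triangles = tris
        self._face_of = face_of
        self.centroids = tris.mean(axis=1)
        self._tree = cKDTree(self.centroids)
        self._rmax = float(radii.max())

    def query(self, points):
        """(closest points, distances, triangle indices) for each query point."""
        P = np.asarray(points, dtype=float).reshape(-1, 3)
        dc, ic = self._tree.query(P)
        # exact distance to the nearest-centroid triangle = upper bound
        _, ub = _point_triangle_closest(P, self.triangles[ic])
        radii = np.maximum(ub + self._rmax, dc) * (1 + 1e-12)
        groups = self._tree.query_ball_point(P, radii)
        counts = np.fromiter((len(g) for g in groups), dtype=np.int64, count=len(P))
        flat_tri = np.concatenate(groups) if len(P) else np.empty(0, dtype=np.int64)
        flat_pt = np.repeat(np.arange(len(P)), counts)

        best_d = np.full(len(P), np.inf)
        best_q = np.zeros((len(P), 3))
        best_i = np.zeros(len(P), dtype=np.int64)
        chunk = 500_000
        for start in range(0, len(flat_pt), chunk):
            sl = slice(start, start + chunk)
            pi, ti = flat_pt[sl], np.asarray(flat_tri[sl], dtype=np.int64)
            q, d = _point_triangle_closest(P[pi], self.triangles[ti])
            # per-point argmin within the chunk, then merge with the running best
            order = np.lexsort((d, pi))
            pi_o = pi[order]
            first = np.concatenate(([True], pi_o[1:] != pi_o[:-1]))
            sel = order[first]
            upd = d[sel] < best_d[pi[sel]]
            tgt = pi[sel][upd]
            best_d[tgt] = d[sel][upd]
            best_q[tgt] = q[sel][upd]
            best_i[tgt] = ti[sel][upd]
        return best_q, best_d, self._face_of[best_i]


def closest_points_on_surface(points, mesh: trimesh.Trimesh):
    """Closest point on the mesh surface for each query point."""
    return SurfaceDistanceQuery(mesh).query(points)


def nearest_surface_distance(points, mesh: trimesh.Trimesh) -> np.ndarray:
    """Exact Euclidean distance from each point to the mesh surface (mm)."""
    _, d, _ = SurfaceDistanceQuery(mesh).query(points)
    return d


# ---------------------------------------------------------------------------
# rigid registration


def procrustes_rigid(source, target, weights=None) -> RigidTransform:
    """Weighted least-squares rigid fit (Kabsch) of source onto target.

    Minimises ``sum w_i || R s_i + t - t_i ||^2`` over rotations with
    det(R) = +1 (reflections are rejected via the sign of the smallest
    singular value) and translations.
    """
    S = np.asarray(source, dtype=float).reshape(-1, 3)
    T = np.asarray(target, dtype=float).reshape(-1, 3)
    if S.shape != T.shape:
        raise ValueError("source and target must have equal shapes")
    if weights is None:
        w = np.ones(len(S))
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
    if (w > 0).sum() < 3:
        raise ValueError("need at least 3 points with positive weight")
    wsum = w.sum()
    mu_s = (w[:, None] * S).sum(axis=0) / wsum
    mu_t = (w[:, None] * T).sum(axis=0) / wsum
    H = (w[:, None] * (S - mu_s)).T @ (T - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidTransform(R, t)


def _tukey_weights(r: np.ndarray, scale: float) -> np.ndarray:
    c = 4.685 * scale
    if c <= 0:
        return np.ones_like(r)
    u = r / c
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w


def _tukey_rho(r: np.ndarray, scale: float) -> np.ndarray:
    c = 4.685 * scale
    if c <= 0:
        return 0.5 * r**2
    u = np.minimum(r / c, 1.0)
    return (c**2 / 6.0) * (1.0 - (1.0 - u**2) ** 3)


def robust_procrustes_icp(
    source_mesh: trimesh.Trimesh,
    target_mesh: trimesh.Trimesh,
    n_samples: int = 5000,
    seed: int = DEFAULT_SEED,
    max_iter: int = 300,
    tol: float = 1e-4,
    robust: bool = True,
    n_scale_phases: int = 3,
    final_n: int | None = None,
) -> RobustAlignmentResult:
    """Robust rigid registration of one surface onto another.

    Alternates closest-point correspondence with a Tukey-biweight
    IRLS-weighted Kabsch solve.  The robust scale (1.4826 * MAD of the
    residuals) is held fixed while the transform converges, then
    re-estimated from the converged residuals and the registration resumed,
    for up to ``n_scale_phases`` phases: the first phase sees residuals
    dominated by the initial misalignment, so only after convergence does
    the MAD reflect the true inlier spread and the cutoff start rejecting
    deformed regions.  Within a phase the objective (mean Tukey rho at the
    frozen scale) is provably non-increasing — each weighted Kabsch step is
    a majorise-minimise update and re-matching to the closest point can
    only shrink residuals; ``objective_trace`` reports the final phase.

    Non-convergence is reported through ``converged``, never raised.
    """
    if len(source_mesh.faces) == 0 or len(target_mesh.faces) == 0:
        raise ValueError("both meshes must be non-empty")
    cloud = sample_quasi_landmarks(source_mesh, n_samples, seed=seed)
    P0 = cloud.points
    query = SurfaceDistanceQuery(target_mesh)
    xform = RigidTransform.identity()
    corners = trimesh.bounds.corners(source_mesh.bounds)
    trace: list[float] = []
    weights = np.ones(len(P0))
    residuals = np.zeros(len(P0))
    converged = False
    total_it = 0
    scale = 0.0
    phases = n_scale_phases if robust else 1
    for phase in range(phases):
        _, r0, _ = query.query(xform.apply(P0))
        if robust:
            med = np.median(r0)
            new_scale = float(1.4826 * np.median(np.abs(r0 - med)))
            if phase > 0 and converged and abs(new_scale - scale) < 0.05 * max(scale, 1e-12):
                break
            scale = new_scale
        trace = []
        converged = False
        for _ in range(1, max_iter + 1):
            total_it += 1
            moved = xform.apply(P0)
            Q, residuals, _ = query.query(moved)
            if robust and scale >= 1e-9:
                weights = _tukey_weights(residuals, scale)
                trace.append(float(np.mean(_tukey_rho(residuals, scale))))
            else:
                weights = np.ones(len(P0))
                trace.append(float(np.mean(0.5 * residuals**2)))
            if (weights > 0).sum() < 3:
                break
            new = procrustes_rigid(P0, Q, weights)
            # convergence: largest displacement of the source bounding box
            delta = np.linalg.norm(new.apply(corners) - xform.apply(corners), axis=1).max()
            xform = new
            if delta < tol:
                converged = True
                break
    if final_n is not None and final_n != len(P0):
        cloudf = sample_quasi_landmarks(source_mesh, final_n, seed=seed + 1)
        _, residuals, _ = query.query(xform.apply(cloudf.points))
        weights = _tukey_weights(residuals, scale) if (robust and scale >= 1e-9) else np.ones(final_n)
    return RobustAlignmentResult(
        transform=xform,
        weights=weights,
        residuals=residuals,
        iterations=total_it,
        converged=converged,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# reference symmetry plane


def _principal_planes(mesh: trimesh.Trimesh, samples: np.ndarray) -> list[Plane]:
    centroid = samples.mean(axis=0)
    cov = np.cov((samples - centroid).T)
    _, vecs = np.linalg.eigh(cov)
    return [Plane(vecs[:, k], float(vecs[:, k] @ centroid)) for k in range(3)]


def reference_symmetry_plane(
    mesh: trimesh.Trimesh,
    n_samples: int = 5000,
    seed: int = DEFAULT_SEED,
    max_outer: int = 20,
    plane_tol_degrees: float = 0.01,
    offset_tol: float = 1e-3,
    icp_kwargs: dict | None = None,
) -> tuple[Plane, RobustAlignmentResult]:
    """Algorithmic optimal symmetry plane by original–mirror alignment.

    1. Seed with the best of the three centroid-anchored principal planes
       (coarse mirrored-sample residual).
    2. Mirror the mesh across the current plane and robustly align the
       mirror back onto the original, giving a rigid map T.
    3. The composite ``M = T ∘ Reflect(plane)`` is an improper isometry;
       its invariant plane (eigenvector of the linear part for eigenvalue
       -1; offset from the translation component) is the improved estimate.
    4. Repeat until the plane stops moving.
    """
    require_closed(mesh, "reference_symmetry_plane")
    icp_kwargs = dict(icp_kwargs or {})
    icp_kwargs.setdefault("n_samples", n_samples)
    icp_kwargs.setdefault("seed", seed)

    cloud = sample_quasi_landmarks(mesh, min(2000, n_samples), seed=seed)
    query = SurfaceDistanceQuery(mesh)

    def coarse_residual(plane: Plane) -> float:
        _, d, _ = query.query(plane.reflect(cloud.points))
        return float(np.sqrt(np.mean(d**2)))

    planes = _principal_planes(mesh, cloud.points)
    plane = min(planes, key=coarse_residual)

    result: RobustAlignmentResult | None = None
    for _ in range(max_outer):
        mirrored = mirror_mesh(mesh, plane)
        result = robust_procrustes_icp(mirrored, mesh, **icp_kwargs)
        R, t = result.transform.rotation, result.transform.translation
        n, d = plane.normal, plane.offset
        # Reflect(x) = H x + 2 d n with H = I - 2 n n^T
        A = R @ (np.eye(3) - 2.0 * np.outer(n, n))
        b = R @ (2.0 * d * n) + t
        vals, vecs = np.linalg.eig(A)
        k = int(np.argmin(np.abs(vals + 1.0)))
        if abs(vals[k] + 1.0) > 1e-6:
            raise DegenerateSymmetryError(
                "original-mirror alignment collapsed: composite map has no "
                f"reflection eigenvalue (closest {vals[k]:.6f})"
            )
        m = np.real(vecs[:, k])
        m /= np.linalg.norm(m)
        new_plane = Plane(m, float(m @ b) / 2.0)
        moved_angle = plane.angle_to(new_plane)
        moved_offset = abs(new_plane.offset - plane.offset)
        plane = new_plane
        if moved_angle < plane_tol_degrees and moved_offset < offset_tol:
            break
    assert result is not None
    return plane, result
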