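"""Per-plane asymmetry metrics.

Given a candidate midsagittal plane these quantify how well it splits the
mandible into mirror halves:

* **Asymmetry index (AI)** — root-mean-square of the pointwise
  surface-to-surface distances between the model and its mirror image
  across the plane, over a dense quasi-landmark sample (mm).  Zero means
  perfect mirror symmetry.  No re-alignment follows the mirroring: the AI
  measures the plane itself, which is what makes candidate planes
  comparable (a free rigid alignment after mirroring would erase the
  between-plane differences the screening relies on).
* **Similarity index (SI)** — split the mesh into sides A and B, mirror B
  across the plane, and form ``2 V(A ∩ B') / (V(A) + V(B'))`` from voxel
  overlap; 1 for perfect symmetry.
* **Side-volume difference** — |V_A - V_B| in mm³.
* **Landmark distance difference** — per bilateral pair, the absolute
  difference of the unsigned left/right distances to the plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import stats

from .alignment import (
    DEFAULT_QUASI_LANDMARKS,
    DEFAULT_SEED,
    SurfaceDistanceQuery,
    sample_quasi_landmarks,
)
from .landmarks import BILATERAL_NAMES, LandmarkSet
from .meshcore import mesh_volume, mirror_mesh, overlap_volume, split_mesh_by_plane
from .plane import Plane

__all__ = [
    "AsymmetryMap",
    "PlaneEvaluation",
    "asymmetry_index",
    "asymmetry_colormap_values",
    "similarity_index",
    "volume_difference",
    "landmark_distance_difference",
    "evaluate_plane",
    "paired_t_test",
    "PairedTTestResult",
]

DEFAULT_VOXEL_PITCH = 0.5  # mm
COLORMAP_VMAX = 4.0  # mm; deviations beyond this saturate the color map


@dataclass(frozen=True)
class AsymmetryMap:
    """Dense per-point mirror deviations and their RMS summary."""

    distances: np.ndarray
    plane: Plane
    seed: int

    @property
    def n(self) -> int:
        return len(self.distances)

    @property
    def ai(self) -> float:
        """Overall asymmetry index: RMS of the pointwise deviations (mm)."""
        return float(np.sqrt(np.mean(self.distances**2)))

    @property
    def ai_mean(self) -> float:
        """Mean absolute deviation (mm), a secondary summary."""
        return float(np.mean(self.distances))


@dataclass(frozen=True)
class PlaneEvaluation:
    """Distance/volume/overlap adjudication of one plane."""

    plane: Plane
    pair_distance_diff: dict[str, float]
    mean_distance_diff: float
    volume_a: float
    volume_b: float
    volume_diff: float
    similarity: float


def asymmetry_index(
    mesh: trimesh.Trimesh,
    plane: Plane,
    n: int = DEFAULT_QUASI_LANDMARKS,
    seed: int = DEFAULT_SEED,
    query: SurfaceDistanceQuery | None = None,
    cloud=None,
) -> AsymmetryMap:
    """Mirror the quasi-landmark cloud across the plane and measure deviation.

    ``query`` and ``cloud`` allow reuse across many candidate planes of the
    same mesh (the expensive parts depend only on the mesh).
    """
    if cloud is None:
        cloud = sample_quasi_landmarks(mesh, n, seed=seed)
    if query is None:
        query = SurfaceDistanceQuery(mesh)
    reflected = plane.reflect(cloud.points)
    _, d, _ = query.query(reflected)
    return AsymmetryMap(distances=d, plane=plane, seed=cloud.seed)


def asymmetry_colormap_values(amap: AsymmetryMap | np.ndarray,
                              vmax: float = COLORMAP_VMAX) -> np.ndarray:
    """Normalise deviations to [0, 1] for color-map export.

    Saturates at ``vmax`` (default 4 mm): everything at or beyond maps to 1
    ("red"), zero deviation maps to 0 ("dark blue").
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    d = amap.distances if isinstance(amap, AsymmetryMap) else np.asarray(amap, dtype=float)
    return np.clip(d / vmax, 0.0, 1.0)


def _split_sides(mesh: trimesh.Trimesh, plane: Plane):
    """(side_a, side_b) with A the side whose centroid has smaller x."""
    neg, pos = split_mesh_by_plane(mesh, plane)
    if len(neg.faces) and len(pos.faces):
        if neg.vertices[:, 0].mean() <= pos.vertices[:, 0].mean():
            return neg, pos
        return pos, neg
    return neg, pos


def similarity_index(
    mesh: trimesh.Trimesh,
    plane: Plane,
    pitch: float = DEFAULT_VOXEL_PITCH,
) -> float:
    """Voxel-overlap similarity ``2 V(A ∩ B') / (V(A) + V(B'))`` in [0, 1].

    B' is side B mirrored across the plane; pitch is the voxel edge (mm).
    """
    side_a, side_b = _split_sides(mesh, plane)
    if len(side_a.faces) == 0 or len(side_b.faces) == 0:
        warnings.warn("plane does not intersect the mesh; similarity index 0",
                      stacklevel=2)
        return 0.0
    mirrored_b = mirror_mesh(side_b, plane)
    inter = overlap_volume(side_a, mirrored_b, pitch)
    va, vb = mesh_volume(side_a), mesh_volume(mirrored_b)
    if va + vb == 0:
        return 0.0
    return float(np.clip(2.0 * inter / (va + vb), 0.0, 1.0))


def volume_difference(mesh: trimesh.Trimesh, plane: Plane):
    """Side volumes and their absolute difference, mm³; A + B = total."""
    side_a, side_b = _split_sides(mesh, plane)
    va = mesh_volume(side_a) if len(side_a.faces) else 0.0
    vb = mesh_volume(side_b) if len(side_b.faces) else 0.0
    return va, vb, abs(va - vb)


def landmark_distance_difference(landmarks: LandmarkSet, plane: Plane):
    """| |d_left| - |d_right| | per bilateral pair, and the mean (mm).

    Distances are unsigned perpendicular distances to the plane.  Pairs with
    a missing side are skipped with a warning.
    """
    diffs: dict[str, float] = {}
    for name in BILATERAL_NAMES:
        present_l = (name, "L") in landmarks
        present_r = (name, "R") in landmarks
        if not (present_l or present_r):
            continue
        if not (present_l and present_r):
            warnings.warn(f"bilateral landmark {name} missing one side; skipped",
                          stacklevel=2)
            continue
        left, right = landmarks.pair(name)
        diffs[name] = abs(
            abs(plane.signed_distance(left)) - abs(plane.signed_distance(right))
        )
    mean = float(np.mean(list(diffs.values()))) if diffs else float("nan")
    return diffs, mean


def evaluate_plane(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    plane: Plane,
    pitch: float = DEFAULT_VOXEL_PITCH,
) -> PlaneEvaluation:
    """Full distance/volume/similarity adjudication of one plane."""
    diffs, mean = landmark_distance_difference(landmarks, plane)
    va, vb, dv = volume_difference(mesh, plane)
    si = similarity_index(mesh, plane, pitch)
    return PlaneEvaluation(
        plane=plane,
        pair_distance_diff=diffs,
        mean_distance_diff=mean,
        volume_a=va,
        volume_b=vb,
        volume_diff=dv,
        similarity=si,
    )


# ---------------------------------------------------------------------------
# paired t test


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False

    @property
    def stars(self) -> str:
        """Significance stars at 0.05 (*) and 0.01 (**)."""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def paired_t_test(x, y) -> PairedTTestResult:
    """Two-sided paired-sample t test of mean(x - y) = 0.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with df = n - 1.  Identical samples
    give t = 0, p = 1; a constant nonzero difference has zero variance and
    is flagged degenerate with p reported as the machine floor.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired samples of equal length n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return PairedTTestResult(t=0.0, df=n - 1, p=1.0)
        return PairedTTestResult(
            t=float(np.sign(d.mean()) * np.inf), df=n - 1,
            p=float(np.finfo(float).tiny), degenerate=True,
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTTestResult(t=float(t), df=n - 1, p=float(p))
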