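"""Candidate-plane screening and adjudication.

The screening pipeline mirrors landmark-based midsagittal-plane practice:
from the 7 midline points (5 central landmarks plus the bilateral F and MF
midpoints) build all C(7,3) = 35 candidate planes, score each one by the
asymmetry index of the mesh mirrored across it, keep the best few, and
adjudicate them against the algorithmic reference symmetry plane through
landmark-distance differences, side-volume differences and the
volume-overlap similarity index, with paired t tests across a cohort.

The user-facing surface follows the model/results convention:

>>> model = MidsagittalScreen(mesh, landmarks)      # doctest: +SKIP
>>> res = model.fit()                               # doctest: +SKIP
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .alignment import (
    DEFAULT_QUASI_LANDMARKS,
    DEFAULT_SEED,
    RobustAlignmentResult,
    SurfaceDistanceQuery,
    reference_symmetry_plane,
    sample_quasi_landmarks,
)
from .landmarks import (
    BILATERAL_NAMES,
    LandmarkSet,
    enumerate_triplets,
    midline_points,
)
from .metrics import (
    DEFAULT_VOXEL_PITCH,
    PlaneEvaluation,
    asymmetry_index,
    evaluate_plane,
    paired_t_test,
)
from .plane import CollinearPointsError, Plane, plane_from_points, triangle_condition

__all__ = [
    "PlaneScore",
    "screen_planes",
    "select_top_k",
    "cohort_summary",
    "evaluate_candidates",
    "cohort_evaluation_tables",
    "MidsagittalScreen",
    "ScreenResults",
]


@dataclass(frozen=True)
class PlaneScore:
    """AI score of one candidate triplet plane."""

    triplet: tuple[str, str, str]
    plane: Plane | None
    ai: float | None
    ai_mean: float | None
    condition: float
    degenerate: bool = False

    @property
    def label(self) -> str:
        return "-".join(self.triplet)

    def sort_key(self):
        return (self.degenerate, self.ai if self.ai is not None else np.inf, self.label)


def screen_planes(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    n: int = DEFAULT_QUASI_LANDMARKS,
    seed: int = DEFAULT_SEED,
    query: SurfaceDistanceQuery | None = None,
) -> list[PlaneScore]:
    """Score all 35 candidate planes; ascending AI, degenerate triplets last.

    Near-collinear triplets are kept in the output, flagged degenerate with
    no AI, so reports always carry the full candidate list.  The same
    quasi-landmark cloud scores every plane, so rankings are deterministic
    given the seed.
    """
    midline = midline_points(landmarks)
    cloud = sample_quasi_landmarks(mesh, n, seed=seed)
    query = query or SurfaceDistanceQuery(mesh)
    scores: list[PlaneScore] = []
    for triplet in enumerate_triplets(midline):
        pts = [midline[name] for name in triplet]
        cond = triangle_condition(*pts)
        try:
            plane = plane_from_points(*pts)
        except CollinearPointsError:
            scores.append(PlaneScore(triplet, None, None, None, cond, degenerate=True))
            continue
        amap = asymmetry_index(mesh, plane, query=query, cloud=cloud)
        scores.append(PlaneScore(triplet, plane, amap.ai, amap.ai_mean, cond))
    scores.sort(key=PlaneScore.sort_key)
    return scores


def select_top_k(scores: list[PlaneScore], k: int = 4) -> list[PlaneScore]:
    """The k lowest-AI planes; ties broken lexicographically by label."""
    valid = sorted((s for s in scores if not s.degenerate), key=PlaneScore.sort_key)
    if len(valid) < k:
        raise ValueError(f"only {len(valid)} non-degenerate planes; need {k}")
    return valid[:k]


def scores_frame(scores: list[PlaneScore]) -> pd.DataFrame:
    """Tabular view of a ranked score list."""
    return pd.DataFrame(
        {
            "plane": [s.label for s in scores],
            "AI_rms": [s.ai for s in scores],
            "AI_mean": [s.ai_mean for s in scores],
            "condition": [s.condition for s in scores],
            "degenerate": [s.degenerate for s in scores],
        }
    )


def cohort_summary(per_subject_scores: list[list[PlaneScore]]) -> pd.DataFrame:
    """Median / IQR / min–max of each triplet's AI across subjects.

    Quantiles use linear interpolation; degenerate scores are excluded.
    Rows are ordered by median AI.
    """
    if not per_subject_scores:
        raise ValueError("need at least one subject")
    by_label: dict[str, list[float]] = {}
    for scores in per_subject_scores:
        for s in scores:
            if not s.degenerate and s.ai is not None:
                by_label.setdefault(s.label, []).append(s.ai)
    rows = []
    for label, ais in by_label.items():
        a = np.asarray(ais)
        rows.append(
            {
                "plane": label,
                "median": float(np.median(a)),
                "q25": float(np.percentile(a, 25)),
                "q75": float(np.percentile(a, 75)),
                "min": float(a.min()),
                "max": float(a.max()),
                "n": len(a),
            }
        )
    frame = pd.DataFrame(rows).sort_values(["median", "plane"]).reset_index(drop=True)
    return frame


def evaluate_candidates(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    candidates: dict[str, Plane],
    reference: Plane,
    pitch: float = DEFAULT_VOXEL_PITCH,
) -> dict[str, PlaneEvaluation]:
    """Distance/volume/similarity evaluation of candidates and reference.

    Returns a mapping label -> :class:`PlaneEvaluation`, with the reference
    plane under the label ``"reference"``.
    """
    out = {"reference": evaluate_plane(mesh, landmarks, reference, pitch)}
    for label, plane in candidates.items():
        out[label] = evaluate_plane(mesh, landmarks, plane, pitch)
    return out


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (an extension beyond the plain test)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def cohort_evaluation_tables(
    per_subject_evals: list[dict[str, PlaneEvaluation]],
    holm: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort distance and volume/similarity tables with paired t tests.

    ``per_subject_evals`` maps, for each subject, plane labels (including
    ``"reference"``) to evaluations.  The distance table has one row per
    bilateral landmark plus a mean row: reference mean ± sd, then per
    candidate the mean ± sd and the paired test against the reference.
    The volume/similarity table has one row per plane with the paired tests
    of |V_A - V_B| and SI against the reference.  Stars: * p<0.05, ** p<0.01.
    """
    if not per_subject_evals:
        raise ValueError("empty cohort")
    labels = [k for k in per_subject_evals[0] if k != "reference"]

    pair_names = [
        n for n in BILATERAL_NAMES
        if all(n in ev["reference"].pair_distance_diff for ev in per_subject_evals)
    ]

    def column(label: str, name: str | None) -> np.ndarray:
        if name is None:
            return np.array([ev[label].mean_distance_diff for ev in per_subject_evals])
        return np.array([ev[label].pair_distance_diff[name] for ev in per_subject_evals])

    dist_rows = []
    for name in pair_names + [None]:
        row = {"landmark": name or "Mean"}
        ref = column("reference", name)
        row["reference"] = f"{ref.mean():.2f} ± {ref.std(ddof=1):.2f}"
        pvals = []
        for label in labels:
            vals = column(label, name)
            test = paired_t_test(vals, ref)
            row[label] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
            row[f"{label}_p"] = test.p
            row[f"{label}_sig"] = test.stars
            pvals.append(test.p)
        if holm:
            for label, adj in zip(labels, _holm(pvals)):
                row[f"{label}_p_holm"] = adj
        dist_rows.append(row)
    distance_table = pd.DataFrame(dist_rows)

    vol_rows = []
    ref_vol = np.array([ev["reference"].volume_diff for ev in per_subject_evals])
    ref_si = np.array([ev["reference"].similarity for ev in per_subject_evals])
    vol_rows.append(
        {
            "plane": "reference",
            "volume_diff": f"{ref_vol.mean():.2f} ± {ref_vol.std(ddof=1):.2f}",
            "volume_p": np.nan,
            "similarity": f"{ref_si.mean():.3f} ± {ref_si.std(ddof=1):.3f}",
            "similarity_p": np.nan,
        }
    )
    for label in labels:
        vol = np.array([ev[label].volume_diff for ev in per_subject_evals])
        si = np.array([ev[label].similarity for ev in per_subject_evals])
        tv = paired_t_test(vol, ref_vol)
        ts = paired_t_test(si, ref_si)
        vol_rows.append(
            {
                "plane": label,
                "volume_diff": f"{vol.mean():.2f} ± {vol.std(ddof=1):.2f}",
                "volume_p": tv.p,
                "volume_sig": tv.stars,
                "similarity": f"{si.mean():.3f} ± {si.std(ddof=1):.3f}",
                "similarity_p": ts.p,
                "similarity_sig": ts.stars,
            }
        )
    volume_table = pd.DataFrame(vol_rows)
    return distance_table, volume_table


# ---------------------------------------------------------------------------
# model / results


class MidsagittalScreen:
    """Midsagittal-plane screening model for one subject.

    Parameters
    ----------
    mesh : trimesh.Trimesh
        Closed, outward-oriented mandible surface, coordinates in mm.
    landmarks : LandmarkSet
        Must contain the five central landmarks and bilateral F and MF.
    n_samples : int
        Quasi-landmark count for the asymmetry index (default 17,415).
    pitch : float
        Voxel edge for similarity-index overlap volumes (mm).
    top_k : int
        How many lowest-AI planes to evaluate against the reference.
    seed : int
        Controls the surface sampling; fixed seed gives identical rankings.
    """

    def __init__(
        self,
        mesh: trimesh.Trimesh,
        landmarks: LandmarkSet,
        n_samples: int = DEFAULT_QUASI_LANDMARKS,
        pitch: float = DEFAULT_VOXEL_PITCH,
        top_k: int = 4,
        seed: int = DEFAULT_SEED,
    ):
        self.mesh = mesh
        self.landmarks = landmarks
        self.n_samples = int(n_samples)
        self.pitch = float(pitch)
        self.top_k = int(top_k)
        self.seed = int(seed)

    @classmethod
    def from_files(cls, mesh_path, landmarks_path, **kwargs) -> "MidsagittalScreen":
        from .landmarks import read_landmarks
        from .meshcore import load_mesh

        return cls(load_mesh(mesh_path), read_landmarks(landmarks_path), **kwargs)

    def fit(
        self,
        compute_reference: bool = True,
        evaluate: bool = True,
        reference_plane: Plane | None = None,
        icp_samples: int = 5000,
    ) -> "ScreenResults":
        """Run the screening: rank the 35 planes, find the reference, evaluate.

        ``reference_plane`` overrides the algorithmic original–mirror
        estimate (e.g. a plane from another modality).
        """
        query = SurfaceDistanceQuery(self.mesh)
        scores = screen_planes(
            self.mesh, self.landmarks, n=self.n_samples, seed=self.seed, query=query
        )
        top = select_top_k(scores, self.top_k)
        ref: Plane | None = reference_plane
        alignment: RobustAlignmentResult | None = None
        if ref is None and compute_reference:
            ref, alignment = reference_symmetry_plane(
                self.mesh, n_samples=icp_samples, seed=self.seed
            )
        evaluations: dict[str, PlaneEvaluation] = {}
        if evaluate and ref is not None:
            evaluations = evaluate_candidates(
                self.mesh,
                self.landmarks,
                {s.label: s.plane for s in top},
                ref,
                pitch=self.pitch,
            )
        return ScreenResults(
            model=self,
            scores=scores,
            top=top,
            reference_plane=ref,
            reference_alignment=alignment,
            evaluations=evaluations,
        )


@dataclass
class ScreenResults:
    """Fitted screening results for one subject."""

    model: MidsagittalScreen
    scores: list[PlaneScore]
    top: list[PlaneScore]
    reference_plane: Plane | None
    reference_alignment: RobustAlignmentResult | None
    evaluations: dict[str, PlaneEvaluation] = field(default_factory=dict)

    @property
    def best(self) -> PlaneScore:
        """The lowest-AI candidate plane."""
        return self.top[0]

    @property
    def scores_frame(self) -> pd.DataFrame:
        return scores_frame(self.scores)

    @property
    def evaluation_frame(self) -> pd.DataFrame:
        rows = []
        for label, ev in self.evaluations.items():
            row = {
                "plane": label,
                "mean_distance_diff": ev.mean_distance_diff,
                "V_A": ev.volume_a,
                "V_B": ev.volume_b,
                "V_diff": ev.volume_diff,
                "SI": ev.similarity,
            }
            for name, v in ev.pair_distance_diff.items():
                row[f"d_{name}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text report: ranking, selection, reference adjudication."""
        lines = []
        lines.append("Midsagittal plane screening")
        lines.append("=" * 60)
        lines.append(
            f"quasi-landmarks: {self.model.n_samples}   seed: {self.model.seed}"
            f"   voxel pitch: {self.model.pitch} mm"
        )
        lines.append("")
        lines.append(f"Candidate planes ranked by asymmetry index "
                     f"(top {self.model.top_k} of {len(self.scores)}):")
        lines.append(f"{'plane':<14}{'AI (mm)':>10}{'AI mean':>10}{'condition':>11}")
        for s in self.scores[: max(self.model.top_k, 4)]:
            lines.append(
                f"{s.label:<14}{s.ai:>10.3f}{s.ai_mean:>10.3f}{s.condition:>11.3f}"
            )
        if self.reference_plane is not None:
            n = self.reference_plane.normal
            lines.append("")
            lines.append(
                f"Reference symmetry plane: normal = ({n[0]:+.4f}, {n[1]:+.4f}, "
                f"{n[2]:+.4f}), offset = {self.reference_plane.offset:.3f} mm"
            )
            if self.reference_alignment is not None:
                lines.append(
                    f"  original-mirror alignment: {self.reference_alignment.iterations}"
                    f" iterations, residual RMS {self.reference_alignment.rms:.4f} mm"
                )
            best = self.best
            lines.append(
                f"  best candidate {best.label}: {best.plane.angle_to(self.reference_plane):.3f} deg"
                " from reference"
            )
        if self.evaluations:
            lines.append("")
            lines.append("Adjudication against the reference plane:")
            lines.append(
                f"{'plane':<14}{'mean |dL-dR|':>13}{'V_diff (mm3)':>14}{'SI':>8}"
            )
            for label, ev in self.evaluations.items():
                lines.append(
                    f"{label:<14}{ev.mean_distance_diff:>13.3f}"
                    f"{ev.volume_diff:>14.2f}{ev.similarity:>8.4f}"
                )
        return "\n".join(lines)
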