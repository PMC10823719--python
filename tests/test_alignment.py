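import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation
from scipy.stats import chi2

from mandisym import alignment as al
from mandisym.alignment import RigidTransform
from mandisym.meshcore import as_mesh
from mandisym.plane import Plane
from mandisym.synthetic import AsymmetrySpec, inject_asymmetry


def test_sampling_count_and_determinism(mandible):
    mesh, _, _ = mandible
    cloud = al.sample_quasi_landmarks(mesh, 17_415, seed=9)
    assert cloud.n == 17_415
    again = al.sample_quasi_landmarks(mesh, 17_415, seed=9)
    assert np.array_equal(cloud.points, again.points)
    # every sample lies on the source surface
    d = al.nearest_surface_distance(cloud.points[::50], mesh)
    assert d.max() < 1e-9


def test_sampling_is_area_weighted():
    # two triangles with area ratio 3:1; per-face counts must be binomial
    verts = [(0, 0, 0), (3, 0, 0), (0, 2, 0), (-1, 0, 0), (0, -1, 0)]
    faces = [(0, 1, 2), (0, 3, 4)]  # areas 3 and 0.5 -> take 3:1 via scaling
    verts = np.asarray(verts, float)
    verts[3:] *= np.sqrt(6)  # second triangle area 0.5*6 = 3... adjust below
    mesh = as_mesh(verts, faces)
    areas = mesh.area_faces
    p = areas[0] / areas.sum()
    n = 40_000
    cloud = al.sample_quasi_landmarks(mesh, n, seed=3)
    n0 = int((cloud.face_index == 0).sum())
    # chi-square goodness of fit, 99% band, 1 dof
    expected = np.array([n * p, n * (1 - p)])
    observed = np.array([n0, n - n0])
    stat = ((observed - expected) ** 2 / expected).sum()
    assert stat < chi2.ppf(0.99, df=1)


def test_nearest_distance_simple_cases():
    square = as_mesh([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)],
                     [(0, 1, 2), (0, 2, 3)])
    d = al.nearest_surface_distance([(0.5, 0.5, 2.0), (0.5, 0.5, 0.0), (2, 0.5, 0)], square)
    assert d == pytest.approx([2.0, 0.0, 1.0], abs=1e-12)


def test_nearest_distance_matches_all_faces_brute_force(mandible, rng):
    mesh, _, _ = mandible
    pts = rng.uniform(-70, 70, size=(250, 3))
    tri = np.asarray(mesh.triangles)
    brute = np.array(
        [al._point_triangle_closest(np.repeat(p[None], len(tri), 0), tri)[1].min()
         for p in pts]
    )
    fast = al.nearest_surface_distance(pts, mesh)
    assert np.abs(fast - brute).max() < 1e-9


def test_kabsch_identity_and_zero_weight_exclusion(rng):
    pts = rng.normal(size=(30, 3))
    xf = al.procrustes_rigid(pts, pts)
    assert np.allclose(xf.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(xf.translation, 0, atol=1e-12)

    target = pts @ Rotation.from_euler("z", 30, degrees=True).as_matrix().T + [1, 2, 3]
    outlier_src = np.vstack([pts, [[100, 0, 0]]])
    outlier_tgt = np.vstack([target, [[0, 0, -50]]])
    w = np.ones(31)
    w[-1] = 0.0
    with_out = al.procrustes_rigid(outlier_src, outlier_tgt, w)
    without = al.procrustes_rigid(pts, target)
    assert np.allclose(with_out.rotation, without.rotation, atol=1e-12)
    assert np.allclose(with_out.translation, without.translation, atol=1e-12)


def test_kabsch_recovers_constructed_transforms(rng):
    pts = rng.normal(size=(40, 3))
    for k in range(25):
        R = Rotation.random(random_state=k).as_matrix()
        t = rng.uniform(-20, 20, 3)
        xf = al.procrustes_rigid(pts, pts @ R.T + t)
        assert np.abs(xf.rotation - R).max() < 1e-9
        assert np.abs(xf.translation - t).max() < 1e-9


def test_kabsch_beats_random_rotation_search(rng):
    # independent oracle: dense random search over rotations on a 4-point cloud
    src = rng.normal(size=(4, 3))
    tgt = rng.normal(size=(4, 3))
    xf = al.procrustes_rigid(src, tgt)

    def sse(R):
        t = tgt.mean(0) - R @ src.mean(0)
        return ((src @ R.T + t - tgt) ** 2).sum()

    best_random = min(sse(R) for R in Rotation.random(20_000, random_state=7).as_matrix())
    assert sse(xf.rotation) <= best_random + 1e-9
    assert best_random - sse(xf.rotation) < 0.05 * max(best_random, 1.0)


def test_icp_mesh_vs_itself_is_identity(mandible):
    mesh, _, _ = mandible
    res = al.robust_procrustes_icp(mesh, mesh, n_samples=1500, seed=2)
    assert res.converged
    assert res.rms < 1e-6
    assert res.transform.angle_degrees() < 1e-4


def test_icp_recovers_rigid_motion(mandible):
    mesh, _, _ = mandible
    R = Rotation.from_rotvec(np.radians(12) * np.array([0.2, 0.9, 0.4]) /
                             np.linalg.norm([0.2, 0.9, 0.4])).as_matrix()
    T = RigidTransform(R, np.array([5.0, -8.0, 3.0]))
    moved = as_mesh(T.apply(mesh.vertices), mesh.faces)
    res = al.robust_procrustes_icp(moved, mesh, n_samples=2000, seed=4)
    err = res.transform.compose(T)
    assert err.angle_degrees() < 0.1
    assert np.linalg.norm(err.translation) < 0.5


def test_icp_objective_trace_non_increasing(mandible):
    mesh, _, _ = mandible
    R = Rotation.from_euler("y", 8, degrees=True).as_matrix()
    moved = as_mesh(mesh.vertices @ R.T + [3, 1, -2], mesh.faces)
    res = al.robust_procrustes_icp(moved, mesh, n_samples=1000, seed=6)
    trace = np.asarray(res.objective_trace)
    assert np.all(np.diff(trace) <= 1e-12)
    assert 0.0 <= res.weights.min() and res.weights.max() <= 1.0


def test_robust_icp_downweights_outlier_bump(mandible):
    # a localized deformation on ~5% of the surface should hurt the
    # unweighted variant far more than the robust one
    mesh, lms, _ = mandible
    bumped, _ = inject_asymmetry(
        mesh, lms, AsymmetrySpec(mode="gaussian_bump", side="R", amplitude=8.0,
                                 center=(40.0, 20.0, 0.0), radius=10.0))
    R = Rotation.from_euler("x", 7, degrees=True).as_matrix()
    T = RigidTransform(R, np.array([4.0, 2.0, -6.0]))
    moved = as_mesh(T.apply(bumped.vertices), bumped.faces)
    res_r = al.robust_procrustes_icp(moved, mesh, n_samples=2000, seed=8, robust=True)
    res_u = al.robust_procrustes_icp(moved, mesh, n_samples=2000, seed=8, robust=False)
    err_r = res_r.transform.compose(T).angle_degrees()
    err_u = res_u.transform.compose(T).angle_degrees()
    assert err_r <= 0.5 * err_u


def test_reference_plane_recovers_ground_truth(mandible):
    mesh, _, truth = mandible
    plane, result = al.reference_symmetry_plane(mesh, n_samples=2000, seed=3)
    assert plane.angle_to(truth) < 0.1
    assert abs(plane.offset - truth.offset) < 0.1
    assert result.rms < 0.05


def test_reference_plane_rigid_equivariance(mandible):
    from mandisym.synthetic import perturb_rigid

    mesh, lms, truth = mandible
    for seed in range(6):
        m2, _, p2, _ = perturb_rigid(mesh, lms, truth, 15, 20, seed=seed)
        plane, _ = al.reference_symmetry_plane(m2, n_samples=2000, seed=3)
        assert plane.angle_to(p2) < 0.5
        anchor = p2.point_on_plane()
        assert abs(plane.signed_distance(anchor)) < 0.5


def test_reference_plane_on_sphere_passes_through_centroid():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    sphere.apply_translation([5.0, -3.0, 2.0])
    plane, result = al.reference_symmetry_plane(sphere, n_samples=1500, seed=5)
    centroid = sphere.vertices.mean(axis=0)
    assert abs(plane.signed_distance(centroid)) < 0.1
    assert result.rms < 0.05


def test_reference_plane_beats_tilted_planes(mandible, mandible_query):
    from mandisym.metrics import asymmetry_index

    mesh, _, _ = mandible
    plane, _ = al.reference_symmetry_plane(mesh, n_samples=2000, seed=3)
    cloud = al.sample_quasi_landmarks(mesh, 4000, seed=12)
    ai_ref = asymmetry_index(mesh, plane, query=mandible_query, cloud=cloud).ai
    for axis in ([0, 1, 0], [0, 0, 1]):
        R = Rotation.from_rotvec(np.radians(5) * np.asarray(axis, float)).as_matrix()
        tilted = Plane(R @ plane.normal, plane.offset)
        ai_tilt = asymmetry_index(mesh, tilted, query=mandible_query, cloud=cloud).ai
        assert ai_ref < ai_tilt
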