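import numpy as np
import pytest
from scipy import stats as sps

from mandisym import metrics as mt
from mandisym.alignment import sample_quasi_landmarks
from mandisym.plane import Plane
from mandisym.synthetic import AsymmetrySpec, generate_mandible, inject_asymmetry, perturb_rigid


def test_rms_definition():
    amap = mt.AsymmetryMap(distances=np.array([3.0, 4.0]), plane=Plane([1, 0, 0], 0), seed=0)
    assert amap.ai == pytest.approx(np.sqrt(12.5))
    assert amap.ai_mean == pytest.approx(3.5)


def test_symmetric_mesh_has_tiny_ai(mandible, mandible_query):
    mesh, _, truth = mandible
    amap = mt.asymmetry_index(mesh, truth, n=17_415, seed=1, query=mandible_query)
    assert amap.n == 17_415
    assert amap.ai < 0.05


def test_ai_invariant_under_common_rigid_motion(mandible):
    mesh, lms, truth = mandible
    bumped, lms2 = inject_asymmetry(mesh, lms, AsymmetrySpec(amplitude=2.0, seed=4))
    base = mt.asymmetry_index(bumped, truth, n=3000, seed=2).ai
    for seed in range(3):
        m2, _, p2, _ = perturb_rigid(bumped, lms2, truth, 15, 20, seed=seed)
        moved = mt.asymmetry_index(m2, p2, n=3000, seed=2).ai
        assert moved == pytest.approx(base, abs=1e-6)


def test_ai_sampling_stability(mandible):
    # AI at the working sample count is within 2% of a 4x denser sampling;
    # unilateral scaling spreads the deviation field over the whole side, the
    # regime the RMS summary is designed for
    mesh, lms, truth = mandible
    scaled, _ = inject_asymmetry(
        mesh, lms, AsymmetrySpec(mode="unilateral_scale", amplitude=0.03, seed=4))
    a1 = mt.asymmetry_index(scaled, truth, n=17_415, seed=5).ai
    a2 = mt.asymmetry_index(scaled, truth, n=70_000, seed=6).ai
    assert abs(a1 - a2) / a2 < 0.02


def test_colormap_normalisation():
    d = np.array([0.0, 2.0, 4.0, 6.0])
    out = mt.asymmetry_colormap_values(d, vmax=4.0)
    assert np.allclose(out, [0.0, 0.5, 1.0, 1.0])
    with pytest.raises(ValueError):
        mt.asymmetry_colormap_values(d, vmax=0.0)


def test_similarity_symmetric_mesh(mandible):
    mesh, _, truth = mandible
    si = mt.similarity_index(mesh, truth, pitch=0.5)
    assert si > 0.98


def test_similarity_plane_missing_mesh(mandible):
    mesh, _, _ = mandible
    with pytest.warns(UserWarning):
        si = mt.similarity_index(mesh, Plane([1, 0, 0], 500.0), pitch=1.0)
    assert si == 0.0


def test_similarity_half_overlapping_boxes():
    # mesh = two cubes mirror-placed across x=0 but offset in y so the
    # mirrored B overlaps A in exactly half its volume
    import trimesh

    a = trimesh.creation.box(extents=(10, 10, 10))
    a.apply_translation([-6, 0, 0])
    b = trimesh.creation.box(extents=(10, 10, 10))
    b.apply_translation([6, 5, 0])
    mesh = trimesh.util.concatenate([a, b])
    pitch = 0.25
    si = mt.similarity_index(mesh, Plane([1, 0, 0], 0.0), pitch=pitch)
    assert si == pytest.approx(0.5, abs=0.02)


def test_volume_difference_conservation(mandible):
    mesh, _, truth = mandible
    from mandisym.meshcore import mesh_volume

    total = mesh_volume(mesh)
    va, vb, diff = mt.volume_difference(mesh, truth)
    assert va + vb == pytest.approx(total, rel=1e-6)
    assert diff < 0.005 * total
    # plane outside the mesh: everything on one side
    va2, vb2, diff2 = mt.volume_difference(mesh, Plane([0, 0, 1], 400.0))
    assert diff2 == pytest.approx(total, rel=1e-9)


def test_landmark_distance_difference_cases(mandible):
    mesh, lms, truth = mandible
    diffs, mean = mt.landmark_distance_difference(lms, truth)
    assert set(diffs) == {"F", "MF", "Go", "Cor", "Consup", "Conmed", "Conlat",
                          "Sig", "RP", "Jlat", "Jmed"}
    assert max(diffs.values()) < 1e-9
    assert mean < 1e-9

    tilted = Plane([1, 0.2, 0], 3.0)
    left, right = lms.pair("Go")
    d = abs(abs(tilted.signed_distance(left)) - abs(tilted.signed_distance(right)))
    diffs2, _ = mt.landmark_distance_difference(lms, tilted)
    assert diffs2["Go"] == pytest.approx(d)


def test_pair_through_midpoint_has_zero_difference(mandible):
    # any plane through a pair's midpoint: d_left = -d_right exactly
    from mandisym.landmarks import bilateral_midpoint
    from mandisym.plane import plane_from_points

    _, lms, _ = mandible
    mid_f = bilateral_midpoint(*lms.pair("F"))
    plane = plane_from_points(mid_f, lms.get("B"), lms.get("Gn"))
    diffs, _ = mt.landmark_distance_difference(lms, plane)
    assert diffs["F"] == pytest.approx(0.0, abs=1e-12)


def test_si_and_distance_invariance_under_rigid_motion(mandible):
    mesh, lms, truth = mandible
    bumped, lms2 = inject_asymmetry(mesh, lms, AsymmetrySpec(amplitude=1.5, seed=9))
    si0 = mt.similarity_index(bumped, truth, pitch=0.8)
    _, _, dv0 = mt.volume_difference(bumped, truth)
    _, mean0 = mt.landmark_distance_difference(lms2, truth)
    m2, l2, p2, _ = perturb_rigid(bumped, lms2, truth, 15, 20, seed=3)
    si1 = mt.similarity_index(m2, p2, pitch=0.8)
    _, _, dv1 = mt.volume_difference(m2, p2)
    _, mean1 = mt.landmark_distance_difference(l2, p2)
    assert si1 == pytest.approx(si0, abs=0.02)
    assert dv1 == pytest.approx(dv0, abs=0.002 * dv0 + 5.0)
    assert mean1 == pytest.approx(mean0, abs=1e-9)


def test_paired_t_matches_scipy():
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    mine = mt.paired_t_test(x, y)
    ref = sps.ttest_rel(x, y)
    assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
    assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)
    assert mine.df == 11


def test_paired_t_textbook_example():
    # differences (1,2,3,4): mean 2.5, sd ~1.2910, t ~3.873 on 3 df
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = mt.paired_t_test(x, np.zeros(4))
    assert res.t == pytest.approx(2.5 / (np.std(x, ddof=1) / 2.0))
    assert res.t == pytest.approx(3.8730, abs=1e-4)
    assert res.df == 3
    assert res.p == pytest.approx(2 * sps.t.sf(3.872983, df=3), abs=1e-6)


def test_paired_t_degenerate_cases():
    same = np.array([1.0, 2.0, 3.0])
    res = mt.paired_t_test(same, same)
    assert res.t == 0.0 and res.p == 1.0
    shifted = mt.paired_t_test(same + 2.0, same)
    assert shifted.degenerate
    assert shifted.p <= np.finfo(float).tiny
    assert shifted.stars == "**"
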