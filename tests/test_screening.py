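import numpy as np
import pytest

from mandisym import screening as sc
from mandisym.landmarks import LandmarkSet
from mandisym.plane import Plane
from mandisym.screening import MidsagittalScreen, PlaneScore
from mandisym.synthetic import add_landmark_noise, generate_subject


@pytest.fixture(scope="module")
def jittered(mandible):
    mesh, lms, truth = mandible
    return mesh, add_landmark_noise(lms, seed=21), truth


@pytest.fixture(scope="module")
def screened(jittered, mandible_query):
    mesh, noisy, _ = jittered
    return sc.screen_planes(mesh, noisy, n=2000, seed=13, query=mandible_query)


def test_screening_yields_35_finite_scores(screened):
    assert len(screened) == 35
    assert all(not s.degenerate and np.isfinite(s.ai) for s in screened)
    ais = [s.ai for s in screened]
    assert ais == sorted(ais)


def test_screening_deterministic(jittered, mandible_query, screened):
    mesh, noisy, _ = jittered
    again = sc.screen_planes(mesh, noisy, n=2000, seed=13, query=mandible_query)
    assert [s.label for s in again] == [s.label for s in screened]
    assert [s.ai for s in again] == [s.ai for s in screened]


def test_best_plane_near_truth_under_jitter(screened, jittered):
    _, _, truth = jittered
    best = sc.select_top_k(screened, 1)[0]
    assert best.plane.angle_to(truth) < 5.0


def test_select_top_k_and_ties(screened):
    top = sc.select_top_k(screened, 4)
    assert len(top) == 4
    assert top[0].ai <= top[1].ai <= top[2].ai <= top[3].ai
    assert sc.select_top_k(screened, 1)[0].ai == min(s.ai for s in screened)
    # tie broken lexicographically
    a = PlaneScore(("B", "F", "G"), Plane([1, 0, 0], 0), 1.0, 1.0, 0.1)
    b = PlaneScore(("B", "F", "Me"), Plane([1, 0, 0], 0), 1.0, 1.0, 0.1)
    assert sc.select_top_k([b, a], 1)[0].label == "B-F-G"
    with pytest.raises(ValueError):
        sc.select_top_k([a, b], 3)


def test_degenerate_triplets_ranked_last(mandible):
    mesh, lms, _ = mandible
    # collapse three central landmarks onto one line so some triplets degenerate
    moved = LandmarkSet()
    for (name, side), p in lms.items():
        if name in ("Pog", "Gn", "Me"):
            p = np.array([0.0, 40.0, -10.0]) + {"Pog": 0, "Gn": 1, "Me": 2}[name] * np.array([0.0, 0.0, 5.0])
        moved.add(name, p, side=side)
    scores = sc.screen_planes(mesh, moved, n=500, seed=1)
    assert len(scores) == 35
    degenerate = [s for s in scores if s.degenerate]
    assert len(degenerate) == 1  # Gn-Me-Pog is exactly collinear
    assert scores[-1].degenerate
    assert degenerate[0].ai is None


def test_cohort_summary_quantiles():
    def fake(label_ais):
        return [PlaneScore(tuple(lab.split("-")), Plane([1, 0, 0], 0), ai, ai, 0.2)
                for lab, ai in label_ais]

    subjects = [fake([("B-F-G", ai)]) for ai in (1.0, 2.0, 3.0, 4.0, 5.0)]
    frame = sc.cohort_summary(subjects)
    row = frame.iloc[0]
    assert row["median"] == 3.0
    assert row["q25"] == 2.0 and row["q75"] == 4.0
    assert row["min"] == 1.0 and row["max"] == 5.0

    single = sc.cohort_summary([fake([("B-F-G", 2.5)])])
    assert single.iloc[0]["median"] == 2.5
    assert single.iloc[0]["q75"] - single.iloc[0]["q25"] == 0.0


def test_cohort_summary_orders_quantiles(screened, jittered, mandible_query):
    mesh, noisy, _ = jittered
    other = sc.screen_planes(mesh, add_landmark_noise(noisy, seed=5),
                             n=2000, seed=13, query=mandible_query)
    frame = sc.cohort_summary([screened, other])
    assert len(frame) == 35
    assert (frame["q25"] <= frame["median"]).all()
    assert (frame["median"] <= frame["q75"]).all()
    assert (frame["min"] <= frame["q25"]).all()
    assert (frame["q75"] <= frame["max"]).all()


def test_candidate_equal_to_reference_gives_zero_differences(mandible):
    mesh, lms, truth = mandible
    evals = sc.evaluate_candidates(mesh, lms, {"self": truth}, truth, pitch=1.0)
    ref, cand = evals["reference"], evals["self"]
    assert cand.mean_distance_diff == pytest.approx(ref.mean_distance_diff)
    assert cand.volume_diff == pytest.approx(ref.volume_diff)
    assert cand.similarity == pytest.approx(ref.similarity)


def test_cohort_evaluation_tables_shape(mandible):
    mesh, lms, truth = mandible
    evals = []
    for seed in range(3):
        noisy = add_landmark_noise(lms, seed=seed)
        evals.append(sc.evaluate_candidates(mesh, noisy, {"B-F-Gn": truth}, truth,
                                            pitch=1.5))
    dist, vol = sc.cohort_evaluation_tables(evals)
    # one row per bilateral pair plus the mean row
    assert list(dist["landmark"])[-1] == "Mean"
    assert len(dist) == 12
    assert "B-F-Gn_p" in dist.columns and "B-F-Gn_p_holm" in dist.columns
    assert list(vol["plane"]) == ["reference", "B-F-Gn"]
    assert "similarity_p" in vol.columns


def test_model_results_surface(mandible):
    mesh, lms, _ = mandible
    model = MidsagittalScreen(mesh, lms, n_samples=1500, top_k=2, seed=3)
    res = model.fit(compute_reference=False, evaluate=False)
    assert res.reference_plane is None
    assert len(res.scores) == 35 and len(res.top) == 2
    assert res.best.ai <= res.top[1].ai
    frame = res.scores_frame
    assert list(frame.columns[:2]) == ["plane", "AI_rms"]
    text = res.summary()
    assert "Candidate planes" in text and "35" in text

    override = Plane([1, 0, 0], 0.0)
    res2 = model.fit(reference_plane=override)
    assert res2.reference_plane is override
    assert "reference" in res2.evaluations
    assert set(res2.evaluations) == {"reference"} | {s.label for s in res2.top}
    assert "Adjudication" in res2.summary()


def test_ranking_invariant_under_rigid_motion(mandible):
    from mandisym.synthetic import perturb_rigid

    mesh, lms, truth = mandible
    noisy = add_landmark_noise(lms, seed=17)
    base = sc.screen_planes(mesh, noisy, n=1500, seed=2)
    base_labels = [s.label for s in base]
    for seed in (1, 2):
        m2, l2, _, _ = perturb_rigid(mesh, noisy, truth, 15, 20, seed=seed)
        moved = sc.screen_planes(m2, l2, n=1500, seed=2)
        assert [s.label for s in moved] == base_labels
        assert np.allclose([s.ai for s in moved], [s.ai for s in base], atol=1e-6)
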