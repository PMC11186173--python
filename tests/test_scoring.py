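"""Class scores, D-line fitting, final scores, and the training pipeline."""

import numpy as np
import pandas as pd
import pytest

from igensig import (
    FeatureMatrix,
    ModelArtifact,
    SimilarityMatrix,
    class_score,
    final_score,
    fit_dline,
    ochiai_matrix,
    score_cohort,
    train,
)
from igensig.scoring import DLine

from conftest import toy_labels


def weight_table(mapping):
    rows = {
        f: {
            "omega": w,
            "klass": "sensitive" if w > 0 else "resistant",
            "retained": abs(w) >= 0.13,
        }
        for f, w in mapping.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature_id")


class TestClassScore:
    def test_orthogonal_reference_gives_mean_weight(self):
        sim = SimilarityMatrix(["f1", "f2"], np.eye(2))
        w = weight_table({"f1": 0.3, "f2": 0.4})
        assert class_score(["f1", "f2"], w, sim, "sensitive") == pytest.approx(0.35, abs=1e-15)

    def test_redundant_trio_hand_worked(self):
        # K12 = 1, K13 = K23 = 0; |omega| = (0.3, 0.3, 0.4)
        # eps = (2, 2, 1); sum EW = .15 + .15 + .4 = 0.70
        # EFN = sum of reciprocals = .5 + .5 + 1 = 2.0; score = 0.35
        v = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        sim = SimilarityMatrix(["f1", "f2", "f3"], v)
        w = weight_table({"f1": 0.3, "f2": 0.3, "f3": 0.4})
        score = class_score(["f1", "f2", "f3"], w, sim, "sensitive")
        assert score == pytest.approx(0.7 / 2.0, abs=1e-12)

    def test_no_class_features_scores_zero(self):
        sim = SimilarityMatrix(["f1"], np.eye(1))
        w = weight_table({"f1": 0.3})
        assert class_score(["f1"], w, sim, "resistant") == 0.0
        assert class_score([], w, sim, "sensitive") == 0.0

    def test_resistant_class_uses_weight_magnitude(self):
        sim = SimilarityMatrix(["f1", "f2"], np.eye(2))
        w = weight_table({"f1": -0.3, "f2": -0.5})
        assert class_score(["f1", "f2"], w, sim, "resistant") == pytest.approx(0.4)

    def test_feature_order_invariance(self, rng):
        ids = [f"f{i}" for i in range(8)]
        raw = rng.random((8, 8)) * 0.5
        v = (raw + raw.T) / 2
        np.fill_diagonal(v, 1.0)
        sim = SimilarityMatrix(ids, v)
        w = weight_table({f: 0.2 + 0.05 * i for i, f in enumerate(ids)})
        perm = list(rng.permutation(ids))
        assert class_score(ids, w, sim, "sensitive") == pytest.approx(
            class_score(perm, w, sim, "sensitive"), abs=1e-12
        )


class TestDLine:
    def test_separable_cloud_smallest_separating_angle(self):
        r = np.array([0.1, 0.2, 0.9, 0.8])
        s = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        d = fit_dline(r, s, y)
        assert d.youden_j == pytest.approx(1.0)
        # J = 1 on the plateau atan(0.25) < theta < atan(4); the grid's
        # smallest angle inside it is 14.5 degrees
        assert d.theta_deg == pytest.approx(14.5)
        assert d.slope == pytest.approx(np.tan(np.deg2rad(14.5)))

    def test_flipped_labels_negate_youden(self):
        r = np.array([0.1, 0.2, 0.9, 0.8])
        s = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        d_flip = fit_dline(r, s, 1 - y)
        assert d_flip.youden_j < 1.0
        # at the angle that separated perfectly before, J is now -1
        thetas = np.arange(0.5, 90, 0.5)
        slopes = np.tan(np.deg2rad(thetas))
        pred = s[None, :] > slopes[:, None] * r[None, :]
        j_flip = pred[:, (1 - y) == 1].mean(axis=1) - pred[:, (1 - y) == 0].mean(axis=1)
        assert j_flip[thetas.tolist().index(14.5)] == pytest.approx(-1.0)
        assert d_flip.youden_j == pytest.approx(j_flip.max())

    def test_two_point_perfect_split(self):
        d = fit_dline(np.array([0.2, 0.8]), np.array([0.8, 0.2]), np.array([1, 0]))
        assert d.youden_j == pytest.approx(1.0)

    def test_degenerate_identical_scores_defaults_to_unit_slope(self):
        with pytest.warns(UserWarning, match="degenerate"):
            d = fit_dline(np.ones(4), np.ones(4), np.array([1, 1, 0, 0]))
        assert d.slope == 1.0

    def test_single_class_is_hard_error(self):
        with pytest.raises(ValueError, match="both"):
            fit_dline(np.array([0.1, 0.2]), np.array([0.3, 0.4]), np.array([1, 1]))


class TestFinalScore:
    def test_point_on_line_scores_zero(self):
        d = DLine(slope=2.0, theta_deg=63.4, youden_j=0.5, angle_step_deg=0.5)
        assert final_score(0.3, 0.6, d) == pytest.approx(0.0, abs=1e-15)

    def test_unit_slope_geometry(self):
        d = DLine(slope=1.0, theta_deg=45.0, youden_j=0.5, angle_step_deg=0.5)
        dist = 0.37
        assert final_score(0.0, dist * np.sqrt(2), d) == pytest.approx(dist)
        assert final_score(dist * np.sqrt(2), 0.0, d) == pytest.approx(-dist)


class TestTrainingPipeline:
    def four_patient_cohort(self):
        inc = np.array([[1, 0], [1, 0], [1, 1], [0, 1]], dtype=np.uint8)
        fm = FeatureMatrix(["P0", "P1", "P2", "P3"], ["fa", "fb"], inc)
        labels = toy_labels([1, 1, 0, 0], fm.patient_ids)
        reference = FeatureMatrix(
            [f"R{i}" for i in range(6)],
            ["fa", "fb"],
            np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1], [0, 0]], dtype=np.uint8),
        )
        return fm, labels, reference

    def test_tiny_cohort_end_to_end_smoke(self):
        fm, labels, reference = self.four_patient_cohort()
        artifact = train(fm, labels, reference)
        scores = score_cohort(artifact, fm)
        assert len(scores) == 4
        assert np.isfinite(scores["final_score"]).all()
        assert set(scores["predicted"]) <= {0, 1}

    def test_loo_scoring_reproduces_training_scores(self, small_cohort):
        fm, labels, reference, _ = small_cohort
        artifact = train(fm, labels, reference)
        rescored = score_cohort(artifact, fm, loo=True)
        merged = artifact.training_scores.merge(rescored, on="patient_id", suffixes=("_t", "_r"))
        for col in ("sensitive_score", "resistant_score", "final_score"):
            assert np.allclose(merged[f"{col}_t"], merged[f"{col}_r"], atol=1e-12)

    def test_loo_refused_for_external_patient(self, small_cohort):
        fm, labels, reference, _ = small_cohort
        artifact = train(fm, labels, reference)
        external = FeatureMatrix(["NEW"], fm.feature_ids, fm.incidence[:1])
        with pytest.raises(KeyError, match="not a training patient"):
            score_cohort(artifact, external, loo=True)

    def test_empty_patient_scores_zero_and_non_sensitive(self, small_cohort):
        fm, labels, reference, _ = small_cohort
        artifact = train(fm, labels, reference)
        empty = FeatureMatrix(
            ["EMPTY"], fm.feature_ids, np.zeros((1, fm.n_features), dtype=np.uint8)
        )
        row = score_cohort(artifact, empty).iloc[0]
        assert row["sensitive_score"] == 0 and row["resistant_score"] == 0
        assert row["final_score"] == 0 and row["predicted"] == 0

    def test_external_cohort_with_missing_features_still_scores(self, small_cohort):
        fm, labels, reference, _ = small_cohort
        artifact = train(fm, labels, reference)
        keep = fm.feature_ids[: int(0.7 * fm.n_features)]  # drop 30% of features
        external = fm.subset_features(keep)
        scores = score_cohort(artifact, external)
        assert np.isfinite(scores["final_score"]).all()
        assert (scores[["sensitive_score", "resistant_score"]] > 0).any().any()

    def test_no_retained_features_is_hard_error(self):
        from igensig import ModelConfig

        fm, labels, reference = self.four_patient_cohort()
        with pytest.raises(ValueError, match="no features retained"):
            train(fm, labels, reference, config=ModelConfig(cutoff=1.01))

    def test_artifact_round_trip_preserves_scoring(self, tmp_path, small_cohort):
        fm, labels, reference, _ = small_cohort
        artifact = train(fm, labels, reference)
        artifact.save(tmp_path / "model")
        back = ModelArtifact.load(tmp_path / "model")
        a = score_cohort(artifact, fm)
        b = score_cohort(back, fm)
        # weights serialize at 6 decimals, bounding the score perturbation
        assert np.allclose(a["final_score"], b["final_score"], atol=1e-5)
        assert back.dline == artifact.dline


def test_duplication_invariance_of_class_scores():
    """k-fold exact duplication (labeled + reference) leaves scores unchanged.

    The base reference gives the features transitive carrier structure
    (two exact-duplicate pairs plus disjoint features), under which the
    cluster gating scales proportionally and the invariance is exact.
    """
    ids = [f"f{i}" for i in range(6)]
    # carriers: f0 == f1 (a duplicate pair), f2 == f3, f4 and f5 disjoint
    n_ref = 12
    ref_inc = np.zeros((n_ref, 6), dtype=np.uint8)
    ref_inc[0:4, 0] = ref_inc[0:4, 1] = 1
    ref_inc[4:7, 2] = ref_inc[4:7, 3] = 1
    ref_inc[7:9, 4] = 1
    ref_inc[9:12, 5] = 1
    weights = weight_table(dict(zip(ids, [0.3, 0.22, 0.41, -0.3, -0.18, 0.27])))
    patient = ["f0", "f1", "f2", "f3", "f4", "f5"]
    base_sim = ochiai_matrix(FeatureMatrix([f"R{i}" for i in range(n_ref)], ids, ref_inc))
    base = {
        k: class_score(patient, weights, base_sim, k) for k in ("sensitive", "resistant")
    }
    assert base["sensitive"] > 0 and base["resistant"] > 0
    for k in (2, 3, 5):
        dup_ids = [f"{f}#c{c}" for f in ids for c in range(k)]
        dup_inc = np.repeat(ref_inc, k, axis=1)
        dup_sim = ochiai_matrix(FeatureMatrix([f"R{i}" for i in range(n_ref)], dup_ids, dup_inc))
        dup_w = weight_table(
            {f"{f}#c{c}": weights.at[f, "omega"] for f in ids for c in range(k)}
        )
        dup_patient = [f"{f}#c{c}" for f in patient for c in range(k)]
        for klass in ("sensitive", "resistant"):
            dup = class_score(dup_patient, dup_w, dup_sim, klass)
            assert dup == pytest.approx(base[klass], abs=1e-9)
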