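"""Training-pixel sampling, kernel machinery, SVM and LOOCV protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirhsi.classify import (
    TrainingSet,
    median_heuristic_sigma2,
    predict_map,
    rbf_kernel,
    run_loocv,
    sample_training_pixels,
    train_classifier,
)
from nirhsi.containers import PRED_NOT_EVALUATED, UsageError, ValidityMask

from oracles import pairwise_sq_distances, qp_svm_decision


def _toy_training(rng, n=100, sep=6.0, dim=4):
    X = np.vstack(
        [rng.normal(0.0, 1.0, (n, dim)), rng.normal(sep / np.sqrt(dim), 1.0, (n, dim))]
    )
    y = np.array([0] * n + [1] * n)
    prov = [("toy", (0, i)) for i in range(2 * n)]
    return TrainingSet(spectra=X, labels=y, provenance=prov)


class TestMedianHeuristic:
    def test_two_points(self):
        assert median_heuristic_sigma2(np.array([[0.0], [1.0]])) == 1.0

    def test_three_points_enumerated(self):
        # pairwise squared distances {1, 9, 4} -> median 4
        assert median_heuristic_sigma2(np.array([[0.0], [1.0], [3.0]])) == 4.0

    def test_matches_pair_enumeration(self, rng):
        X = rng.random((15, 6))
        assert median_heuristic_sigma2(X) == pytest.approx(
            float(np.median(pairwise_sq_distances(X))), rel=1e-12
        )

    def test_identical_rows_rejected(self):
        with pytest.raises(UsageError):
            median_heuristic_sigma2(np.ones((4, 3)))


class TestRBFKernel:
    def test_identity_and_scale(self):
        x = np.array([1.0, 2.0])
        assert rbf_kernel(x, x, 2.0) == 1.0
        # squared distance equal to sigma2 -> exp(-1)
        assert rbf_kernel(np.zeros(1), np.array([2.0]), 4.0) == pytest.approx(np.exp(-1))

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 8))
        k = rbf_kernel(a, b, 3.0)
        assert k == rbf_kernel(b, a, 3.0)
        assert 0.0 < k <= 1.0

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(UsageError):
            rbf_kernel(np.zeros(2), np.ones(2), 0.0)


class TestSampling:
    def test_balanced_deterministic_no_duplicates(self, preprocessed):
        ts1 = sample_training_pixels(
            preprocessed.snv, preprocessed.annotation, preprocessed.mask,
            n_per_class=50, seed=3, specimen_id="unit",
        )
        ts2 = sample_training_pixels(
            preprocessed.snv, preprocessed.annotation, preprocessed.mask,
            n_per_class=50, seed=3, specimen_id="unit",
        )
        assert len(ts1) == 100
        assert (ts1.labels == 0).sum() == (ts1.labels == 1).sum() == 50
        assert len(set(ts1.provenance)) == 100
        np.testing.assert_array_equal(ts1.spectra, ts2.spectra)
        assert ts1.provenance == ts2.provenance

    def test_sampled_pixels_are_valid_and_correctly_labelled(self, preprocessed):
        ts = sample_training_pixels(
            preprocessed.snv, preprocessed.annotation, preprocessed.mask,
            n_per_class=30, seed=0, specimen_id="unit",
        )
        for (sid, (r, c)), label in zip(ts.provenance, ts.labels):
            assert preprocessed.mask.valid[r, c]
            is_tumor = preprocessed.annotation.tumor_mask[r, c]
            assert bool(label) == bool(is_tumor)

    def test_insufficient_pixels_error_names_class(self, preprocessed):
        n_tumor = int(np.sum(preprocessed.mask.valid & preprocessed.annotation.tumor_mask))
        n_normal = int(
            np.sum(preprocessed.mask.valid & (preprocessed.annotation.labels == 1))
        )
        smaller = "tumor" if n_tumor < n_normal else "normal"
        with pytest.raises(UsageError, match=smaller):
            sample_training_pixels(
                preprocessed.snv, preprocessed.annotation, preprocessed.mask,
                n_per_class=min(n_tumor, n_normal) + 1, seed=0, specimen_id="unit",
            )


class TestTrainPredict:
    def test_separable_clusters_reach_full_training_accuracy(self):
        ts = _toy_training(np.random.default_rng(0), sep=6.0)
        model = train_classifier(ts)
        assert np.all(model.predict(ts.spectra) == ts.labels)

    def test_label_flip_symmetry(self, rng):
        ts = _toy_training(rng, sep=2.0)
        flipped = TrainingSet(
            spectra=ts.spectra, labels=1 - ts.labels, provenance=ts.provenance
        )
        pred = train_classifier(ts).predict(ts.spectra)
        pred_flipped = train_classifier(flipped).predict(ts.spectra)
        assert np.mean(pred == 1 - pred_flipped) > 0.99

    def test_single_class_rejected(self, rng):
        X = rng.random((10, 3))
        ts = TrainingSet(spectra=X, labels=np.zeros(10, int),
                         provenance=[("a", (0, i)) for i in range(10)])
        with pytest.raises(UsageError):
            train_classifier(ts)

    @pytest.mark.parametrize("trial", range(4))
    def test_decision_values_match_dual_qp_oracle(self, trial):
        """On tiny training sets the fitted machine must agree with a
        brute-force solution of the dual quadratic program to 1e-3."""
        rng = np.random.default_rng(100 + trial)
        n = 5 if trial < 2 else 6
        sep = 2.0 if trial % 2 else 3.0
        X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
        y = np.array([0] * n + [1] * n)
        ts = TrainingSet(spectra=X, labels=y,
                         provenance=[("t", (0, i)) for i in range(2 * n)])
        model = train_classifier(ts, C=1.0)
        oracle = qp_svm_decision(X, y, 1.0, model.sigma2, X)
        np.testing.assert_allclose(model.decision_values(X), oracle, atol=1e-3)

    def test_predict_map_structure(self, preprocessed, rng):
        ts = sample_training_pixels(
            preprocessed.snv, preprocessed.annotation, preprocessed.mask,
            n_per_class=60, seed=1, specimen_id="unit",
        )
        model = train_classifier(ts)
        pm = predict_map(model, preprocessed.snv, preprocessed.mask, "unit")
        assert np.all((pm.classes == PRED_NOT_EVALUATED) == ~preprocessed.mask.valid)
        pm2 = predict_map(model, preprocessed.snv, preprocessed.mask, "unit")
        np.testing.assert_array_equal(pm.classes, pm2.classes)

    def test_all_invalid_mask_yields_all_not_evaluated(self, preprocessed):
        ts = sample_training_pixels(
            preprocessed.snv, preprocessed.annotation, preprocessed.mask,
            n_per_class=30, seed=1, specimen_id="unit",
        )
        model = train_classifier(ts)
        shape = preprocessed.mask.shape
        empty = ValidityMask(
            valid=np.zeros(shape, bool), exclusion_reason=np.full(shape, 5, np.uint8)
        )
        pm = predict_map(model, preprocessed.snv, empty)
        assert np.all(pm.classes == PRED_NOT_EVALUATED)

    def test_band_mismatch_rejected(self, preprocessed, rng):
        ts = _toy_training(rng, dim=4)
        model = train_classifier(ts)
        with pytest.raises(UsageError):
            predict_map(model, preprocessed.snv, preprocessed.mask)


class TestLOOCV:
    def _mini_cohort(self):
        from nirhsi.pipeline import preprocess_cohort
        from nirhsi.preprocess import PreprocessParams
        from nirhsi.synth import SpecimenConfig, simulate_cohort

        cfg = SpecimenConfig(shape=(64, 88), semi_axes=(18.0, 26.0), core_fraction=1.0)
        specimens = simulate_cohort(3, template=cfg, seed=5, unexposed_fraction=0.0)
        return preprocess_cohort(specimens, PreprocessParams())

    def test_fold_isolation_and_size(self):
        cohort = self._mini_cohort()
        folds = run_loocv(cohort, n_per_class=40, seed=2)
        for fold in folds:
            assert len(fold.training) == 2 * 2 * 40  # 2 specimens x 2 classes x 40
            held_out = {sid for sid, _ in fold.training.provenance}
            assert fold.specimen_id not in held_out

    def test_order_invariance_of_maps(self):
        cohort = self._mini_cohort()
        folds_fwd = run_loocv(cohort, n_per_class=40, seed=2)
        folds_rev = run_loocv(cohort[::-1], n_per_class=40, seed=2)
        rev = {f.specimen_id: f for f in folds_rev}
        for f in folds_fwd:
            np.testing.assert_array_equal(
                f.prediction.classes, rev[f.specimen_id].prediction.classes
            )

    def test_too_few_specimens_rejected(self):
        cohort = self._mini_cohort()[:1]
        with pytest.raises(UsageError):
            run_loocv(cohort)
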