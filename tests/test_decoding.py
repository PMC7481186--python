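import numpy as np
import pytest

import pareidolia as p
from pareidolia.core import ValidationError
from pareidolia.decoding import (
    FoldPlan,
    Fold,
    fit_predict_lda,
    fit_predict_svm,
    make_folds,
    searchlight_decode,
    sphere_offsets,
)
from pareidolia.preprocess import pca_reduce


class TestLDA:
    def test_test_point_at_centroid_classified_correctly(self, rng):
        X0 = rng.standard_normal((20, 3)) + np.array([10, 0, 0])
        X1 = rng.standard_normal((20, 3)) - np.array([10, 0, 0])
        X = np.vstack([X0, X1])
        y = np.array(["a"] * 20 + ["b"] * 20)
        pred = fit_predict_lda(X, y, np.array([[10.0, 0, 0], [-10.0, 0, 0]]))
        assert list(pred) == ["a", "b"]

    def test_full_shrinkage_equals_nearest_centroid(self, rng):
        X = rng.standard_normal((30, 5))
        y = np.array(["a", "b"] * 15)
        test = rng.standard_normal((40, 5))
        pred = fit_predict_lda(X, y, test, shrinkage=1.0)
        mu_a, mu_b = X[y == "a"].mean(0), X[y == "b"].mean(0)
        d_a = np.linalg.norm(test - mu_a, axis=1)
        d_b = np.linalg.norm(test - mu_b, axis=1)
        oracle = np.where(d_b < d_a, "b", "a")
        assert list(pred) == list(oracle)

    def test_weight_vector_matches_closed_form(self, rng):
        """LDA scores agree with the direct Sigma^-1 (mu1 - mu0) solution."""
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(cov)
        X0 = rng.standard_normal((200, 2)) @ L.T
        X1 = rng.standard_normal((200, 2)) @ L.T + np.array([1.5, -0.5])
        X = np.vstack([X0, X1])
        y = np.array(["a"] * 200 + ["b"] * 200)
        test = rng.standard_normal((50, 2)) * 2
        pred = fit_predict_lda(X, y, test, shrinkage=0.0)
        mu0, mu1 = X0.mean(0), X1.mean(0)
        R0, R1 = X0 - mu0, X1 - mu1
        S = (R0.T @ R0 + R1.T @ R1) / (400 - 2)
        w = np.linalg.solve(S, mu1 - mu0)
        scores = test @ w - w @ (mu0 + mu1) / 2
        oracle = np.where(scores > 0, "b", "a")
        assert list(pred) == list(oracle)

    def test_singular_covariance_advises_shrinkage(self):
        X = np.zeros((6, 4))
        X[:3, 0] = 1.0
        y = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValidationError, match="shrinkage"):
            fit_predict_lda(X, y, X, shrinkage=0.0)


class TestSVM:
    def test_separable_data_zero_training_error(self, rng):
        X = np.vstack([rng.standard_normal((10, 2)) + 5,
                       rng.standard_normal((10, 2)) - 5])
        y = np.array(["a"] * 10 + ["b"] * 10)
        assert list(fit_predict_svm(X, y, X)) == list(y)

    def test_duplicate_training_rows_do_not_change_predictions(self, rng):
        X = np.vstack([rng.standard_normal((8, 3)) + 2,
                       rng.standard_normal((8, 3)) - 2])
        y = np.array(["a"] * 8 + ["b"] * 8)
        test = rng.standard_normal((20, 3))
        base = fit_predict_svm(X, y, test)
        dup = fit_predict_svm(np.vstack([X, X]), np.concatenate([y, y]), test)
        assert list(base) == list(dup)

    def test_lda_svm_agree_on_high_snr_synthetic(self, small_meg, stimuli8):
        datasets, cfg = small_meg
        stim = p.make_stimulus_set(cfg.n_exemplars_per_category)
        proc = [pca_reduce(datasets[0])]
        t = np.array([160.0])
        kwargs = dict(scheme="paired_exemplar", times_ms=t)
        acc_lda = p.decode_timecourse(proc, stim, ("human_face", "matched_object"),
                                      classifier="lda", **kwargs).accuracy_percent
        acc_svm = p.decode_timecourse(proc, stim, ("human_face", "matched_object"),
                                      classifier="svm", **kwargs).accuracy_percent
        assert abs(acc_lda[0, 0] - acc_svm[0, 0]) <= 2.0


class TestFoldPlans:
    def test_paired_scheme_32_exemplars(self):
        stim = p.make_stimulus_set(32)
        plan = make_folds(stim, ("illusory_face", "matched_object"), "paired_exemplar")
        assert len(plan) == 32
        for fold in plan.folds:
            assert len(fold.train) == 62
            assert len(fold.test) == 2

    def test_paired_scheme_holds_out_yoked_partners_together(self):
        stim = p.make_stimulus_set(4)
        plan = make_folds(stim, ("illusory_face", "matched_object"), "paired_exemplar")
        for fold in plan.folds:
            (a, _), (b, _) = fold.test
            assert stim.yoke_of(a) == b

    def test_exhaustive_scheme_fold_count(self):
        stim = p.make_stimulus_set(32)
        plan = make_folds(stim, ("human_face", "matched_object"), "exhaustive_exemplar")
        assert len(plan) == 32 * 32

    def test_run_by_exemplar_small_case(self, tiny_stimuli):
        plan = make_folds(
            tiny_stimuli, ("illusory_face", "matched_object"),
            "run_by_exemplar", runs=[0, 1, 2],
        )
        assert len(plan) == 6
        for fold in plan.folds:
            train_stims = {s for s, _ in fold.train}
            test_stims = {s for s, _ in fold.test}
            assert not train_stims & test_stims
            (_, r1), (_, r2) = fold.test
            assert r1 == r2
            assert all(rr != r1 for _, rr in fold.train)

    def test_run_scheme_without_runs_rejected(self, tiny_stimuli):
        with pytest.raises(ValidationError, match="runs"):
            make_folds(tiny_stimuli, ("illusory_face", "matched_object"),
                       "run_by_exemplar")

    def test_overlapping_fold_rejected_structurally(self):
        with pytest.raises(ValidationError, match="train and test"):
            FoldPlan(
                [Fold((("a", None), ("b", None)), (("a", None),))],
                "custom", ("x", "y"),
            )


class TestTimecourseDecoding:
    def test_noise_free_separable_signal_decodes_perfectly(self):
        from pareidolia.synth import build_trajectory

        traj = build_trajectory(
            [(100.0, np.array([[0, 2.0, 2.0], [2.0, 0, 2.0], [2.0, 2.0, 0]]), 0.0)],
            onset_ms=50.0,
        )
        cfg = p.SyntheticMEGConfig(
            n_subjects=1, n_channels=16, n_exemplars_per_category=3,
            n_runs=1, repeats_per_run=2, sample_rate_hz=100.0,
            epoch_ms=(0.0, 190.0), sensor_noise_sd=0.0, evoked_dim=0, seed=5,
        )
        ds = p.generate_meg_dataset(cfg, traj)
        res = p.decode_timecourse(
            ds, p.make_stimulus_set(3), ("illusory_face", "matched_object"),
            scheme="paired_exemplar", times_ms=np.array([100.0, 150.0]),
        )
        assert np.all(res.accuracy_percent == 100.0)

    def test_schemes_agree_on_high_snr_data(self, small_meg):
        datasets, cfg = small_meg
        stim = p.make_stimulus_set(cfg.n_exemplars_per_category)
        proc = [pca_reduce(e) for e in datasets[:2]]
        t = np.array([160.0])
        a = p.decode_timecourse(proc, stim, ("human_face", "matched_object"),
                                scheme="paired_exemplar", times_ms=t)
        b = p.decode_timecourse(proc, stim, ("human_face", "matched_object"),
                                scheme="exhaustive_exemplar", times_ms=t)
        assert abs(a.accuracy_percent.mean() - b.accuracy_percent.mean()) <= 2.0


class TestROIDecoding:
    def test_single_informative_voxel_noise_free_is_perfect(self):
        profile = p.ROIProfile(
            "toy", np.array([[0, 1.0, 1.0], [1.0, 0, 1.0], [1.0, 1.0, 0]]),
            exemplar_spread=0.0, voxel_range=(1, 1),
        )
        ds, stim = p.generate_fmri_dataset(
            n_subjects=1, n_runs=3, profiles=[profile],
            n_exemplars_per_category=2, run_noise_sd=0.0, seed=9,
        )
        res = p.decode_roi(ds, stim, ("illusory_face", "matched_object"))
        assert np.all(res.accuracy_percent == 100.0)


class TestSearchlight:
    def test_sphere_radius3_contains_123_voxels(self):
        assert sphere_offsets(3).shape[0] == 123

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValidationError, match="radius"):
            sphere_offsets(0)

    def _blob_volume(self, rng, n_ex=4, shape=(7, 7, 7)):
        stim = p.make_stimulus_set(n_ex)
        ids = sorted(stim.ids)
        vol = rng.standard_normal((len(ids),) + shape) * 0.1
        cats = np.array([stim.category_of(s) for s in ids])
        # informative blob near one corner
        signal = np.where(cats == "illusory_face", 2.0,
                          np.where(cats == "matched_object", -2.0, 0.0))
        for dx in range(2):
            for dy in range(2):
                vol[:, 1 + dx, 1 + dy, 1] += signal
        return vol, stim, ids

    def test_blob_signal_localized(self, rng):
        vol, stim, ids = self._blob_volume(rng)
        mask = np.ones(vol.shape[1:], dtype=bool)
        acc = searchlight_decode(
            vol, mask, stim, ("illusory_face", "matched_object"),
            radius_voxels=1, classifier="lda", stimulus_ids=ids, shrinkage=0.5,
        )
        best = np.unravel_index(np.nanargmax(acc), acc.shape)
        assert abs(best[0] - 1) <= 2 and abs(best[1] - 1) <= 2 and abs(best[2] - 1) <= 2
        far_corner = acc[5:, 5:, 5:]
        assert np.nanmax(acc) > np.nanmean(far_corner)

    def test_single_voxel_sphere_reduces_to_voxel_decoding(self, rng):
        vol, stim, ids = self._blob_volume(rng, shape=(3, 3, 3))
        mask = np.zeros(vol.shape[1:], dtype=bool)
        mask[1, 1, 1] = True  # lone in-mask voxel: sphere == that voxel
        acc = searchlight_decode(
            vol, mask, stim, ("illusory_face", "matched_object"),
            radius_voxels=3, classifier="lda", stimulus_ids=ids, shrinkage=0.5,
        )
        plan = make_folds(stim, ("illusory_face", "matched_object"), "paired_exemplar")
        cats = np.array([stim.category_of(s) for s in ids])
        X = vol[:, 1, 1, 1][:, None]
        correct = total = 0
        for fold in plan.folds:
            tr = np.isin(ids, [s for s, _ in fold.train]) & np.isin(
                cats, ["illusory_face", "matched_object"])
            te = np.isin(ids, [s for s, _ in fold.test])
            pred = fit_predict_lda(X[tr], cats[tr], X[te], shrinkage=0.5)
            correct += (pred == cats[te]).sum()
            total += te.sum()
        assert acc[1, 1, 1] == pytest.approx(100.0 * correct / total)
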