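import hashlib

import numpy as np
import pytest

import pareidolia as p
from pareidolia.core import ValidationError
from pareidolia.stats import ttest_paired
from pareidolia.synth import build_trajectory, default_trajectory


def _digest(arr):
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


class TestTrajectory:
    def test_null_trajectory_is_zero_everywhere(self):
        traj = build_trajectory([(100.0, np.zeros((3, 3)), 0.0)], onset_ms=0.0)
        for t in (-50.0, 0.0, 100.0, 500.0):
            assert np.all(traj.delta_at(t) == 0.0)

    def test_linear_interpolation_midpoint(self):
        d1 = np.zeros((3, 3))
        # collinear geometry: d01 = 2 with the third point midway
        d2 = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        traj = build_trajectory([(100.0, d1, 0.0), (200.0, d2, 0.0)], onset_ms=50.0)
        assert traj.delta_at(150.0)[0, 1] == pytest.approx(1.0)

    def test_default_illusory_matched_distance_collapses_by_260ms(self):
        traj = default_trajectory()
        d160 = traj.delta_at(160.0)[1, 2]
        d260 = traj.delta_at(260.0)[1, 2]
        assert d260 < d160

    def test_zero_before_onset(self):
        traj = default_trajectory()
        assert np.all(traj.delta_at(traj.onset_ms - 1.0) == 0.0)
        assert traj.sigma_at(-100.0) == 0.0

    def test_asymmetric_delta_rejected_naming_cell(self):
        d = np.zeros((3, 3))
        d[0, 1] = 1.0
        with pytest.raises(ValidationError, match=r"\(0,1\)"):
            build_trajectory([(100.0, d, 0.1)])

    def test_negative_delta_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = -0.5
        with pytest.raises(ValidationError, match="negative"):
            build_trajectory([(100.0, d, 0.1)])

    def test_triangle_violating_delta_rejected(self):
        d = np.array([[0, 5.0, 1.0], [5.0, 0, 1.0], [1.0, 1.0, 0]])
        with pytest.raises(ValidationError, match="embeddable"):
            build_trajectory([(100.0, d, 0.1)])


class TestMEGGenerator:
    def test_default_design_dimensions(self):
        """Full-scale config implies 2304 trials, 160 channels, 1101 samples."""
        cfg = p.SyntheticMEGConfig()
        assert cfg.n_trials == 2304
        assert cfg.n_channels == 160
        assert cfg.times_ms.size == 1101
        assert cfg.n_subjects == 22

    def test_small_dataset_shapes_and_metadata(self, small_meg):
        datasets, cfg = small_meg
        assert len(datasets) == cfg.n_subjects
        ep = datasets[0]
        assert ep.data.shape == (cfg.n_trials, cfg.n_channels, cfg.times_ms.size)
        counts = ep.trials.groupby("stimulus_id").size()
        assert (counts == cfg.n_runs * cfg.repeats_per_run).all()

    def test_identical_seeds_byte_identical(self):
        cfg = dict(
            n_subjects=2, n_channels=8, n_exemplars_per_category=2,
            n_runs=2, repeats_per_run=2, sample_rate_hz=100.0,
            epoch_ms=(-50.0, 145.0), seed=7,
        )
        a = p.generate_meg_dataset(p.SyntheticMEGConfig(**cfg))
        b = p.generate_meg_dataset(p.SyntheticMEGConfig(**cfg))
        assert _digest(a[0].data) == _digest(b[0].data)
        assert _digest(a[1].data) == _digest(b[1].data)
        assert a[0].trials.equals(b[0].trials)

    def test_noise_free_zero_spread_trials_identical_per_category(self):
        traj = build_trajectory(
            [(100.0, np.array([[0, 1.0, 1.0], [1.0, 0, 0], [1.0, 0, 0]]), 0.0)],
            onset_ms=50.0,
        )
        cfg = p.SyntheticMEGConfig(
            n_subjects=1, n_channels=8, n_exemplars_per_category=2,
            n_runs=1, repeats_per_run=2, sample_rate_hz=100.0,
            epoch_ms=(0.0, 190.0), sensor_noise_sd=0.0, evoked_dim=0, seed=3,
        )
        ep = p.generate_meg_dataset(cfg, traj)[0]
        cats = ep.trials["category"].to_numpy()
        for cat in p.CATEGORIES:
            idx = np.flatnonzero(cats == cat)
            ref = ep.data[idx[0]]
            for k in idx[1:]:
                np.testing.assert_allclose(ep.data[k], ref, atol=1e-12)


class TestFMRIGenerator:
    def test_shapes_per_roi(self):
        ds, stim = p.generate_fmri_dataset(
            n_subjects=2, n_runs=7, n_exemplars_per_category=32, seed=0
        )
        assert len(ds) == 2
        for roi, stack in ds[0].items():
            n_stim, n_runs, n_vox = stack.values.shape
            assert n_stim == 96 and n_runs == 7 and n_vox >= 1

    def test_zero_noise_all_runs_identical(self):
        ds, _ = p.generate_fmri_dataset(
            n_subjects=1, n_runs=7, n_exemplars_per_category=2,
            run_noise_sd=0.0, seed=0,
        )
        stack = ds[0]["FFA"].values
        for r in range(1, 7):
            np.testing.assert_allclose(stack[:, r], stack[:, 0], atol=1e-12)

    def test_single_run_rejected(self):
        with pytest.raises(ValidationError, match="n_runs"):
            p.generate_fmri_dataset(n_subjects=1, n_runs=1, seed=0)

    def test_roi_profile_invalid_voxel_range_rejected(self):
        with pytest.raises(ValidationError, match="voxel_range"):
            p.ROIProfile("bad", np.zeros((3, 3)), voxel_range=(0, 5))


class TestRatings:
    def test_zero_variance_gives_exact_category_means(self):
        cfg = p.RatingConfig(
            category_sds={c: 0.0 for c in p.CATEGORIES},
            rater_noise_sd=0.0, n_exemplars_per_category=4, seed=0,
        )
        ratings = p.generate_ratings(cfg)
        stim = p.make_stimulus_set(4)
        for sid in ratings.columns:
            expected = cfg.category_means[stim.category_of(sid)]
            assert np.all(ratings[sid] == expected)

    def test_default_category_means_near_empirical_values(self):
        cfg = p.RatingConfig(n_exemplars_per_category=200, seed=5)
        ratings = p.generate_ratings(cfg)
        stim = p.make_stimulus_set(200)
        targets = {"human_face": 9.96, "illusory_face": 6.27, "matched_object": 0.70}
        for cat, mu in targets.items():
            ids = stim.by_category(cat)
            item_means = ratings[ids].mean(axis=0)
            se = item_means.std(ddof=1) / np.sqrt(len(ids))
            # the scale ceiling truncates human-face ratings (nominal mean
            # 9.96 sits within one rater-noise SD of 10), biasing the sample
            # mean downward; allow for that known truncation
            tol = max(2 * se, 0.05) + (0.12 if cat == "human_face" else 0.0)
            assert abs(item_means.mean() - mu) < tol

    def test_paired_t_across_yoked_items_large_positive(self):
        ratings = p.generate_ratings(p.RatingConfig(seed=1))
        stim = p.make_stimulus_set(32)
        ill = stim.by_category("illusory_face")
        mat = [stim.yoke_of(i) for i in ill]
        res = ttest_paired(
            ratings[ill].mean(axis=0).to_numpy(),
            ratings[mat].mean(axis=0).to_numpy(),
        )
        assert res.t > 10
        assert res.p < 1e-6

    def test_out_of_bounds_mean_rejected(self):
        with pytest.raises(ValidationError, match="bounds"):
            p.RatingConfig(category_means={
                "human_face": 11.0, "illusory_face": 6.0, "matched_object": 1.0,
            })
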