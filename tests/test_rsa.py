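import itertools

import numpy as np
import pytest
from scipy import stats as sps

import pareidolia as p
from pareidolia.core import RDM, PatternMatrix, ValidationError
from pareidolia.rsa import (
    ModelCorrelation,
    RDMTimecourse,
    category_average,
    category_contrast_perm,
    classical_mds,
    compute_rdm,
    kendall_tau_a,
    model_correlation_timecourse,
    noise_ceiling,
)


def _rdm_from_values(vals, labels=None):
    vals = np.asarray(vals, dtype=float)
    n = vals.shape[0]
    return RDM(vals, labels or [f"s{k}" for k in range(n)])


class TestComputeRDM:
    def test_identical_patterns_zero_dissimilarity(self):
        pat = PatternMatrix(np.tile([1.0, 2.0, 5.0, 3.0], (3, 1)) * [[1], [2], [3]],
                            ["a", "b", "c"])
        # rows are scalar multiples: identical ranks -> rho 1 -> dissimilarity 0
        rdm = compute_rdm(pat)
        assert np.allclose(rdm.matrix, 0.0, atol=1e-12)

    def test_rank_reversal_gives_two(self):
        pat = PatternMatrix(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]), ["a", "b"])
        assert compute_rdm(pat).matrix[0, 1] == pytest.approx(2.0)

    def test_matches_bruteforce_rank_then_pearson(self, rng):
        X = rng.standard_normal((3, 10))
        rdm = compute_rdm(PatternMatrix(X, ["a", "b", "c"]))
        for i, j in itertools.combinations(range(3), 2):
            ri = sps.rankdata(X[i])
            rj = sps.rankdata(X[j])
            expect = 1 - np.corrcoef(ri, rj)[0, 1]
            assert rdm.matrix[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_pattern_rejected_naming_item(self):
        X = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(ValidationError, match="'a'"):
            compute_rdm(PatternMatrix(X, ["a", "b"]))


class TestCategoryAverage:
    def test_constant_rdm_gives_constant_cells(self):
        m = np.full((4, 4), 0.7)
        np.fill_diagonal(m, 0.0)
        avg = category_average(_rdm_from_values(m), ["x", "x", "y", "y"])
        assert np.allclose(avg.matrix, 0.7)

    def test_matches_hand_computation(self):
        m = np.array(
            [[0.0, 1.0, 2.0, 3.0],
             [1.0, 0.0, 4.0, 5.0],
             [2.0, 4.0, 0.0, 6.0],
             [3.0, 5.0, 6.0, 0.0]]
        )
        avg = category_average(_rdm_from_values(m), ["x", "x", "y", "y"])
        i = avg.labels.index("x")
        j = avg.labels.index("y")
        assert avg.matrix[i, i] == pytest.approx(1.0)       # within x
        assert avg.matrix[j, j] == pytest.approx(6.0)       # within y
        assert avg.matrix[i, j] == pytest.approx((2 + 3 + 4 + 5) / 4)

    def test_symmetric_output(self, rng):
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        avg = category_average(_rdm_from_values(m), ["a", "a", "b", "b", "c", "c"])
        np.testing.assert_allclose(avg.matrix, avg.matrix.T)

    def test_single_item_category_rejected(self):
        m = np.zeros((3, 3))
        with pytest.raises(ValidationError, match="<2 items"):
            category_average(_rdm_from_values(m), ["a", "a", "b"])


class TestContrastPermutation:
    def test_label_invariant_rdm_gives_p_one(self):
        m = np.full((6, 6), 0.5)
        np.fill_diagonal(m, 0.0)
        obs, pv = category_contrast_perm(
            _rdm_from_values(m), ["a", "a", "b", "b", "c", "c"],
            (("a", "b"), ("a", "c")), n_perm=200, seed=0,
        )
        assert obs == pytest.approx(0.0)
        assert pv == pytest.approx(1.0)

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        rdm = _rdm_from_values(m)
        cats = ["a", "a", "b", "b", "c", "c"]
        contrast = (("a", "b"), ("a", "c"))
        obs, p_mc = category_contrast_perm(rdm, cats, contrast, n_perm=2000, seed=3)

        def stat(assign):
            avg = category_average(rdm, list(assign))
            return avg.cell("a", "b") - avg.cell("a", "c")

        nulls = [stat(perm) for perm in set(itertools.permutations(cats))]
        p_ex = np.mean([abs(v) >= abs(obs) - 1e-12 for v in nulls])
        se = np.sqrt(p_ex * (1 - p_ex) / 2000)
        assert abs(p_mc - p_ex) <= 3 * se + 1e-3


class TestClassicalMDS:
    def test_equilateral_three_points(self):
        m = np.ones((3, 3)) - np.eye(3)
        coords, evals = classical_mds(_rdm_from_values(m), k=2)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d[np.triu_indices(3, 1)], 1.0, atol=1e-10)

    def test_euclidean_rdm_reconstructed_exactly(self, rng):
        pts = rng.standard_normal((7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = classical_mds(_rdm_from_values(d), k=2)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_zero_rdm_gives_zero_coordinates(self):
        with pytest.warns(UserWarning):
            coords, _ = classical_mds(_rdm_from_values(np.zeros((4, 4))), k=2)
        assert coords.shape[1] == 0 or np.allclose(coords, 0.0)

    def test_full_dimension_reconstructs_any_euclidean_rdm(self, rng):
        pts = rng.standard_normal((6, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = classical_mds(_rdm_from_values(d), k=6)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        pts = rng.standard_normal((5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        c1, _ = classical_mds(_rdm_from_values(d), k=2)
        c2, _ = classical_mds(_rdm_from_values(d), k=2)
        np.testing.assert_array_equal(c1, c2)
        assert c1[np.abs(c1[:, 0]) > 1e-12, 0][0] > 0


class TestKendallTauA:
    @pytest.mark.parametrize(
        "x, y, expect",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 2], [1, 2, 3], 2 / 3),
        ],
    )
    def test_known_values(self, x, y, expect):
        assert kendall_tau_a(np.array(x, float), np.array(y, float)) == pytest.approx(expect)

    def test_matches_exhaustive_pair_counting(self, rng):
        for n in (5, 17, 50):
            x = rng.integers(0, 8, n).astype(float)  # ties present
            y = rng.standard_normal(n)
            num = 0
            for i, j in itertools.combinations(range(n), 2):
                num += int(np.sign(x[i] - x[j]) * np.sign(y[i] - y[j]))
            expect = num / (n * (n - 1) / 2)
            assert kendall_tau_a(x, y) == pytest.approx(expect)

    def test_tie_free_agrees_with_tau_b(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        assert kendall_tau_a(x, y) == pytest.approx(sps.kendalltau(x, y).statistic)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            kendall_tau_a(np.arange(3.0), np.arange(4.0))


class TestNoiseCeiling:
    def test_identical_subjects_lower_equals_upper(self, rng):
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        rdms = [_rdm_from_values(m) for _ in range(4)]
        lower, upper = noise_ceiling(rdms)
        assert lower == pytest.approx(upper)
        assert upper == pytest.approx(1.0)

    def test_lower_never_exceeds_upper(self, rng):
        for _ in range(50):
            rdms = []
            for _ in range(4):
                m = rng.random((5, 5))
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0)
                rdms.append(_rdm_from_values(m))
            lower, upper = noise_ceiling(rdms)
            assert lower <= upper + 1e-12

    def test_matches_bruteforce_on_three_subjects(self, rng):
        mats = []
        for _ in range(3):
            m = rng.random((4, 4))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mats.append(m)
        rdms = [_rdm_from_values(m) for m in mats]
        lower, upper = noise_ceiling(rdms)
        tril = np.tril_indices(4, -1)
        vecs = [m[tril] for m in mats]
        mean_all = np.mean(vecs, axis=0)
        up = np.mean([kendall_tau_a(v, mean_all) for v in vecs])
        lo = np.mean(
            [
                kendall_tau_a(vecs[i], np.mean([vecs[j] for j in range(3) if j != i], axis=0))
                for i in range(3)
            ]
        )
        assert upper == pytest.approx(up)
        assert lower == pytest.approx(lo)


class TestModelCorrelation:
    def test_model_equal_to_subject_rdm_gives_tau_one(self, rng):
        n = 6
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"s{k}" for k in range(n)]
        tc = RDMTimecourse(m[None, None], labels, np.array([100.0]))
        mc = model_correlation_timecourse(tc, RDM(m, labels), stimuli=None,
                                          exclude_categories=set())
        assert mc.tau[0, 0] == pytest.approx(1.0)

    def test_label_mismatch_rejected(self, rng):
        m = np.zeros((4, 4))
        tc = RDMTimecourse(m[None, None], ["a", "b", "c", "d"], np.array([0.0]))
        model = RDM(np.zeros((3, 3)), ["a", "b", "x"])
        with pytest.raises(ValidationError, match="missing"):
            model_correlation_timecourse(tc, model, stimuli=None, exclude_categories=set())

    def test_human_faces_excluded_by_default(self, small_meg):
        datasets, cfg = small_meg
        from pareidolia.preprocess import pca_reduce
        from pareidolia.rsa import rdm_timecourse

        stim = p.make_stimulus_set(cfg.n_exemplars_per_category)
        tc = rdm_timecourse([pca_reduce(datasets[0])], times_ms=np.array([160.0]))
        ratings = p.generate_ratings(p.RatingConfig(
            n_exemplars_per_category=cfg.n_exemplars_per_category, seed=0))
        model = p.behavioral_rdm(ratings)
        mc = model_correlation_timecourse(tc, model, stim)
        # only illusory + matched items remain: 2N items
        kept = 2 * cfg.n_exemplars_per_category
        assert mc.tau.shape == (1, 1)
        sub = tc.subset_items(stim.subset({"human_face"}))
        assert len(sub.labels) == kept
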