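"""PCA projections, exact planar Wasserstein, geometric median, and the
subgroup-separation experiment. Brute-force assignment enumeration serves as
the optimal-transport oracle."""

import itertools
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wasserstein_distance as scipy_w1

from patshortcut.representation import (draw_balanced_subsets, geometric_median,
                                        pca_project, representation_experiment,
                                        select_representative_model,
                                        wasserstein_2d)
from patshortcut.sampling import StratumCounts
from patshortcut.synthgen import GeneratorConfig, generate_pool


def brute_force_w(points_a, points_b, order=2):
    """Exact equal-size OT by enumerating all assignments."""
    A, B = np.asarray(points_a, float), np.asarray(points_b, float)
    n = len(A)
    best = np.inf
    for perm in itertools.permutations(range(n)):
        cost = np.mean([np.linalg.norm(A[i] - B[j]) ** order for i, j in enumerate(perm)])
        best = min(best, cost)
    return best ** (1.0 / order)


def _fake_ensemble(member_scores, y):
    """Ensemble stand-in whose members produce fixed scores (known AUROCs)."""
    members = [
        SimpleNamespace(spec=SimpleNamespace(task="disease"),
                        predict_proba=lambda subj, s=np.asarray(s): s)
        for s in member_scores
    ]
    subjects = [SimpleNamespace(disease="D" if v else "H", sex="F") for v in y]
    ens = SimpleNamespace(members=members, task="disease")
    return ens, subjects


class TestSelectRepresentativeModel:
    Y = [1, 1, 0, 0]
    S_100 = [0.9, 0.8, 0.2, 0.1]   # AUROC 1.0
    S_075 = [0.9, 0.2, 0.8, 0.1]   # AUROC 0.75
    S_050 = [0.5, 0.5, 0.5, 0.5]   # AUROC 0.5
    S_025 = [0.85, 0.2, 0.8, 0.9]  # AUROC 0.25

    def test_single_member_returned(self):
        ens, subj = _fake_ensemble([self.S_075], self.Y)
        assert select_representative_model(ens, subj) is ens.members[0]

    def test_odd_count_takes_exact_median(self):
        ens, subj = _fake_ensemble([self.S_050, self.S_075, self.S_100], self.Y)
        assert select_representative_model(ens, subj) is ens.members[1]

    def test_even_count_tie_takes_lower_index(self):
        # member AUROCs 0.25/0.5/0.75/1.0 -> median 0.625, 0.5 and 0.75
        # equidistant -> lowest index (the 0.5 member) wins
        ens, subj = _fake_ensemble(
            [self.S_025, self.S_050, self.S_075, self.S_100], self.Y)
        assert select_representative_model(ens, subj) is ens.members[1]


class TestDrawBalancedSubsets:
    CFG = GeneratorConfig(image_height=16, image_width=16)

    def test_subsets_are_balanced_pr1(self):
        pool = generate_pool(StratumCounts(10, 10, 10, 10), self.CFG, seed=0)
        by_id = {s.subject_id: s for s in pool}
        runs = draw_balanced_subsets(pool, per_stratum=7, n_runs=20, seed=1)
        for run in runs:
            assert len(run) == 28 and len(set(run)) == 28
            assert sum(by_id[i].sex == "F" for i in run) == 14
            assert sum(by_id[i].disease == "D" for i in run) == 14

    def test_exact_size_pool_forces_identical_runs(self):
        pool = generate_pool(StratumCounts(7, 7, 7, 7), self.CFG, seed=2)
        runs = draw_balanced_subsets(pool, per_stratum=7, n_runs=5, seed=3)
        assert all(sorted(r) == sorted(runs[0]) for r in runs)

    def test_larger_pool_produces_distinct_runs(self):
        pool = generate_pool(StratumCounts(10, 10, 10, 10), self.CFG, seed=4)
        runs = draw_balanced_subsets(pool, per_stratum=7, n_runs=50, seed=5)
        assert len({tuple(sorted(r)) for r in runs}) >= 2

    def test_stratum_shortfall_raises(self):
        pool = generate_pool(StratumCounts(6, 7, 7, 7), self.CFG, seed=6)
        with pytest.raises(ValueError, match="stratum"):
            draw_balanced_subsets(pool, per_stratum=7, n_runs=1, seed=0)


class TestPcaProject:
    def test_planar_cloud_explains_everything(self, rng):
        basis = rng.normal(size=(2, 8))
        X = rng.normal(size=(50, 2)) @ basis + rng.normal(size=8)
        proj = pca_project(X)
        assert sum(proj.explained_variance_fractions) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_cloud_spreads_variance(self, rng):
        X = rng.normal(size=(1000, 10))
        proj = pca_project(X)
        for f in proj.explained_variance_fractions:
            assert abs(f - 0.1) < 0.03

    def test_duplicating_points_preserves_projection(self, rng):
        X = rng.normal(size=(20, 5))
        a = pca_project(X).points
        b = pca_project(np.vstack([X, X])).points
        np.testing.assert_allclose(b[:20], a, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        X = rng.normal(size=(30, 4)) * np.array([5.0, 1.0, 0.5, 0.1])
        proj = pca_project(X)
        for c in range(2):
            assert proj.loadings[c, np.argmax(np.abs(proj.loadings[c]))] > 0

    def test_rank_deficient_input_rejected(self):
        X = np.ones((10, 4)) * np.arange(10)[:, None]  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            pca_project(X)

    def test_top2_reconstruction_residual_is_orthogonal(self, rng):
        X = rng.normal(size=(40, 6))
        proj = pca_project(X)
        Xc = X - X.mean(axis=0)
        recon = proj.points @ proj.loadings
        residual = Xc - recon
        assert np.abs(residual @ proj.loadings.T).max() < 1e-8


class TestWasserstein2d:
    def test_identical_sets_give_zero(self, rng):
        A = rng.normal(size=(6, 2))
        assert wasserstein_2d(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_transport_is_euclidean(self):
        assert wasserstein_2d([[0, 0]], [[3, 4]]) == pytest.approx(5.0)

    def test_two_point_parallel_transport(self):
        A = [[0, 0], [1, 0]]
        B = [[0, 1], [1, 1]]
        assert wasserstein_2d(A, B) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_assignment_enumeration(self, n, rng):
        A = rng.normal(size=(n, 2))
        B = rng.normal(size=(n, 2)) + 0.5
        assert wasserstein_2d(A, B) == pytest.approx(brute_force_w(A, B), rel=1e-9)

    def test_unequal_sizes_match_1d_transport(self, rng):
        """Collinear clouds of unequal size reduce to the classic 1-D
        earth-mover distance (order 1), solved here by the exact LP."""
        xa, xb = rng.normal(size=5), rng.normal(size=8)
        A = np.c_[xa, np.zeros(5)]
        B = np.c_[xb, np.zeros(8)]
        assert wasserstein_2d(A, B, order=1) == pytest.approx(
            scipy_w1(xa, xb), rel=1e-7)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        A, B, C = (r.normal(size=(r.integers(1, 5), 2)) for _ in range(3))
        ab, ba = wasserstein_2d(A, B), wasserstein_2d(B, A)
        assert ab == pytest.approx(ba, rel=1e-7)
        assert ab <= wasserstein_2d(A, C) + wasserstein_2d(C, B) + 1e-9


class TestGeometricMedian:
    def test_identical_points(self):
        X = np.tile([2.0, -1.0], (5, 1))
        np.testing.assert_allclose(geometric_median(X), [2.0, -1.0])

    def test_equilateral_triangle_gives_centroid(self):
        X = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        np.testing.assert_allclose(geometric_median(X), X.mean(axis=0), atol=1e-7)

    def test_collinear_points_give_coordinate_median(self):
        X = np.array([[0.0, 0], [1.0, 0], [10.0, 0]])
        np.testing.assert_allclose(geometric_median(X), [1.0, 0.0], atol=1e-6)

    def test_coincident_data_point_handled(self):
        X = np.array([[0.0, 0], [0.0, 0], [5.0, 0]])
        np.testing.assert_allclose(geometric_median(X), [0.0, 0.0], atol=1e-9)

    def test_objective_beats_every_data_point(self, rng):
        X = rng.normal(size=(25, 2))
        med = geometric_median(X)
        obj = lambda p: np.linalg.norm(X - p, axis=1).sum()
        assert obj(med) <= min(obj(x) for x in X) + 1e-9


class TestRepresentationExperiment:
    CFG = GeneratorConfig(image_height=16, image_width=16)

    def _pool(self):
        return generate_pool(StratumCounts(8, 8, 8, 8), self.CFG, seed=0)

    def test_constant_features_give_zero_distances_and_run_zero(self):
        pool = self._pool()
        model = SimpleNamespace(features=lambda subj: np.ones((len(subj), 6)))
        out = representation_experiment(model, model, pool, per_stratum=7,
                                        n_runs=8, seed=1)
        for summary in out.values():
            assert summary.median_w_sex == 0.0
            assert summary.median_w_disease == 0.0
            assert summary.representative_run_index == 0

    def test_sex_aligned_features_separate_sex_not_disease(self):
        """An embedding that is a scaled one-hot of sex must put all its
        Wasserstein mass on the sex grouping."""
        pool = self._pool()
        r = np.random.default_rng(2)

        def feats(subjects):
            onehot = np.array([[10.0, 0.0] if s.sex == "F" else [0.0, 10.0]
                               for s in subjects])
            return np.hstack([onehot, r.normal(0, 0.01, size=(len(subjects), 4))])

        model = SimpleNamespace(features=feats)
        out = representation_experiment(model, model, pool, per_stratum=7,
                                        n_runs=6, seed=3)
        s = out["pr1"]
        assert s.median_w_sex > 5 * max(s.median_w_disease, 1e-9)

    def test_summary_invariants(self):
        pool = self._pool()
        r = np.random.default_rng(4)
        model = SimpleNamespace(features=lambda subj: r.normal(size=(len(subj), 5)))
        out = representation_experiment(model, model, pool, per_stratum=7,
                                        n_runs=10, seed=5)
        for s in out.values():
            assert len(s.per_run_w_sex) == 10
            assert all(w >= 0 for w in s.per_run_w_sex + s.per_run_w_disease)
            assert s.iqr_w_sex[0] <= s.median_w_sex <= s.iqr_w_sex[1]
            assert 0 <= s.representative_run_index < 10
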