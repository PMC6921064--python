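import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg

from conftest import make_dataset
from morphoseq import morphometry as mm
from morphoseq.synthetic_data import LandmarkSimSpec, gen_landmarks


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]], float)
        assert mm.centroid_size(square) == pytest.approx(np.sqrt(8.0), abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneous_in_scale(self, s):
        rng = np.random.default_rng(7)
        X = rng.uniform(-5, 5, size=(18, 2))
        assert mm.centroid_size(X * s) == pytest.approx(s * mm.centroid_size(X), rel=1e-9)

    def test_matches_direct_summation(self, rng):
        X = rng.uniform(0, 100, size=(18, 2))
        c = X.mean(axis=0)
        direct = np.sqrt(sum((x - c[0]) ** 2 + (y - c[1]) ** 2 for x, y in X))
        assert mm.centroid_size(X) == pytest.approx(direct, abs=1e-12)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mm.centroid_size(np.ones((5, 2)))


def _similarity_copies(base, n, rng):
    out = []
    for _ in range(n):
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        out.append(base @ R.T * rng.uniform(0.5, 2.0) + rng.uniform(-10, 10, 2))
    return out


class TestGPA:
    def test_identical_specimens_zero_variance(self, triangle):
        ds = make_dataset({"g": [triangle.copy() for _ in range(4)]})
        fit = mm.gpa(ds)
        assert np.allclose(fit.aligned.std(axis=0), 0, atol=1e-12)
        # consensus equals the normalized shared shape (up to rotation)
        assert mm.procrustes_distance(fit.consensus, triangle) < 1e-9

    def test_similarity_transforms_removed(self, rng):
        base = rng.uniform(0, 100, size=(18, 2))
        ds = make_dataset({"g": [base] + _similarity_copies(base, 5, rng)})
        fit = mm.gpa(ds)
        n = len(ds)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(fit.aligned[i] - fit.aligned[j])
                assert d < 1e-8

    def test_centering_and_unit_size_invariants(self, rng):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=5, seed=3))
        fit = mm.gpa(res.dataset)
        for i in range(len(res.dataset)):
            X = fit.aligned_configuration(i)
            assert np.abs(X.mean(axis=0)).max() < 1e-9
            assert abs(np.sqrt((X**2).sum()) - 1.0) < 1e-9
        assert abs(np.sqrt((fit.consensus**2).sum()) - 1.0) < 1e-9

    def test_two_triangles_match_closed_form_rotation(self, rng):
        """For two configurations the optimal rotation has the closed form
        theta = atan2(sum(x1 y2 - y1 x2), sum(x1 x2 + y1 y2))."""
        A = rng.uniform(0, 1, size=(3, 2))
        B = rng.uniform(0, 1, size=(3, 2))

        def norm(X):
            X = X - X.mean(axis=0)
            return X / np.sqrt((X**2).sum())

        a, b = norm(A), norm(B)
        th = np.arctan2(
            (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]).sum(),
            (a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]).sum(),
        )
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expected = np.sqrt(((a @ R.T - b) ** 2).sum())
        assert mm.procrustes_distance(A, B) == pytest.approx(expected, abs=1e-10)

    def test_procrustes_distances_invariant_under_similarity(self, rng):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=3, seed=5))
        ds = res.dataset
        fit1 = mm.gpa(ds)
        # transform every raw configuration arbitrarily and re-fit
        transformed = {}
        for c in ds.configurations:
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            transformed.setdefault(c.group_label, []).append(
                c.landmarks @ R.T * rng.uniform(0.2, 3.0) + rng.uniform(-50, 50, 2)
            )
        fit2 = mm.gpa(make_dataset(transformed))
        d1 = np.array([np.linalg.norm(fit1.aligned[0] - fit1.aligned[i]) for i in range(len(ds))])
        d2 = np.array([np.linalg.norm(fit2.aligned[0] - fit2.aligned[i]) for i in range(len(ds))])
        np.testing.assert_allclose(d1, d2, atol=1e-8)


class TestCVA:
    def _fit(self, seed=0, groups=6, n=10):
        res = gen_landmarks(
            LandmarkSimSpec(
                groups=[f"g{i}" for i in range(groups)], n_per_group=n, seed=seed
            )
        )
        fit = mm.gpa(res.dataset)
        return mm.cva(fit, res.dataset.group_assignment()), res

    def test_six_groups_give_five_axes(self):
        result, _ = self._fit()
        assert result.n_axes == 5

    def test_identical_group_means_give_unit_wilks_and_zero_smd(self, rng, triangle):
        # both groups hold the exact same set of shapes -> between-group
        # scatter is exactly zero
        shapes = [triangle + rng.normal(scale=0.01, size=(3, 2)) for _ in range(10)]
        ds = make_dataset({"a": shapes, "b": [s.copy() for s in shapes]})
        fit = mm.gpa(ds)
        result = mm.cva(fit, ds.group_assignment())
        assert np.all(result.eigenvalues < 1e-9)
        assert result.wilks_lambda == pytest.approx(1.0, abs=1e-9)
        assert mm.mahalanobis_sq(result, "a", "b") == pytest.approx(0.0, abs=1e-9)

    def test_eigenvalues_match_dense_generalized_eigen_oracle(self):
        result, _ = self._fit(seed=2, groups=3, n=8)
        Y = result.reduced_coords
        labels = result.group_labels
        groups = result.groups
        W = np.zeros((Y.shape[1],) * 2)
        B = np.zeros_like(W)
        grand = Y.mean(axis=0)
        for gname in groups:
            Yg = Y[[i for i, lb in enumerate(labels) if lb == gname]]
            d = Yg - Yg.mean(axis=0)
            W += d.T @ d
            mb = Yg.mean(axis=0) - grand
            B += len(Yg) * np.outer(mb, mb)
        # independent route: ordinary eigenvalues of W^-1 B
        ev = np.sort(np.real(np.linalg.eigvals(np.linalg.solve(W, B))))[::-1]
        np.testing.assert_allclose(result.eigenvalues, ev[: result.n_axes], atol=1e-9)

    def test_wilks_identity_and_percent_variance(self):
        result, _ = self._fit(seed=4)
        lam = result.eigenvalues
        assert result.wilks_lambda == pytest.approx(np.prod(1 / (1 + lam)), abs=1e-9)
        assert result.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_canonical_scores_have_identity_within_covariance(self):
        result, _ = self._fit(seed=6)
        pooled = np.zeros((result.n_axes,) * 2)
        n = len(result.specimen_ids)
        for gname in result.groups:
            S = result.scores[[i for i, lb in enumerate(result.group_labels) if lb == gname]]
            d = S - S.mean(axis=0)
            pooled += d.T @ d
        pooled /= n - len(result.groups)
        np.testing.assert_allclose(pooled, np.eye(result.n_axes), atol=1e-8)


class TestMahalanobis:
    def test_same_group_zero(self):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=5, seed=1))
        fit = mm.gpa(res.dataset)
        result = mm.cva(fit, res.dataset.group_assignment())
        assert mm.mahalanobis_sq(result, "g1", "g1") == 0.0

    def test_euclidean_case_identity_covariance(self):
        result = mm.CVAResult(
            groups=["a", "b"],
            specimen_ids=[],
            group_labels=[],
            eigenvalues=np.array([1.0]),
            axes=np.eye(2)[:, :1],
            scores=np.zeros((0, 1)),
            percent_variance=np.array([100.0]),
            wilks_lambda=0.5,
            f_statistic=1.0,
            df1=1,
            df2=1,
            group_means_canonical=np.zeros((2, 1)),
            reduced_coords=np.zeros((0, 2)),
            group_means_reduced=np.array([[0.0, 0.0], [3.0, 4.0]]),
            pooled_cov_reduced=np.eye(2),
            pc_basis=np.eye(2),
            grand_mean=np.zeros(2),
        )
        assert mm.mahalanobis_sq(result, "a", "b") == pytest.approx(25.0)

    def test_matches_direct_quadratic_form(self):
        res = gen_landmarks(
            LandmarkSimSpec(groups=["a", "b", "c"], n_per_group=8, seed=9)
        )
        fit = mm.gpa(res.dataset)
        result = mm.cva(fit, res.dataset.group_assignment())
        diff = result.group_means_reduced[0] - result.group_means_reduced[1]
        direct = diff @ np.linalg.inv(result.pooled_cov_reduced) @ diff
        assert mm.mahalanobis_sq(result, "a", "b") == pytest.approx(direct, abs=1e-9)

    def test_unknown_group_rejected(self):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=5, seed=1))
        fit = mm.gpa(res.dataset)
        result = mm.cva(fit, res.dataset.group_assignment())
        with pytest.raises(KeyError):
            mm.mahalanobis_sq(result, "g1", "nope")

    def test_distance_matrix_symmetric_zero_diagonal(self):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=6, seed=2))
        fit = mm.gpa(res.dataset)
        smd = mm.shape_distance_matrix(mm.cva(fit, res.dataset.group_assignment()))
        np.testing.assert_allclose(smd.values, smd.values.T)
        assert np.all(np.diag(smd.values) == 0)
        assert np.all(smd.values >= 0)


class TestPhenogram:
    def test_two_groups_merge_at_half_distance(self):
        df = pd.DataFrame([[0, 10.0], [10.0, 0]], index=["A", "B"], columns=["A", "B"])
        tree = mm.upgma_phenogram(df)
        assert {t.name for t in tree.tips()} == {"A", "B"}
        assert all(abs(t.length - 5.0) < 1e-12 for t in tree.tips())

    def test_published_shape_distances_cluster_most_similar_pair_first(self):
        """With the published squared Mahalanobis distances among the six
        morphotypes, Brazilian-1 and Brazilian-3 (SMD 7.17, the smallest
        printed value) must be the first pair to merge."""
        groups = ["Brazilian-1", "Brazilian-2", "Brazilian-3", "Andean", "Mexican", "Peruvian"]
        printed = {
            ("Brazilian-1", "Brazilian-3"): 7.17,
            ("Brazilian-1", "Brazilian-2"): 45.9,
            ("Brazilian-2", "Brazilian-3"): 49.2,
            ("Peruvian", "Mexican"): 9.18,
            ("Mexican", "Andean"): 55.0,
            ("Brazilian-3", "Andean"): 70.4,
            ("Brazilian-3", "Peruvian"): 74.2,
        }
        M = pd.DataFrame(0.0, index=groups, columns=groups)
        filler = 60.0
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                v = printed.get((a, b)) or printed.get((b, a))
                if v is None:
                    v = filler
                    filler += 1.0
                M.loc[a, b] = M.loc[b, a] = v
        tree = mm.upgma_phenogram(M)
        pair = tree.lca(["Brazilian-1", "Brazilian-3"])
        assert {t.name for t in pair.tips()} == {"Brazilian-1", "Brazilian-3"}
        b1 = tree.find("Brazilian-1")
        assert b1.length == pytest.approx(7.17 / 2)


class TestClassification:
    def test_well_separated_groups_fully_recovered(self):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=10, seed=11))
        fit = mm.gpa(res.dataset)
        result = mm.cva(fit, res.dataset.group_assignment())
        matrix = mm.classify(result, "resubstitution")
        counts = matrix.counts.values
        assert np.all(counts == np.diag(np.diag(counts)))
        rows, overall = mm.percent_correct(matrix)
        assert overall == 100.0

    def test_resubstitution_matches_nearest_mean_oracle(self):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=8, seed=13, noise_sd=0.02))
        fit = mm.gpa(res.dataset)
        result = mm.cva(fit, res.dataset.group_assignment())
        matrix = mm.classify(result, "resubstitution")
        # brute-force nearest group mean in the pooled-covariance metric
        Vinv = np.linalg.inv(result.pooled_cov_reduced)
        oracle = np.zeros_like(matrix.counts.values)
        for i, lb in enumerate(result.group_labels):
            y = result.reduced_coords[i]
            d2 = [
                (y - mu) @ Vinv @ (y - mu) for mu in result.group_means_reduced
            ]
            oracle[result.groups.index(lb), int(np.argmin(d2))] += 1
        np.testing.assert_array_equal(matrix.counts.values, oracle)

    def test_row_sums_equal_group_sizes_in_both_modes(self):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=7, seed=15))
        fit = mm.gpa(res.dataset)
        result = mm.cva(fit, res.dataset.group_assignment())
        for mode in ("resubstitution", "leave_one_out"):
            matrix = mm.classify(result, mode)
            assert (matrix.counts.sum(axis=1) == 7).all()

    def test_unknown_mode_rejected(self):
        res = gen_landmarks(LandmarkSimSpec(n_per_group=5, seed=1))
        fit = mm.gpa(res.dataset)
        result = mm.cva(fit, res.dataset.group_assignment())
        with pytest.raises(ValueError, match="mode"):
            mm.classify(result, "jackknife")


class TestPercentCorrect:
    def test_identity_matrix_all_correct(self):
        counts = pd.DataFrame(np.eye(3, dtype=int) * 5, index=list("abc"), columns=list("abc"))
        rows, overall = mm.percent_correct(mm.ClassificationMatrix(counts))
        assert (rows == 100.0).all() and overall == 100.0

    def test_six_morphotype_confusion_matrix_arithmetic(self):
        groups = ["Brazilian-1", "Brazilian-2", "Brazilian-3", "Andean", "Mexican", "Peruvian"]
        counts = pd.DataFrame(
            [
                [85, 0, 1, 0, 0, 0],
                [0, 11, 0, 0, 0, 0],
                [0, 0, 21, 0, 0, 0],
                [0, 0, 0, 15, 0, 0],
                [0, 0, 0, 0, 60, 1],
                [0, 0, 0, 0, 0, 45],
            ],
            index=groups,
            columns=groups,
        )
        matrix = mm.ClassificationMatrix(counts)
        rows, overall = mm.percent_correct(matrix)
        assert matrix.total == 239
        assert rows["Brazilian-1"] == 98.8
        assert rows["Mexican"] == 98.4
        assert overall == 99.2

    def test_empty_row_rejected(self):
        counts = pd.DataFrame([[2, 0], [0, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="empty"):
            mm.percent_correct(mm.ClassificationMatrix(counts))


class TestCentroidSizeTest:
    def test_hand_computed_h_statistic(self):
        # ranks 1..6, no ties: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)
        res = mm.centroid_size_test([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        assert res.h_statistic == pytest.approx(4.5714, abs=1e-4)
        assert res.df == 2

    def test_identical_groups_no_signal(self):
        res = mm.centroid_size_test([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.h_statistic == 0.0
        assert (res.dunn["p_adjusted"] == 1.0).all()
        assert len(set(res.letters.values())) == 1

    def test_smaller_winged_groups_share_a_distinct_letter(self):
        """Two groups generated with smaller wings must be significant in
        the Kruskal-Wallis test and isolated by the letter display;
        verified against a permutation oracle for the H statistic."""
        res = gen_landmarks(
            LandmarkSimSpec(n_per_group=12, size_scales=[1, 1, 1, 1, 0.85, 0.85], seed=7)
        )
        sizes = np.array([mm.centroid_size(c) for c in res.dataset.configurations])
        groups = [c.group_label for c in res.dataset.configurations]
        out = mm.centroid_size_test(sizes, groups)
        assert out.p_value < 0.001
        small = {out.letters["g5"], out.letters["g6"]}
        large = {out.letters[g] for g in ("g1", "g2", "g3", "g4")}
        assert len(small) == 1 and small.isdisjoint(large)
        # permutation oracle for significance of H
        rng = np.random.default_rng(0)
        perm_h = []
        arr = np.array(groups)
        for _ in range(200):
            rng.shuffle(arr)
            perm_h.append(mm.centroid_size_test(sizes, list(arr)).h_statistic)
        assert (np.sum(np.array(perm_h) >= out.h_statistic) + 1) / 201 < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mm.centroid_size_test([1.0, 2.0], ["a", "a"])
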