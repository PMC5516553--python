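"""Cluster engine: Lloyd k-means, Sarle's CCC, local-peak selection, naming."""

import itertools
import math

import numpy as np
import pytest

from pdsubtypes import (
    CohortSpec,
    build_feature_matrix,
    compute_ccc,
    generate_cohort,
    kmeans,
    label_clusters,
    run_cluster_scan,
    select_k,
)
from pdsubtypes.cluster import ClusterSolution, ccc_from_expected, expected_r2
from pdsubtypes.features import FEATURE_COLUMNS, FeatureMatrix, standardize


def exhaustive_bipartition_wss(X):
    """Minimum WSS over every 2-part split (oracle for tiny n)."""
    n = X.shape[0]
    best = math.inf
    for size in range(1, n // 2 + 1):
        for subset in itertools.combinations(range(n), size):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            wss = 0.0
            for part in (X[mask], X[~mask]):
                wss += ((part - part.mean(axis=0)) ** 2).sum()
            best = min(best, wss)
    return best


class TestKMeans:
    def test_perfectly_separated_pairs(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        with pytest.warns(UserWarning):
            sol = kmeans(X, 2, restarts=5, seed=0)
        assert sol.wss == pytest.approx(0.0)
        assert sol.r2 == pytest.approx(1.0)
        assert sol.labels[0] == sol.labels[1] != sol.labels[2] == sol.labels[3]

    def test_single_cluster(self):
        rng = np.random.default_rng(0)
        X = standardize(rng.normal(size=(30, 3)))
        sol = kmeans(X, 1, restarts=1, seed=0)
        assert np.allclose(sol.centroids[0], X.mean(axis=0))
        assert sol.r2 == pytest.approx(0.0)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((3, 2)), 4)

    def test_determinism(self, feature_matrix):
        a = kmeans(feature_matrix, 4, restarts=10, seed=7)
        b = kmeans(feature_matrix, 4, restarts=10, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert a.wss == b.wss

    def test_no_empty_clusters(self, feature_matrix):
        for k in (2, 3, 4, 5):
            sol = kmeans(feature_matrix, k, restarts=5, seed=0)
            assert (sol.sizes() > 0).all()

    def test_matches_exhaustive_bipartition_oracle(self):
        """Best-of-50 restarts finds the global 2-cluster optimum at tiny n."""
        rng = np.random.default_rng(12)
        hits = 0
        trials = 100
        for _ in range(trials):
            n = int(rng.integers(5, 9))
            X = standardize(rng.normal(size=(n, 2)))
            sol = kmeans(X, 2, restarts=50, seed=int(rng.integers(2**31)))
            oracle = exhaustive_bipartition_wss(X)
            hits += math.isclose(sol.wss, oracle, rel_tol=1e-9, abs_tol=1e-9)
        assert hits >= 0.99 * trials

    def test_matches_sklearn_inertia(self, feature_matrix):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        for k in (2, 4):
            ours = kmeans(feature_matrix, k, restarts=20, seed=0)
            ref = sklearn_cluster.KMeans(n_clusters=k, n_init=20, random_state=0).fit(
                feature_matrix.values
            )
            # both are best-of-20 stochastic restarts; agreement to 0.1%
            assert ours.wss <= ref.inertia_ * (1 + 1e-3)


class TestCCC:
    def test_closed_form_against_independent_expression(self):
        # independently coded rendering of the same closed form
        r2, er2, n, p_star = 0.8, 0.5, 100, 2
        expected = (
            math.sqrt(n * p_star / 2)
            * math.log((1 - er2) / (1 - r2))
            / (0.001 + er2) ** 1.2
        )
        assert ccc_from_expected(r2, er2, n, p_star) == pytest.approx(expected)
        assert expected == pytest.approx(20.998, abs=0.01)

    def test_zero_when_r2_equals_expectation(self):
        rng = np.random.default_rng(0)
        X = standardize(rng.normal(size=(120, 5)))
        er2, _ = expected_r2(X, 3)
        assert compute_ccc(X, er2, 3) == pytest.approx(0.0, abs=1e-9)

    def test_r2_of_one_rejected(self):
        with pytest.raises(ValueError):
            ccc_from_expected(1.0, 0.5, 50, 2)
        with pytest.raises(ValueError):
            compute_ccc(np.zeros((10, 2)) + np.arange(10)[:, None], 1.0, 2)

    def test_peak_at_true_k_on_separated_blobs(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], float)
        X = standardize(np.vstack([c + rng.normal(0, 0.4, (60, 2)) for c in centers]))
        _, profile = run_cluster_scan(X, restarts=10, seed=0)
        assert profile.selected_k == 4
        assert profile.selection_kind == "interior_peak"

    def test_unimodal_data_yields_decreasing_ccc(self):
        rng = np.random.default_rng(6)
        X = standardize(rng.normal(size=(300, 9)))
        solutions, profile = run_cluster_scan(X, restarts=10, seed=0)
        cccs = [s.ccc for s in solutions]
        assert all(b < a for a, b in zip(cccs, cccs[1:]))


class TestSelectK:
    @pytest.mark.parametrize(
        "cccs,expected_k,kind",
        [
            ((1.0, 0.5, 3.0, 2.0), 4, "interior_peak"),
            ((1.0, 2.0, 3.0, 4.0), 5, "boundary_max"),
            ((0.0, 2.0, 1.0, 2.0), 3, "interior_peak"),
        ],
    )
    def test_local_peak_rule(self, cccs, expected_k, kind):
        profile = select_k([2, 3, 4, 5], cccs)
        assert profile.selected_k == expected_k
        assert profile.selection_kind == kind

    def test_equal_interior_peaks_break_to_smaller_k(self):
        profile = select_k([2, 3, 4, 5, 6], (0.0, 2.0, 1.0, 2.0, 0.0))
        assert profile.selected_k == 3

    def test_fewer_than_two_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_k([2], [1.0])


class TestClusterScan:
    def test_single_k_range(self, feature_matrix):
        solutions, profile = run_cluster_scan(feature_matrix, k_range=[2], restarts=5, seed=0)
        assert profile.selected_k == 2
        assert profile.selection_kind == "boundary_max"
        assert len(solutions) == 1

    def test_determinism(self, feature_matrix):
        _, a = run_cluster_scan(feature_matrix, restarts=5, seed=3)
        _, b = run_cluster_scan(feature_matrix, restarts=5, seed=3)
        assert a.ccc_values == b.ccc_values
        assert a.selected_k == b.selected_k

    def test_r2_nondecreasing_in_k(self, feature_matrix):
        solutions, _ = run_cluster_scan(feature_matrix, restarts=50, seed=0)
        r2s = [s.r2 for s in solutions]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_latent_agreement_above_chance(self):
        """k=4 assignments agree with the latent subgroups beyond chance."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        cohort = generate_cohort(CohortSpec(n=400, seed=2))
        fm = build_feature_matrix(cohort)
        sol = kmeans(fm, 4, restarts=50, seed=2)
        latent = [r.latent_cluster for r in cohort]
        ari = sklearn_metrics.adjusted_rand_score(latent, sol.labels)
        assert ari > 0.2


class TestLabelClusters:
    @staticmethod
    def _matrix_with_means(means_by_cluster):
        rows, labels = [], []
        cols = {name: i for i, name in enumerate(FEATURE_COLUMNS)}
        for j, means in enumerate(means_by_cluster):
            for _ in range(5):
                row = np.zeros(len(FEATURE_COLUMNS))
                for name, value in means.items():
                    row[cols[name]] = value
                rows.append(row)
                labels.append(j)
        raw = np.array(rows)
        fm = FeatureMatrix(
            ids=[str(i) for i in range(len(rows))], columns=FEATURE_COLUMNS,
            values=standardize(raw), raw=raw, standardized=True,
        )
        sol = ClusterSolution(
            k=len(means_by_cluster), ids=fm.ids, labels=np.array(labels),
            centroids=np.zeros((len(means_by_cluster), len(FEATURE_COLUMNS))),
            wss=1.0, tss=2.0,
        )
        return sol, fm

    def test_reported_centroid_pattern(self):
        sol, fm = self._matrix_with_means([
            {"motor_phenotype": 0.68, "progression_rate": 5.29, "age_onset": 56.63},
            {"motor_phenotype": 1.86, "progression_rate": 7.49, "age_onset": 62.28},
            {"motor_phenotype": 0.43, "progression_rate": 4.61, "age_onset": 59.86},
            {"motor_phenotype": 0.62, "progression_rate": 17.77, "age_onset": 69.87},
        ])
        names, evidence = label_clusters(sol, fm)
        assert names == {0: "YO", 1: "TD", 2: "NTD", 3: "RDP"}
        assert list(evidence["label"]) == ["YO", "TD", "NTD", "RDP"]

    def test_non_four_solution_gets_generic_names(self):
        sol, fm = self._matrix_with_means([
            {"age_onset": 50.0}, {"age_onset": 60.0}, {"age_onset": 70.0},
        ])
        names, _ = label_clusters(sol, fm)
        assert names == {0: "C1", 1: "C2", 2: "C3"}
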