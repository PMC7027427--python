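"""Clustering and classification tests."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import norm

from swarmtopo.ml import (
    cluster_accuracy,
    kmedoids_cluster,
    pca_reduce,
    phenotype_index_of_label,
    run_benchmark,
    svm_train_eval,
)
from swarmtopo.model import PARAM_GRID, PHENOTYPE_MAP


def _pam_objective(X, medoids):
    D = cdist(X, X)
    return D[:, medoids].min(axis=1).sum()


class TestPCA:
    def test_exact_low_rank_data_reconstructs(self, rng):
        basis = rng.normal(size=(3, 20))
        coeffs = rng.normal(size=(40, 3))
        x = coeffs @ basis + rng.normal(size=20)  # affine 3-dim subspace
        xr = pca_reduce(x, 3)
        # distances preserved exactly when the subspace is captured
        d_orig = cdist(x, x)
        d_red = cdist(xr, xr)
        np.testing.assert_allclose(d_red, d_orig, atol=1e-8)

    def test_full_dimension_preserves_distances(self, rng):
        x = rng.normal(size=(15, 6))
        xr = pca_reduce(x, 6)
        np.testing.assert_allclose(cdist(xr, xr), cdist(x, x), atol=1e-8)

    def test_variances_match_eigendecomposition(self, rng):
        x = rng.normal(size=(60, 8)) * np.arange(1, 9)
        xr = pca_reduce(x, 8)
        centered = x - x.mean(0)
        eigvals = np.sort(np.linalg.eigvalsh(centered.T @ centered
                                             / (len(x) - 1)))[::-1]
        np.testing.assert_allclose(np.var(xr, axis=0, ddof=1), eigvals,
                                   rtol=1e-8)

    def test_overlarge_dimension_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.normal(size=(5, 3)), 4)


class TestKMedoids:
    def test_separated_blobs_recovered(self, rng):
        centers = rng.uniform(-50, 50, (5, 2))
        x = np.vstack([c + 0.01 * rng.normal(size=(8, 2)) for c in centers])
        labels = np.repeat(np.arange(5), 8)
        assign, medoids = kmedoids_cluster(x, k=5)
        # each blob is one cluster
        for blob in range(5):
            assert len(set(assign[labels == blob])) == 1
        assert len(set(assign)) == 5

    def test_k_equals_n_gives_zero_objective(self, rng):
        x = rng.normal(size=(6, 3))
        assign, medoids = kmedoids_cluster(x, k=6)
        assert _pam_objective(x, medoids) == 0.0
        assert sorted(medoids) == list(range(6))

    @pytest.mark.parametrize("k,per_blob", [(2, 4), (3, 4), (3, 3)])
    def test_matches_exhaustive_search_on_clustered_instances(self, k,
                                                              per_blob, rng):
        """On instances with separated groups (the regime the clustering is
        used in) PAM's objective equals the global optimum over all medoid
        subsets. On fully unstructured clouds PAM — like any BUILD+SWAP
        local search, including the reference R implementation — can stop at
        a swap-local optimum, which the fixed-point test below covers."""
        for _ in range(10):
            centers = rng.uniform(-100, 100, (k, 2))
            while cdist(centers, centers)[np.triu_indices(k, 1)].min() < 30:
                centers = rng.uniform(-100, 100, (k, 2))
            x = np.vstack([c + rng.normal(size=(per_blob, 2))
                           for c in centers])
            _, medoids = kmedoids_cluster(x, k=k)
            got = _pam_objective(x, medoids)
            best = min(_pam_objective(x, list(sub))
                       for sub in combinations(range(len(x)), k))
            assert got == pytest.approx(best, rel=1e-12)

    def test_objective_comparable_to_reference_r_pam(self, rng, tmp_path):
        """Cross-check against cluster::pam (the reference implementation):
        both are BUILD+SWAP local searches, so objectives agree on most
        instances and neither dominates; require ours within 5% of R's."""
        import subprocess

        for trial in range(5):
            n, k = 18, 3
            x = rng.normal(size=(n, 3))
            _, medoids = kmedoids_cluster(x, k=k)
            mine = _pam_objective(x, medoids)
            csv = tmp_path / f"pts{trial}.csv"
            np.savetxt(csv, x, delimiter=",")
            out = subprocess.run(
                ["Rscript", "-e",
                 f'x <- as.matrix(read.csv("{csv}", header=FALSE));'
                 f'library(cluster); p <- pam(x, {k});'
                 f'cat(p$objective["swap"] * nrow(x))'],
                capture_output=True, text=True, check=True)
            r_obj = float(out.stdout.strip().split()[-1])
            assert mine <= r_obj * 1.05 + 1e-9

    def test_objective_is_swap_fixed_point(self, rng):
        x = rng.normal(size=(30, 2))
        _, medoids = kmedoids_cluster(x, k=4)
        base = _pam_objective(x, medoids)
        for mi in range(4):
            for h in range(30):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                assert _pam_objective(x, trial) >= base - 1e-9


class TestClusterAccuracy:
    def test_perfect_clustering_scores_one(self):
        labels = np.repeat(np.arange(25), 4)
        phenos = phenotype_index_of_label()[labels]
        rep = cluster_accuracy(labels.copy(), labels, phenos)
        assert rep.parameter_accuracy == 1.0
        assert rep.phenotype_accuracy == 1.0
        assert rep.param_confusion.trace() == 100

    def test_hand_built_majority_example(self):
        # two clusters over six rows, one row misplaced: accuracy 5/6
        assign = np.array([0, 0, 0, 1, 1, 1])
        labels = np.array([0, 0, 1, 1, 1, 1])
        phenos = np.zeros(6, dtype=int)
        rep = cluster_accuracy(assign, labels, phenos, n_classes=2)
        assert rep.parameter_accuracy == pytest.approx(5 / 6)

    def test_row_permutation_invariance(self, rng):
        assign = rng.integers(0, 5, 60)
        labels = rng.integers(0, 5, 60)
        phenos = rng.integers(0, 7, 60)
        rep = cluster_accuracy(assign, labels, phenos, n_classes=5)
        perm = rng.permutation(60)
        rep_p = cluster_accuracy(assign[perm], labels[perm], phenos[perm],
                                 n_classes=5)
        assert rep.parameter_accuracy == pytest.approx(rep_p.parameter_accuracy)

    def test_hungarian_mapping_is_one_to_one(self, rng):
        labels = np.repeat(np.arange(4), 5)
        assign = labels.copy()
        rep = cluster_accuracy(assign, labels, np.zeros(20, int),
                               n_classes=4, mapping="hungarian")
        assert rep.parameter_accuracy == 1.0


class TestSvm:
    def test_separable_classes_fully_recovered(self, rng):
        x = np.vstack([rng.normal(size=(20, 2)),
                       rng.normal(size=(20, 2)) + 50])
        y = np.repeat([0, 1], 20)
        rep = svm_train_eval(x, y, np.repeat([0, 1], 20), n_classes=2)
        assert rep.parameter_accuracy == 1.0

    def test_accuracy_near_bayes_rate_for_overlapping_gaussians(self, rng):
        # two 1-D unit-variance Gaussians at +/- mu: Bayes accuracy Phi(mu)
        mu = 1.0
        n = 400
        x = np.concatenate([rng.normal(-mu, 1, n),
                            rng.normal(+mu, 1, n)])[:, None]
        y = np.repeat([0, 1], n)
        rep = svm_train_eval(x, y, y.copy(), n_classes=2, seed=1)
        bayes = norm.cdf(mu)
        assert rep.parameter_accuracy == pytest.approx(bayes, abs=0.05)

    def test_class_smaller_than_folds_rejected(self, rng):
        x = rng.normal(size=(7, 2))
        y = np.array([0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError):
            svm_train_eval(x, y, y.copy(), folds=5, n_classes=2)

    def test_phenotype_accuracy_dominates_parameter_accuracy(self, rng):
        # noisy 25-class problem on the real phenotype map
        labels = np.repeat(np.arange(25), 5)
        x = labels[:, None] + rng.normal(0, 2.0, (125, 1))
        phenos = phenotype_index_of_label()[labels]
        rep = svm_train_eval(x, labels, phenos, seed=0)
        assert rep.phenotype_accuracy >= rep.parameter_accuracy


class TestRunBenchmark:
    def test_emits_all_cells_and_is_deterministic(self, rng):
        labels = np.repeat(np.arange(5), 6)
        phenos = labels % 3
        feats = {
            "op/toy": rng.normal(size=(30, 8)) + labels[:, None],
            "tda/toy": rng.normal(size=(30, 12)) + 2 * labels[:, None],
        }
        kw = dict(label_indices=labels, phenotype_indices=phenos,
                  methods=("kmedoids", "svm"), pca_dims=(None, 3), k=5,
                  folds=5, seed=3)
        a = run_benchmark(feats, **kw)
        b = run_benchmark(feats, **kw)
        assert len(a) == 2 * (1 + 2)  # kmedoids + svm x {raw, pca3}
        assert a.equals(b)
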