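"""Standardization, agglomerative clustering, class naming and LOTO-CV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from edafaa.classify import (agglomerative_cluster, coincidence_rate,
                             label_clusters_by_faa, loto_cv, standardize)


def _two_blobs(rng, n_per=30, sep=10.0, dims=2):
    a = rng.normal(size=(n_per, dims))
    b = rng.normal(size=(n_per, dims)) + sep
    return np.vstack([a, b]), np.repeat([0, 1], n_per)


def _synthetic_table(rng, kappa=1.0, noise=0.05, n_trials=12, n_windows=30,
                     n_features=3):
    """Windowed table with a two-state latent process driving both the
    features and the ratio-FAA target; strength kappa, observation noise."""
    rows = []
    for trial in range(1, n_trials + 1):
        state = 1.0 if trial % 2 else -1.0
        for _ in range(n_windows):
            latent = state * rng.uniform(0.2, 0.6)
            feats = {f"f{j}": kappa * latent + noise * rng.normal()
                     for j in range(n_features)}
            rows.append({"participant": 1, "task": "EAT", "trial": trial,
                         "P_Asym": latent + 0.02 * rng.normal(), **feats})
    return pd.DataFrame(rows)


class TestStandardize:
    def test_self_statistics_give_zero_mean_unit_sd(self, rng):
        Z = standardize(rng.normal(loc=3, scale=2, size=(200, 4)))
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_train_statistics_preserve_test_shift(self, rng):
        train = rng.normal(size=(100, 2))
        test = train + 5.0
        Zte = standardize(test, stats_from=train)
        Ztr = standardize(train)
        assert np.allclose(Zte.mean(axis=0) - Ztr.mean(axis=0),
                           5.0 / train.std(axis=0), atol=1e-9)

    def test_idempotent_on_standardized_input(self, rng):
        Z = standardize(rng.normal(size=(100, 3)))
        assert np.allclose(standardize(Z), Z, atol=1e-9)

    def test_constant_column_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="1"):
            standardize(X)


def _brute_force_single_linkage(X):
    """O(n^3) reference: merge closest clusters under single linkage."""
    d = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best, pair = np.inf, None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            dist = min(d[a, b] for a in clusters[i] for b in clusters[j])
            if dist < best:
                best, pair = dist, (i, j)
        i, j = pair
        merges.append((sorted(clusters[i] + clusters[j]), best))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] \
            + [clusters[i] + clusters[j]]
    return merges


class TestClustering:
    def test_well_separated_blobs_recovered_exactly(self, rng):
        X, truth = _two_blobs(rng)
        labels = agglomerative_cluster(X).labels
        agreement = max(np.mean(labels == truth), np.mean(labels != truth))
        assert agreement == 1.0

    def test_identical_points_merge_at_zero_distance(self):
        res = agglomerative_cluster(np.zeros((3, 2)), n_clusters=1)
        assert res.merge_tree[0, 2] == 0.0
        assert res.merge_tree[1, 2] == 0.0

    def test_single_linkage_matches_brute_force_on_chain(self, rng):
        # 5-point chain with distinct gaps
        X = np.array([[0.0], [1.0], [2.5], [4.5], [7.0]])
        res = agglomerative_cluster(X, linkage="single", n_clusters=1)
        expected = _brute_force_single_linkage(X)
        assert np.allclose(res.merge_tree[:, 2],
                           [dist for _, dist in expected])

    def test_merge_distances_nondecreasing(self, rng):
        X = rng.normal(size=(40, 3))
        for linkage in ("single", "complete", "average"):
            Z = agglomerative_cluster(X, linkage=linkage).merge_tree
            assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_two_cluster_cut_is_stable_on_separated_data(self, rng):
        X, _ = _two_blobs(rng, sep=12.0)
        Z = agglomerative_cluster(standardize(X)).merge_tree
        assert Z[-1, 2] >= 2 * Z[-2, 2]

    def test_fewer_rows_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            agglomerative_cluster(np.zeros((1, 2)), n_clusters=2)


class TestClassNaming:
    def test_positive_cluster_becomes_class_one(self, rng):
        X, truth = _two_blobs(rng)
        res = agglomerative_cluster(X)
        p_faa = np.where(truth == 1, 0.5, -0.5)
        classes = label_clusters_by_faa(res, p_faa)
        assert np.all(classes[truth == 1] == 1)
        assert np.all(classes[truth == 0] == 2)

    def test_invariant_to_cluster_index_swap(self, rng):
        X, truth = _two_blobs(rng)
        res = agglomerative_cluster(X)
        from edafaa.classify import ClusteringResult
        swapped = ClusteringResult(labels=1 - res.labels,
                                   merge_tree=res.merge_tree,
                                   linkage=res.linkage, n_clusters=2)
        p_faa = np.where(truth == 1, 0.5, -0.5)
        assert np.array_equal(label_clusters_by_faa(res, p_faa),
                              label_clusters_by_faa(swapped, p_faa))

    def test_strong_coupling_table_names_classes_in_the_right_direction(
            self, small_table):
        """Closed loop on generated data: Class 1 collects the higher-FAA
        windows.  The 2-cluster cut on the pooled noisy window features is not
        always sign-pure (it can peel a sub-mode), so the directional
        property, not full purity, is the reliable contract."""
        from edafaa.features import mi_feature_ranking, select_top_features
        ranking = mi_feature_ranking(small_table,
                                     group_by=("participant", "task"))
        top = select_top_features(ranking, 6)
        Z = standardize(small_table[top].to_numpy())
        res = agglomerative_cluster(Z)
        faa = small_table["P_Asym"].to_numpy()
        classes = label_clusters_by_faa(res, faa)
        assert faa[classes == 1].mean() > faa[classes == 2].mean()
        assert (faa[classes == 1] > 0).mean() > (faa[classes == 2] > 0).mean()


class TestCoincidence:
    def test_perfect_agreement(self):
        pred = np.array([1, 1, 2, 2])
        faa = np.array([0.3, 0.1, -0.2, -0.4])
        assert coincidence_rate(pred, faa) == (100.0, 100.0)

    def test_random_labels_on_balanced_fixture_near_chance(self, rng):
        faa = rng.choice([-1.0, 1.0], size=1000)
        pred = rng.choice([1, 2], size=1000)
        c1, c2 = coincidence_rate(pred, faa)
        assert 40 <= c1 <= 60 and 40 <= c2 <= 60

    def test_flipping_predictions_complements_rates(self, rng):
        faa = np.concatenate([rng.uniform(0.1, 1, 500),
                              rng.uniform(-1, -0.1, 500)])
        pred = rng.choice([1, 2], size=1000)
        c1, c2 = coincidence_rate(pred, faa)
        f1, f2 = coincidence_rate(np.where(pred == 1, 2, 1), faa)
        assert f1 == pytest.approx(100 - c2)
        assert f2 == pytest.approx(100 - c1)

    def test_empty_class_reported_missing(self):
        c1, c2 = coincidence_rate(np.array([1, 1]), np.array([0.5, 0.5]))
        assert c1 == 100.0 and np.isnan(c2)

    def test_zero_faa_counts_as_class_two(self):
        c1, c2 = coincidence_rate(np.array([2]), np.array([0.0]))
        assert c2 == 100.0


class TestLotoCv:
    def test_near_separable_table_scores_high_everywhere(self, rng):
        table = _synthetic_table(rng, kappa=1.0, noise=0.05)
        report = loto_cv(table, ["f0", "f1", "f2"])
        vals = report.per_trial[["class1_pct", "class2_pct"]].to_numpy()
        assert np.nanmin(vals) >= 95.0

    def test_uncoupled_features_score_near_chance(self, rng):
        table = _synthetic_table(rng, kappa=0.0, noise=1.0)
        report = loto_cv(table, ["f0", "f1", "f2"])
        assert 35.0 <= report.grand_average <= 65.0

    def test_performance_nondecreasing_in_coupling(self):
        """20-seed average coincidence grows with the coupling strength."""
        means = []
        for kappa in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                table = _synthetic_table(rng, kappa=kappa, noise=0.1,
                                         n_trials=6, n_windows=20)
                vals.append(loto_cv(table, ["f0", "f1", "f2"]).grand_average)
            means.append(np.mean(vals))
        assert all(a <= b + 2.0 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 10.0

    def test_faa_and_label_columns_rejected_as_features(self, rng):
        table = _synthetic_table(rng)
        with pytest.raises(ValueError, match="firewall|may not"):
            loto_cv(table, ["f0", "P_Asym"])
        with pytest.raises(ValueError, match="firewall|may not"):
            loto_cv(table, ["f0", "trial"])

    def test_report_shape_and_averages(self, rng):
        table = _synthetic_table(rng)
        report = loto_cv(table, ["f0", "f1"])
        assert len(report.per_trial) == 12
        avg = report.task_averages
        assert avg.loc[0, "class1_pct"] == pytest.approx(
            report.per_trial["class1_pct"].mean())

    def test_test_fold_rows_never_influence_the_fitted_model(self, rng):
        """CV hygiene mutation check: perturbing held-out rows leaves every
        fold's standardizer and SVM untouched."""
        table = _synthetic_table(rng, n_trials=6, n_windows=15)
        _, models_a = loto_cv(table, ["f0", "f1", "f2"], return_models=True)
        mutated = table.copy()
        held = mutated["trial"] == 3
        mutated.loc[held, ["f0", "f1", "f2"]] += 100.0
        mutated.loc[held, "P_Asym"] *= -1
        _, models_b = loto_cv(mutated, ["f0", "f1", "f2"], return_models=True)
        mean_a, sd_a, svm_a = models_a[("EAT", 3)]
        mean_b, sd_b, svm_b = models_b[("EAT", 3)]
        assert np.array_equal(mean_a, mean_b)
        assert np.array_equal(sd_a, sd_b)
        assert np.array_equal(svm_a.dual_coef_, svm_b.dual_coef_)
        assert np.array_equal(svm_a.intercept_, svm_b.intercept_)

    def test_global_labeling_mode_runs(self, rng):
        table = _synthetic_table(rng)
        report = loto_cv(table, ["f0", "f1"], labeling="global")
        assert len(report.per_trial) == 12
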