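import itertools

import numpy as np
import pandas as pd
import pytest

from fibrostrat.io_formats import ClinicalTable, ExpressionMatrix
from fibrostrat.subtype_clustering import (
    ClusterAssignment,
    clinical_separation_score,
    fit_pca_project,
    order_clusters_by_severity,
    select_cluster_count,
    severity_group,
    ward_cluster,
)


def _clinical(rows):
    return ClinicalTable(pd.DataFrame(rows))


class TestSeverityGroup:
    @pytest.mark.parametrize(
        "fvc, dlco, expected",
        [
            (60.0, 30.0, "mild_moderate"),  # FVC criterion rescues
            (50.0, 39.0, "severe"),  # both cut-offs fail
            (np.nan, np.nan, "unknown"),
            (np.nan, 45.0, "mild_moderate"),  # available measure decides
            (54.0, np.nan, "severe"),
            (55.0, 39.0, "mild_moderate"),  # boundary is inclusive
        ],
    )
    def test_lung_function_rule(self, fvc, dlco, expected):
        clin = _clinical(
            [{"sample_id": "p1", "group": "disease", "fvc_pct": fvc, "dlco_pct": dlco}]
        )
        assert severity_group(clin).loc["p1"] == expected

    def test_controls_are_not_graded(self, small_clinical):
        groups = severity_group(small_clinical)
        assert set(groups.index) == set(small_clinical.disease_samples())


class TestPCAProjection:
    def test_rank_one_data_has_single_component(self):
        base = np.array([[1.0, 2.0, 3.0, 4.0]])
        m = ExpressionMatrix.from_arrays(
            ["g1", "g2"], list("abcd"), np.vstack([base, 2 * base])
        )
        model, _ = fit_pca_project(m, m, n_components=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_projection_matches_fit_scores(self, rng):
        values = rng.normal(size=(30, 12))
        genes = [f"g{i}" for i in range(30)]
        all_m = ExpressionMatrix.from_arrays(genes, [f"s{j}" for j in range(12)], values)
        disease = [f"s{j}" for j in range(4, 12)]
        disease_m = all_m.subset_samples(disease)
        model, scores = fit_pca_project(disease_m, all_m, n_components=5)
        from sklearn.decomposition import PCA

        direct = PCA(n_components=5, svd_solver="full").fit_transform(disease_m.values.T)
        np.testing.assert_allclose(
            np.abs(scores.loc[disease].to_numpy()), np.abs(direct), atol=1e-8
        )

    def test_loadings_match_hand_eigendecomposition(self):
        # 3 samples x 2 genes; covariance eigenvectors computed by hand
        X = np.array([[1.0, 2.0, 3.0], [1.0, 3.0, 5.0]])  # genes x samples
        m = ExpressionMatrix.from_arrays(["g1", "g2"], ["a", "b", "c"], X)
        model, _ = fit_pca_project(m, m, n_components=2)
        cov = np.cov(X)
        w, v = np.linalg.eigh(cov)
        leading = v[:, np.argmax(w)]
        got = model.loadings["PC1"].to_numpy()
        assert abs(abs(got @ leading) - 1.0) < 1e-8

    def test_orthonormal_loadings(self, rng):
        values = rng.normal(size=(25, 10))
        m = ExpressionMatrix.from_arrays(
            [f"g{i}" for i in range(25)], [f"s{j}" for j in range(10)], values
        )
        model, _ = fit_pca_project(m, m, n_components=4)
        L = model.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-8)

    def test_too_many_components_raises(self, small_matrix):
        with pytest.raises(ValueError):
            fit_pca_project(small_matrix, small_matrix, n_components=10)


def _brute_force_ward(points, k):
    """Exhaustive Ward agglomeration: repeatedly merge the pair with the
    smallest Ward cost increase; lowest-index pair on ties."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    clusters = [[i] for i in range(len(points))]
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = points[clusters[a]], points[clusters[b]]
            na, nb = len(ca), len(cb)
            cost = (na * nb) / (na + nb) * np.sum((ca.mean(0) - cb.mean(0)) ** 2)
            if best is None or cost < best[0] - 1e-12:
                best = (cost, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(points), dtype=int)
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab
    return labels


def _partitions_equal(a, b):
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


class TestWard:
    def test_well_separated_pairs(self):
        labels = ward_cluster(np.array([0.0, 1.0, 10.0, 11.0]), 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n_gives_singletons(self):
        assert len(set(ward_cluster(np.arange(5, dtype=float), 5))) == 5

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError):
            ward_cluster(np.arange(4, dtype=float), 0)

    @pytest.mark.parametrize("n, k", [(6, 2), (7, 3), (8, 2), (8, 4)])
    def test_matches_exhaustive_ward_oracle(self, rng, n, k):
        for _ in range(5):
            points = rng.normal(size=(n, 2))
            got = ward_cluster(points, k)
            expected = _brute_force_ward(points, k)
            assert _partitions_equal(got, expected)


class TestSeparationScore:
    def _two_cluster_clinical(self, values_a, values_b, measure="fev1_pct"):
        rows = []
        for i, v in enumerate(values_a):
            rows.append({"sample_id": f"a{i}", "group": "disease", measure: v})
        for i, v in enumerate(values_b):
            rows.append({"sample_id": f"b{i}", "group": "disease", measure: v})
        labels = pd.Series(
            ["A"] * len(values_a) + ["B"] * len(values_b),
            index=[f"a{i}" for i in range(len(values_a))]
            + [f"b{i}" for i in range(len(values_b))],
        )
        return labels, _clinical(rows)

    def test_identical_cluster_means_score_zero(self):
        labels, clin = self._two_cluster_clinical([50, 60], [50, 60])
        assert clinical_separation_score(labels, clin) == pytest.approx(0.0)

    def test_direct_arithmetic_example(self):
        # means 40 and 60, pooled within-cluster SD 10 -> score 2.0
        labels, clin = self._two_cluster_clinical([30, 50], [50, 70])
        # each cluster SD = sqrt(200) ... construct exact SD 10:
        labels, clin = self._two_cluster_clinical(
            [40 - 10 * np.sqrt(1 / 2), 40 + 10 * np.sqrt(1 / 2)],
            [60 - 10 * np.sqrt(1 / 2), 60 + 10 * np.sqrt(1 / 2)],
        )
        assert clinical_separation_score(labels, clin) == pytest.approx(2.0)

    def test_invariant_to_relabeling(self, rng):
        labels, clin = self._two_cluster_clinical(
            rng.normal(50, 5, 6), rng.normal(70, 5, 6)
        )
        renamed = labels.map({"A": "X", "B": "Y"})
        assert clinical_separation_score(labels, clin) == pytest.approx(
            clinical_separation_score(renamed, clin)
        )

    def test_single_cluster_raises(self):
        labels, clin = self._two_cluster_clinical([50, 60], [])
        with pytest.raises(ValueError):
            clinical_separation_score(labels[labels == "A"], clin)


class TestSelectClusterCount:
    def test_two_separated_groups_select_two(self, rng):
        # two clean expression clusters whose clinical profiles differ
        # far more between than within groups: the smallest k already
        # achieves the maximal separation, so k = 2 is forced
        n = 30
        points = np.concatenate([rng.normal(0, 0.3, n), rng.normal(8, 0.3, n)])
        ids = [f"p{i}" for i in range(2 * n)]
        rows = [
            {
                "sample_id": ids[i],
                "group": "disease",
                "fev1_pct": 80 - 30 * (i >= n) + rng.normal(0, 1),
                "fvc_pct": 85 - 30 * (i >= n) + rng.normal(0, 1),
                "dlco_pct": 75 - 30 * (i >= n) + rng.normal(0, 1),
            }
            for i in range(2 * n)
        ]
        k, trace = select_cluster_count(points, ids, _clinical(rows), k_max=6)
        assert k == 2
        assert list(trace["k"]) == [2, 3, 4, 5, 6]

    def test_zero_tolerance_returns_argmax(self, rng, default_cohort):
        from fibrostrat import preprocess

        m, clin, _ = default_cohort
        cen = preprocess.median_center_genes(m)
        sub = preprocess.standardize_genes(
            cen.subset_genes(preprocess.top_variable_genes(cen, 0.25))
        )
        dis = clin.disease_samples()
        _, scores = fit_pca_project(
            sub.subset_samples(dis), sub, explained_variance=0.9
        )
        pts = scores.loc[dis].to_numpy()
        k, trace = select_cluster_count(pts, dis, clin, tolerance=0.0)
        best = trace.dropna()
        assert k == int(best.loc[best["score"].idxmax(), "k"])


class TestSeverityOrdering:
    def test_higher_dlco_becomes_first_cluster(self):
        labels = pd.Series(["x", "x", "y", "y"], index=["p1", "p2", "p3", "p4"])
        clin = _clinical(
            [
                {"sample_id": f"p{i}", "group": "disease", "dlco_pct": v}
                for i, v in [(1, 70), (2, 72), (3, 30), (4, 28)]
            ]
        )
        assignment = order_clusters_by_severity(labels, clin)
        assert assignment.labels.loc["p1"] == "C1"
        assert assignment.labels.loc["p3"] == "C2"

    def test_input_label_names_do_not_matter(self, rng):
        ids = [f"p{i}" for i in range(12)]
        clin = _clinical(
            [
                {"sample_id": s, "group": "disease", "dlco_pct": 30 + 5 * (i % 3)}
                for i, s in enumerate(ids)
            ]
        )
        labels = pd.Series([i % 3 for i in range(12)], index=ids)
        permuted = labels.map({0: 7, 1: 5, 2: 9})
        a = order_clusters_by_severity(labels, clin)
        b = order_clusters_by_severity(permuted, clin)
        assert a.labels.equals(b.labels)

    def test_mean_dlco_is_nonincreasing(self, default_cohort):
        m, clin, truth = default_cohort
        assignment = order_clusters_by_severity(truth.subgroups, clin)
        means = clin.measure("dlco_pct").groupby(assignment.labels).mean()
        ordered = means.reindex(assignment.cluster_names()).to_numpy()
        assert (np.diff(ordered) <= 1e-9).all()
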