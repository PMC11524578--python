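"""PCA, SNN/Leiden communities, markers, group tests and pseudobulk DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import menigrad as mg


def _gaussian_blobs(rng, centers, n_per, scale=1.0):
    pts = np.concatenate([rng.normal(c, scale, size=(n_per, len(c))) for c in centers])
    return pts


class TestPCA:
    def test_rank_one_matrix_single_direction(self):
        u = np.linspace(1, 3, 8)
        v = np.array([2.0, -1.0, 0.5, 4.0])
        X = np.outer(v, u)  # genes x spots, all spots on one line
        emb = mg.embed_pca(X, n_components=2)
        total_var = np.asarray(X.T, float).var(axis=0, ddof=1).sum()
        assert emb[:, 0].var(ddof=1) == pytest.approx(total_var, rel=1e-9)
        assert emb[:, 1].var(ddof=1) == pytest.approx(0.0, abs=1e-18)

    def test_components_orthonormal_scores_uncorrelated(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 200))
        emb = mg.embed_pca(X, n_components=5)
        cov = np.cov(emb.T)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-8)
        assert np.all(np.diff(np.diag(cov)) <= 1e-8)  # non-increasing variance

    def test_axes_align_with_known_covariance(self):
        """2-D Gaussian cloud: PC axes match the covariance eigenvectors."""
        rng = np.random.default_rng(1)
        cov = np.array([[4.0, 1.2], [1.2, 1.0]])
        pts = rng.multivariate_normal([0, 0], cov, size=4000)  # spots x genes
        emb = mg.embed_pca(pts.T, n_components=2)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        # recover the loading direction by regressing data on scores
        load = pts.T @ emb[:, 0] / (emb[:, 0] @ emb[:, 0])
        cos = abs(load @ lead) / np.linalg.norm(load)
        assert cos > 0.99

    def test_excess_components_reduced_with_warning(self):
        X = np.random.default_rng(2).normal(size=(3, 10))
        with pytest.warns(UserWarning, match="reduced"):
            emb = mg.embed_pca(X, n_components=9)
        assert emb.shape == (10, 3)


class TestSNN:
    def test_two_separated_blobs_two_communities(self):
        rng = np.random.default_rng(3)
        pts = _gaussian_blobs(rng, [np.zeros(3), np.full(3, 20.0)], 60)
        labels = mg.cluster_snn(pts, k_neighbors=15, resolution=0.3, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:60])) == 1
        assert len(np.unique(labels[60:])) == 1

    def test_permutation_invariance_up_to_renaming(self):
        rng = np.random.default_rng(4)
        pts = _gaussian_blobs(rng, [np.zeros(2), np.full(2, 25.0), [25.0, -25.0]], 40)
        labels = mg.cluster_snn(pts, k_neighbors=10, seed=0)
        perm = rng.permutation(len(pts))
        labels_perm = mg.cluster_snn(pts[perm], k_neighbors=10, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_single_tight_cluster_one_community(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(40, 3)) * 0.01
        labels = mg.cluster_snn(pts, k_neighbors=15, resolution=0.3, seed=0)
        assert len(np.unique(labels)) == 1

    def test_partition_covers_all_points(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(100, 4))
        labels = mg.cluster_snn(pts, k_neighbors=10, seed=0)
        assert len(labels) == 100
        assert np.all(np.bincount(labels) > 0)  # no empty clusters

    def test_k_clipped_with_warning(self):
        pts = np.random.default_rng(7).normal(size=(8, 2))
        with pytest.warns(UserWarning, match="clipped"):
            mg.cluster_snn(pts, k_neighbors=50, seed=0)


class TestSubcluster:
    def _study_with_split_cluster(self, split=True):
        """Planted parent cluster (spots 0-59) with an optional subpopulation."""
        rng = np.random.default_rng(8)
        n_genes, n = 40, 180
        counts = rng.poisson(5, size=(n_genes, n))
        counts[:8, :60] += 40  # parent cluster A (spots 0-59)
        if split:
            counts[8:16, 30:60] += 30  # subpopulation inside A
        counts[16:24, 60:] += 40  # the rest of the tissue
        sample = mg.SpatialSample(
            "s1", "EAE", counts,
            np.array([f"g{i}" for i in range(n_genes)], dtype=object),
            np.array([f"b{i}" for i in range(n)], dtype=object),
            np.column_stack([np.arange(n) * 10.0, np.zeros(n)]),
        )
        assignment = mg.ClusterAssignment(
            table=pd.DataFrame(
                {
                    "sample_id": "s1",
                    "spot_id": sample.spot_ids,
                    "cluster": [1] * 60 + [0] * 120,
                    "subcluster": [None] * n,
                }
            )
        )
        return sample, assignment

    def test_planted_subpopulations_recovered_with_prefix(self):
        sample, assignment = self._study_with_split_cluster()
        sub = mg.subcluster([sample], assignment, 1, n_pcs=5, k_neighbors=10, seed=0)
        got = sub.table.iloc[:60]["subcluster"]
        assert got.str.startswith("1_").all()  # parent prefix contract
        assert got.nunique() == 2  # both planted subpopulations found
        # subcluster labels line up with the planted split
        assert got.iloc[:30].nunique() == 1 and got.iloc[30:].nunique() == 1
        assert got.iloc[0] != got.iloc[30]
        # untouched spots keep no subcluster label
        assert sub.table.iloc[60:]["subcluster"].isna().all()

    def test_homogeneous_parent_single_subcluster(self):
        sample, assignment = self._study_with_split_cluster(split=False)
        sub = mg.subcluster([sample], assignment, 1, n_pcs=5, k_neighbors=10, seed=0)
        assert sub.table.iloc[:60]["subcluster"].nunique() == 1

    def test_empty_parent_rejected(self):
        sample, assignment = self._study_with_split_cluster()
        with pytest.raises(ValueError, match="empty"):
            mg.subcluster([sample], assignment, 999)


class TestMarkers:
    def _toy_matrix(self):
        rng = np.random.default_rng(9)
        X = rng.normal(2, 0.5, size=(6, 10))
        X[0, :5] += 5.0  # perfectly separated gene in cluster 0
        X[1, :] = 1.0  # constant gene
        labels = np.array([0] * 5 + [1] * 5)
        genes = np.array([f"g{i}" for i in range(6)], dtype=object)
        return X, genes, labels

    def test_perfect_separation_exact_wilcoxon_p(self):
        X, genes, labels = self._toy_matrix()
        res = mg.marker_genes(X, genes, labels, target=0, lfc_min=0.1)
        p0 = res.set_index("gene").loc["g0", "p"]
        assert p0 == pytest.approx(2 / 252, rel=1e-12)  # exact enumeration: 2/C(10,5)

    def test_constant_gene_null(self):
        X, genes, labels = self._toy_matrix()
        res = mg.marker_genes(X, genes, labels, target=0).set_index("gene")
        assert res.loc["g1", "p"] == 1.0
        assert res.loc["g1", "log2FC"] == 0.0

    def test_bh_monotone_in_raw_p(self):
        X, genes, labels = self._toy_matrix()
        res = mg.marker_genes(X, genes, labels, target=0).sort_values("p")
        assert (np.diff(res["p_adj"]) >= -1e-12).all()

    def test_degenerate_group_sizes_rejected(self):
        X, genes, _ = self._toy_matrix()
        with pytest.raises(ValueError):
            mg.marker_genes(X, genes, np.array([0] + [1] * 9), target=0)


class TestGroupTest:
    def test_closed_form_t(self):
        t, p = mg.students_t([10, 12, 11], [20, 22, 21])
        # pooled-variance closed form: t = -10 / sqrt(1 * 2/3)
        assert t == pytest.approx(-12.24744871391589, abs=1e-10)
        assert p == pytest.approx(0.0002552167494419268, rel=1e-9)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 5)
        t, p = mg.students_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_groups_null(self):
        t, p = mg.students_t([5, 5, 5], [5, 5, 5])
        assert (t, p) == (0.0, 1.0)

    def test_cluster_group_test_counts_and_proportions(self):
        table = pd.DataFrame(
            {
                "sample_id": ["e1"] * 10 + ["e2"] * 10 + ["n1"] * 10 + ["n2"] * 10,
                "spot_id": [f"s{i}" for i in range(40)],
                "cluster": [1] * 6 + [0] * 4 + [1] * 5 + [0] * 5 + [0] * 10 + [1] * 1 + [0] * 9,
                "subcluster": [None] * 40,
            }
        )
        assignment = mg.ClusterAssignment(table=table)
        groups = {"e1": "EAE", "e2": "EAE", "n1": "naive", "n2": "naive"}
        t, p, per_sample = mg.cluster_group_test(assignment, groups, cluster=1, mode="count")
        vals = per_sample.set_index("sample_id")["value"]
        assert list(vals[["e1", "e2", "n1", "n2"]]) == [6, 5, 0, 1]
        t2, _ = mg.students_t([6, 5], [0, 1])
        assert t == pytest.approx(t2)
        _, _, prop = mg.cluster_group_test(assignment, groups, cluster=1, mode="proportion")
        assert prop.set_index("sample_id")["value"]["e1"] == pytest.approx(0.6)


class TestPseudobulkDE:
    def _two_group_samples(self, fold=4.0, n_per=4, n_genes=50, seed=0, lib_boost=None):
        # n_genes affected genes on top of a majority of unchanged genes,
        # so median-of-ratios size factors anchor on the background
        progs = [
            mg.GeneProgram(f"g{i}", 8.0, fold - 1.0, "flat", group_specific=True)
            for i in range(n_genes)
        ] + [mg.GeneProgram(f"bg{i}", 8.0) for i in range(3 * n_genes)]
        cfg = mg.SimConfig(
            n_naive=n_per, n_eae=n_per, lattice_rows=8, lattice_cols=8,
            focus_radius_um=150.0, programs=progs, library_size_sigma=0.2,
        )
        samples = mg.simulate_study(cfg, seed=seed)
        if lib_boost is not None:
            s = samples[lib_boost]
            samples[lib_boost] = mg.SpatialSample(
                s.sample_id, s.group, s.counts * 10, s.gene_ids, s.spot_ids, s.spot_xy_um
            )
        return samples

    def test_null_centered_on_zero(self):
        samples = self._two_group_samples(fold=1.0, seed=3)
        res = mg.pseudobulk_de(samples)
        assert abs(res["log2FC"].mean()) < 0.1

    def test_four_fold_effect_recovered(self):
        samples = self._two_group_samples(fold=4.0, seed=4)
        res = mg.pseudobulk_de(samples)
        affected = res[~res["gene"].str.startswith("bg")]
        assert affected["log2FC"].mean() == pytest.approx(2.0, abs=0.3)

    def test_size_factor_invariance(self):
        base = mg.pseudobulk_de(self._two_group_samples(fold=4.0, seed=5))
        boosted = mg.pseudobulk_de(self._two_group_samples(fold=4.0, seed=5, lib_boost=0))
        diff = (base["log2FC"] - boosted["log2FC"]).abs().max()
        assert diff < 0.05

    def test_all_zero_gene_excluded(self):
        samples = self._two_group_samples(fold=1.0, seed=6)
        for s in samples:
            s.counts[7, :] = 0
        res = mg.pseudobulk_de(samples)
        row = res[res["gene"] == "g7"].iloc[0]
        assert row["excluded"] and np.isnan(row["p"])
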