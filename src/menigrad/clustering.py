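"""Dimensionality reduction, SNN community detection and group statistics.

The clustering pipeline mirrors the standard spot-transcriptomics
toolchain: log-normalized expression is reduced to its first 10
principal components, a shared-nearest-neighbour (SNN) graph is built on
the embedding (k-nearest neighbours, Jaccard overlap of neighbour sets,
weak edges pruned), and communities are found by modularity (Leiden)
optimization at resolution 0.3.  Subclustering reruns the same pipeline
on the spots of one parent cluster and labels the result
"parent_child" (e.g. "1_3").

Downstream statistics:

* marker genes — two-sided Wilcoxon rank-sum per gene (target cluster vs
  rest) with Benjamini-Hochberg adjustment;
* cluster group enrichment — per-sample spot count (or proportion) in a
  cluster compared between groups with a pooled-variance two-tailed
  Student's t-test; `find_focal_cluster` returns the cluster most
  significantly enriched in the EAE-like group, the operational
  definition of the meningeal-inflammation cluster;
* pseudobulk differential expression — counts summed per sample so
  biological replicates are the units, then a per-gene two-group
  negative-binomial Wald test with median-of-ratios size factors and
  method-of-moments dispersion (deliberately without dispersion
  shrinkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .preprocess import SpatialSample, normalize_log

__all__ = [
    "ClusterAssignment",
    "embed_pca",
    "cluster_snn",
    "cluster_study",
    "subcluster",
    "marker_genes",
    "students_t",
    "cluster_group_test",
    "find_focal_cluster",
    "pseudobulk_de",
    "merge_normalized",
]

SNN_PRUNE = 1 / 15  # drop SNN edges with Jaccard below this (standard toolchain default)


@dataclass
class ClusterAssignment:
    """Spot-to-cluster table with provenance.

    ``table`` columns: sample_id, spot_id, cluster (int) and subcluster
    (string "parent_child", NaN where not subclustered).
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def labels_for(self, sample: SpatialSample) -> np.ndarray:
        """Cluster labels aligned to ``sample.spot_ids``."""
        sub = self.table[self.table["sample_id"] == sample.sample_id].set_index("spot_id")
        return sub.loc[sample.spot_ids, "cluster"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def merge_normalized(samples: list[SpatialSample], target_sum: float = 1e4):
    """Concatenate normalized matrices across samples.

    Normalizes any sample lacking a normalized matrix.  All samples must
    share the same gene panel.  Returns ``(X, obs)`` with X genes x
    all-spots and obs a DataFrame (sample_id, spot_id, group) aligned to
    the columns of X.
    """
    if not samples:
        raise ValueError("no samples given")
    genes = samples[0].gene_ids
    for s in samples:
        if not np.array_equal(s.gene_ids, genes):
            raise ValueError("samples must share an identical gene panel")
        if s.normalized is None:
            normalize_log(s, target_sum)
    X = np.concatenate([s.normalized for s in samples], axis=1)
    obs = pd.concat(
        [
            pd.DataFrame({"sample_id": s.sample_id, "spot_id": s.spot_ids, "group": s.group})
            for s in samples
        ],
        ignore_index=True,
    )
    return X, obs


def embed_pca(normalized: np.ndarray, n_components: int = 10) -> np.ndarray:
    """Principal-component embedding of spots.

    ``normalized`` is genes x spots; the returned embedding is spots x
    components.  Components are orthonormal with non-increasing
    explained variance; the sign of each component is fixed (largest-
    magnitude loading positive) so the embedding is deterministic.
    """
    X = np.asarray(normalized, float).T  # spots x genes
    max_comp = min(X.shape)
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds min(matrix dims)={max_comp}; reduced",
            stacklevel=2,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    signs = np.sign(pca.components_[np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)])
    signs[signs == 0] = 1.0
    return emb * signs[None, :]


def _snn_graph(embedding: np.ndarray, k_neighbors: int) -> igraph.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = len(embedding)
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    # neighbour sets include the point itself
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    cols = np.concatenate([idx, np.arange(n)[:, None]], axis=1).ravel()
    A = scipy.sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    shared = (A @ A.T).tocoo()
    size = k_neighbors + 1
    jacc = shared.data / (2 * size - shared.data)
    keep = (shared.row < shared.col) & (jacc >= SNN_PRUNE)
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jacc[keep]
    return g


def cluster_snn(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """SNN graph construction plus Leiden community detection.

    k-nearest-neighbour graph on the embedding, shared-neighbour Jaccard
    edge weights (weak edges pruned), then Leiden modularity
    optimization at the given resolution.  Labels are integers ordered
    by decreasing community size, so the partition is stable under
    permutation of the input rows (up to renaming).
    """
    embedding = np.asarray(embedding, float)
    n = len(embedding)
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    if k_neighbors >= n:
        warnings.warn(f"k_neighbors={k_neighbors} >= n={n}; clipped to {n - 1}", stacklevel=2)
        k_neighbors = n - 1
    g = _snn_graph(embedding, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    raw = np.array(part.membership)
    order = np.argsort([-np.sum(raw == c) for c in range(raw.max() + 1)], kind="stable")
    relabel = np.empty(raw.max() + 1, dtype=int)
    relabel[order] = np.arange(len(order))
    return relabel[raw]


def cluster_study(
    samples: list[SpatialSample],
    n_pcs: int = 10,
    k_neighbors: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
    target_sum: float = 1e4,
) -> ClusterAssignment:
    """Full clustering pipeline over a merged multi-sample study."""
    X, obs = merge_normalized(samples, target_sum)
    emb = embed_pca(X, n_pcs)
    labels = cluster_snn(emb, k_neighbors, resolution, seed)
    table = obs.assign(cluster=labels, subcluster=pd.array([None] * len(obs), dtype=object))
    return ClusterAssignment(
        table=table[["sample_id", "spot_id", "cluster", "subcluster"]],
        provenance={
            "n_pcs": n_pcs,
            "k_neighbors": k_neighbors,
            "resolution": resolution,
            "seed": seed,
        },
    )


def subcluster(
    samples: list[SpatialSample],
    assignment: ClusterAssignment,
    parent_cluster: int,
    n_pcs: int = 10,
    k_neighbors: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
) -> ClusterAssignment:
    """Re-cluster the spots of one parent cluster.

    The embed/cluster pipeline is rerun on the subset; resulting labels
    are written into the ``subcluster`` column as "parent_child".
    Components and k are reduced automatically when the subset is small.
    """
    X, obs = merge_normalized(samples)
    mask = (assignment.table["cluster"] == parent_cluster).to_numpy()
    if not mask.any():
        raise ValueError(f"parent cluster {parent_cluster!r} is empty")
    sub_X = X[:, mask]
    labels = cluster_snn(embed_pca(sub_X, n_pcs), k_neighbors, resolution, seed)
    table = assignment.table.copy()
    table.loc[mask, "subcluster"] = [f"{parent_cluster}_{c}" for c in labels]
    prov = dict(assignment.provenance)
    prov[f"subcluster_{parent_cluster}"] = {"resolution": resolution, "seed": seed}
    return ClusterAssignment(table=table, provenance=prov)


def marker_genes(
    normalized: np.ndarray,
    gene_ids: np.ndarray,
    labels: np.ndarray,
    target,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Cluster-enriched genes by two-sided Wilcoxon rank-sum tests.

    Each gene is tested target-cluster spots vs all other spots
    (exact p for small groups without ties, normal approximation
    otherwise); p-values are BH-adjusted across genes.  log2FC is
    computed from group means on the de-logged normalized scale with
    pseudocount 1.  Rows are flagged significant when p_adj < alpha and
    |log2FC| > lfc_min.
    """
    labels = np.asarray(labels)
    in_target = labels == target
    if not in_target.any():
        raise ValueError(f"target cluster {target!r} not present")
    n1, n2 = int(in_target.sum()), int((~in_target).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 spots per side, got {n1} vs {n2}")
    X = np.asarray(normalized, float)
    rows = []
    for gi, gene in enumerate(gene_ids):
        x, y = X[gi, in_target], X[gi, ~in_target]
        mean_t = np.expm1(x).mean()
        mean_r = np.expm1(y).mean()
        lfc = float(np.log2((mean_t + 1.0) / (mean_r + 1.0)))
        if np.ptp(X[gi]) == 0:  # constant gene: no information
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)
        rows.append({"gene": gene, "log2FC": lfc, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["p_adj"] < alpha) & (out["log2FC"].abs() > lfc_min)
    return out.sort_values("p").reset_index(drop=True)


def students_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample two-tailed Student's t-test with pooled variance.

    Zero variance in both groups with equal means gives t=0, p=1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0:
        return (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p)


def cluster_group_test(
    assignment: ClusterAssignment,
    sample_groups: dict,
    cluster,
    mode: str = "count",
) -> tuple[float, float, pd.DataFrame]:
    """Group enrichment of one cluster on per-sample spot tallies.

    Every sample in ``sample_groups`` contributes one value — its spot
    count in the cluster (``mode="count"``) or the proportion of its
    spots in the cluster (``mode="proportion"``); samples without any
    spot in the cluster contribute 0.  EAE-like samples are compared to
    the rest with a pooled-variance two-tailed Student's t-test.
    Returns (t, p, per-sample table); positive t means enrichment in
    the EAE-like group.
    """
    if mode not in ("count", "proportion"):
        raise ValueError("mode must be 'count' or 'proportion'")
    tab = assignment.table
    rows = []
    for sid, grp in sample_groups.items():
        sample_tab = tab[tab["sample_id"] == sid]
        n_in = int((sample_tab["cluster"] == cluster).sum())
        value = n_in if mode == "count" else n_in / max(len(sample_tab), 1)
        rows.append({"sample_id": sid, "group": grp, "value": value})
    per_sample = pd.DataFrame(rows)
    eae = per_sample[per_sample["group"] == "EAE"]["value"].to_numpy()
    rest = per_sample[per_sample["group"] != "EAE"]["value"].to_numpy()
    t, p = students_t(eae, rest)
    return t, p, per_sample


def find_focal_cluster(assignment: ClusterAssignment, sample_groups: dict, mode: str = "count"):
    """Operational focal-cluster identification.

    The focal (meningeal-inflammation-like) cluster is the one with the
    most significant EAE-enrichment (smallest cluster_group_test p among
    clusters whose EAE mean exceeds the naive mean).
    """
    best, best_p = None, np.inf
    for c in sorted(assignment.table["cluster"].unique()):
        t, p, _ = cluster_group_test(assignment, sample_groups, c, mode)
        if t > 0 and p < best_p:
            best, best_p = c, p
    if best is None:
        raise ValueError("no cluster is enriched in the EAE-like group")
    return best


def pseudobulk_de(
    samples: list[SpatialSample],
    groups: dict | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB differential expression on pseudobulked samples.

    Counts are summed per gene per sample, size factors are estimated by
    median-of-ratios, per-gene dispersion by pooled within-group method
    of moments, and the log fold change (EAE-like over the other group)
    is tested with a Wald z on the normalized group means.  Genes with
    zero counts in every sample are excluded from testing and flagged.
    """
    if groups is None:
        groups = {s.sample_id: s.group for s in samples}
    labels = np.array([groups[s.sample_id] for s in samples])
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    # EAE-like group (if present) is the numerator of the fold change
    g2 = "EAE" if "EAE" in uniq else uniq[1]
    g1 = [u for u in uniq if u != g2][0]
    if (labels == g1).sum() < 2 or (labels == g2).sum() < 2:
        raise ValueError("need >= 2 replicates per group")
    pb = np.stack([s.counts.sum(axis=1) for s in samples], axis=1).astype(float)  # genes x samples
    gene_ids = samples[0].gene_ids
    nonzero = pb.sum(axis=1) > 0

    # median-of-ratios size factors over genes expressed in every sample
    ref_ok = np.all(pb > 0, axis=1)
    if not ref_ok.any():
        raise ValueError("no gene expressed in all samples; cannot estimate size factors")
    log_ref = np.log(pb[ref_ok]).mean(axis=1)
    sf = np.exp(np.median(np.log(pb[ref_ok]) - log_ref[:, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    q = pb / sf[None, :]

    m1_mask, m2_mask = labels == g1, labels == g2
    n1, n2 = m1_mask.sum(), m2_mask.sum()
    m1 = q[:, m1_mask].mean(axis=1)
    m2 = q[:, m2_mask].mean(axis=1)
    v1 = q[:, m1_mask].var(axis=1, ddof=1)
    v2 = q[:, m2_mask].var(axis=1, ddof=1)
    mu_pool = (m1 * n1 + m2 * n2) / (n1 + n2)
    v_pool = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.clip((v_pool - mu_pool) / mu_pool**2, 0.0, None)
    alpha = np.nan_to_num(alpha)

    lfc_ln = np.log(m2 + pseudocount) - np.log(m1 + pseudocount)
    var_ln = (m1 + alpha * m1**2) / (n1 * (m1 + pseudocount) ** 2) + (
        m2 + alpha * m2**2
    ) / (n2 * (m2 + pseudocount) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc_ln / np.sqrt(var_ln)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(var_ln == 0, 1.0, p)

    out = pd.DataFrame(
        {
            "gene": gene_ids,
            "log2FC": lfc_ln / np.log(2),
            "p": p,
            "excluded": ~nonzero,
        }
    )
    out.loc[~nonzero, ["log2FC", "p"]] = np.nan
    padj = np.full(len(out), np.nan)
    padj[nonzero] = multipletests(out.loc[nonzero, "p"], method="fdr_bh")[1]
    out["p_adj"] = padj
    return out
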