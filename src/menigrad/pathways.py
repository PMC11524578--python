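"""Footprint pathway activity, group FDR testing and gene-set statistics.

Pathway activity per spot follows the footprint idea: a pathway is
represented not by its members but by the genes that respond downstream
of it, each carrying a signed weight.  Given a pathway x gene weight
matrix, the score of pathway p in spot s is the weight-weighted sum of
the per-gene z-scores over the top-``n`` weighted genes measured in the
data (default 500), finally z-scaled per pathway across spots.

Group comparison treats samples — not spots — as replicates: activity is
averaged per sample, compared between groups with Student's t-tests and
corrected with the Benjamini-Krieger-Yekutieli two-stage linear step-up
FDR.  Over-representation analysis (ORA) of a query gene list against a
GMT gene-set collection uses the hypergeometric upper tail with BH
adjustment; sets are filtered to sizes 10-500 after intersection with
the measured universe.  A simple per-spot gene-set score (mean of member
z-scores) supports trajectory screening of gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import students_t

__all__ = [
    "PathwayWeights",
    "GeneSetCollection",
    "EnrichmentResult",
    "footprint_activity",
    "activity_group_compare",
    "bky_twostage",
    "bh_adjust",
    "ora",
    "spot_set_score",
    "read_gmt",
    "write_gmt",
]


@dataclass
class PathwayWeights:
    """Signed pathway x gene weight matrix with provenance."""

    matrix: pd.DataFrame  # pathways x genes
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValueError("gene identifiers must be unique")
        if (self.matrix.fillna(0) == 0).all(axis=1).any():
            bad = self.matrix.index[(self.matrix.fillna(0) == 0).all(axis=1)]
            raise ValueError(f"pathways with no nonzero weight: {list(bad)}")

    @classmethod
    def from_long(cls, table: pd.DataFrame, provenance: str = "") -> "PathwayWeights":
        """Build from a long (pathway, gene, weight) table."""
        mat = table.pivot_table(index="pathway", columns="gene", values="weight", fill_value=0.0)
        return cls(matrix=mat, provenance=provenance)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PathwayWeights":
        return cls.from_long(pd.read_csv(path, sep="\t"), provenance=str(path))

    def to_tsv(self, path: str | Path) -> None:
        long = self.matrix.stack().rename("weight").reset_index()
        long.columns = ["pathway", "gene", "weight"]
        long[long["weight"] != 0].to_csv(path, sep="\t", index=False)


@dataclass
class GeneSetCollection:
    """Mapping of set name to deduplicated gene list."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        self.sets = {name: list(dict.fromkeys(genes)) for name, genes in self.sets.items()}


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    p_adj: float
    enrichment_ratio: float


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file."""
    from gseapy.parser import read_gmt as _read_gmt

    return GeneSetCollection(sets=_read_gmt(str(path)), source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a gene-set collection in GMT format."""
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


def _zscore_genes(normalized: np.ndarray) -> np.ndarray:
    """Per-gene z-score across spots; constant genes map to 0."""
    X = np.asarray(normalized, float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def footprint_activity(
    normalized: np.ndarray,
    gene_ids: np.ndarray,
    weights: PathwayWeights,
    top_n: int = 500,
    scale: bool = True,
) -> pd.DataFrame:
    """Per-spot footprint pathway activity scores.

    For each pathway the ``top_n`` genes by absolute weight that are
    measured in the data are selected; per-gene expression is z-scored
    across spots; the pathway score of a spot is the weighted sum of
    those z-scores.  With ``scale=True`` (default) scores are z-scaled
    per pathway across spots.  Pathways with no measured gene are
    dropped with a warning.

    Returns a pathway x spot DataFrame.
    """
    import warnings

    gene_ids = np.asarray(gene_ids, dtype=object)
    Z = _zscore_genes(normalized)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    scores = {}
    for pathway, w in weights.matrix.iterrows():
        w = w[w != 0]
        present = w.index[[g in gene_pos for g in w.index]]
        if len(present) == 0:
            warnings.warn(f"pathway {pathway!r} has no measured genes; dropped", stacklevel=2)
            continue
        w = w[present]
        top = w.reindex(w.abs().sort_values(ascending=False, kind="stable").index[:top_n])
        rows = [gene_pos[g] for g in top.index]
        s = top.to_numpy() @ Z[rows]
        if scale:
            sd = s.std()
            s = (s - s.mean()) / (sd if sd > 0 else 1.0)
        scores[pathway] = s
    if not scores:
        raise ValueError("no pathway had any measured gene")
    return pd.DataFrame(scores).T


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def bky_twostage(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Krieger-Yekutieli two-stage linear step-up rejections.

    Stage 1 runs BH at q' = q / (1 + q) and estimates the number of true
    nulls m0 = m - r1; stage 2 reruns BH at q * m / m0.  If stage 1
    rejects everything, everything is flagged significant.  Returns a
    boolean rejection mask.
    """
    p = np.asarray(p, float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    if q <= 0:
        return np.zeros(m, dtype=bool)
    qprime = q / (1.0 + q)
    stage1 = _bh_reject(p, qprime)
    r1 = int(stage1.sum())
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool)
    return _bh_reject(p, q * m / m0)


def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Linear step-up (BH) rejection mask at level q."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = q * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


def activity_group_compare(
    scores: pd.DataFrame,
    spot_samples: np.ndarray,
    sample_groups: dict,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-pathway group comparison of activity with two-stage FDR.

    Activity is first averaged per sample (samples are the replicates),
    then each pathway's per-sample means are compared between the
    EAE-like group and the rest with a pooled-variance t-test; the
    resulting p-values are corrected with the BKY two-stage step-up at
    level ``q``.

    Parameters
    ----------
    scores
        Pathway x spot score matrix (from :func:`footprint_activity`).
    spot_samples
        Sample id of each spot (aligned to score columns).
    sample_groups
        Mapping sample id -> group label.
    """
    spot_samples = np.asarray(spot_samples)
    sample_ids = list(dict.fromkeys(spot_samples))
    per_sample = pd.DataFrame(
        {sid: scores.loc[:, spot_samples == sid].mean(axis=1) for sid in sample_ids}
    )
    grp = np.array([sample_groups[sid] for sid in sample_ids])
    eae = grp == "EAE"
    if eae.sum() < 2 or (~eae).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for pathway in per_sample.index:
        a = per_sample.loc[pathway, eae].to_numpy(float)
        b = per_sample.loc[pathway, ~eae].to_numpy(float)
        t, p = students_t(a, b)
        rows.append(
            {"pathway": pathway, "mean_diff": a.mean() - b.mean(), "t": t, "p": p}
        )
    out = pd.DataFrame(rows).set_index("pathway")
    out["significant"] = bky_twostage(out["p"].to_numpy(), q)
    return out


def ora(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation analysis.

    Sets are intersected with the universe and filtered to sizes in
    [min_size, max_size]; the upper-tail hypergeometric p of the overlap
    with the query is BH-adjusted across the retained sets.
    """
    if len(query) == 0:
        raise ValueError("empty query gene list")
    uni = set(universe)
    offenders = [g for g in query if g not in uni]
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders[:10]}")
    qset = set(query)
    N, n = len(uni), len(qset)
    retained = []
    for name, genes in sets.sets.items():
        members = set(genes) & uni
        if not (min_size <= len(members) <= max_size):
            continue
        k = len(members & qset)
        p = float(stats.hypergeom.sf(k - 1, N, len(members), n))
        expected = len(members) * n / N
        retained.append((name, k, len(members), p, k / expected if expected > 0 else np.nan))
    if not retained:
        return []
    padj = bh_adjust([r[3] for r in retained])
    return [
        EnrichmentResult(
            set_name=name,
            overlap=k,
            set_size=size,
            query_size=n,
            universe_size=N,
            p=p,
            p_adj=float(pa),
            enrichment_ratio=float(ratio),
        )
        for (name, k, size, p, ratio), pa in zip(retained, padj)
    ]


def spot_set_score(normalized: np.ndarray, gene_ids: np.ndarray, gene_set: list[str]) -> np.ndarray:
    """Per-spot gene-set score: mean of member-gene z-scores.

    Duplicate members are collapsed; raises if no member gene is
    measured.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    members = list(dict.fromkeys(gene_set))
    pos = {g: i for i, g in enumerate(gene_ids)}
    rows = [pos[g] for g in members if g in pos]
    if not rows:
        raise ValueError("no gene of the set is measured in the data")
    Z = _zscore_genes(normalized)
    return Z[rows].mean(axis=0)
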