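"""Reading, quality control and normalization of Visium-style spot data.

A tissue section is held as a :class:`SpatialSample`: an integer gene x spot
count matrix, spot barcodes, spot centre coordinates in micrometres, and a
group label (``naive`` or ``EAE``).  The on-disk layout mirrors the
SpaceRanger convention at desk scale: a Matrix Market counts file,
features/barcodes TSVs, a tissue-positions CSV and a small YAML metadata
file.

Spot-level QC drops spots with fewer than 250 detected genes or fewer than
500 total UMIs (either criterion failing removes the spot).  Counts are
normalized by library size to a common target sum and log1p-transformed;
the normalization is isolated behind one function so an alternative
variance-stabilizing transform can be plugged in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "SpatialSample",
    "FormatError",
    "read_visium_like",
    "write_visium_like",
    "qc_filter",
    "normalize_log",
]

POSITIONS_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "x_um", "y_um"]


class FormatError(ValueError):
    """Raised when on-disk sample files are malformed or inconsistent."""


@dataclass
class SpatialSample:
    """One tissue section: counts, spot geometry and group label.

    Parameters
    ----------
    sample_id
        Unique section identifier.
    group
        Experimental group, ``"naive"`` or ``"EAE"``.
    counts
        Integer count matrix, genes x spots.
    gene_ids, spot_ids
        Row / column identifiers; spot barcodes must be unique.
    spot_xy_um
        Spot centre coordinates in micrometres, image convention
        (origin top-left, y increasing downward), shape (n_spots, 2).
    normalized
        Optional normalized matrix (same shape as ``counts``).
    spot_meta
        Optional per-spot metadata (e.g. generative region labels);
        indexed like ``spot_ids``.
    """

    sample_id: str
    group: str
    counts: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    spot_xy_um: np.ndarray
    normalized: np.ndarray | None = None
    spot_meta: pd.DataFrame | None = None
    qc_report: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.spot_xy_um = np.asarray(self.spot_xy_um, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x spots matrix")
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} rows")
        if len(self.spot_ids) != n_spots:
            raise ValueError(f"{len(self.spot_ids)} spot ids for {n_spots} columns")
        if self.spot_xy_um.shape != (n_spots, 2):
            raise ValueError("spot_xy_um must have shape (n_spots, 2)")
        if not np.all(np.isfinite(self.spot_xy_um)):
            raise ValueError("spot coordinates must be finite")
        if len(set(self.spot_ids)) != n_spots:
            raise ValueError("spot barcodes must be unique within a sample")
        if np.any(self.counts < 0) or not np.all(self.counts == np.floor(self.counts)):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def genes_per_spot(self) -> np.ndarray:
        """Number of genes with at least one count, per spot."""
        return (self.counts > 0).sum(axis=0)

    def umi_per_spot(self) -> np.ndarray:
        """Total UMI count per spot."""
        return self.counts.sum(axis=0)

    def subset_spots(self, mask: np.ndarray) -> "SpatialSample":
        """Return a copy restricted to the spots selected by ``mask``."""
        mask = np.asarray(mask)
        return replace(
            self,
            counts=self.counts[:, mask],
            spot_ids=self.spot_ids[mask],
            spot_xy_um=self.spot_xy_um[mask],
            normalized=None if self.normalized is None else self.normalized[:, mask],
            spot_meta=None if self.spot_meta is None else self.spot_meta.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask].reset_index(drop=True),
            qc_report=None,
        )


def write_visium_like(sample: SpatialSample, path: str | Path, in_tissue: np.ndarray | None = None) -> Path:
    """Write ``sample`` in the SpaceRanger-like on-disk layout.

    Creates ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv``,
    ``tissue_positions.csv`` and ``meta.yaml`` under ``path``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.csc_matrix(sample.counts.astype(int)))
    pd.Series(sample.gene_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(sample.spot_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    if in_tissue is None:
        in_tissue = np.ones(sample.n_spots, dtype=int)
    pos = pd.DataFrame(
        {
            "barcode": sample.spot_ids,
            "in_tissue": np.asarray(in_tissue, dtype=int),
            "array_row": 0,
            "array_col": np.arange(sample.n_spots),
            "x_um": sample.spot_xy_um[:, 0],
            "y_um": sample.spot_xy_um[:, 1],
        }
    )
    if sample.spot_meta is not None:
        for col in ("array_row", "array_col"):
            if col in sample.spot_meta:
                pos[col] = sample.spot_meta[col].to_numpy()
    pos.to_csv(path / "tissue_positions.csv", index=False)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump({"sample_id": sample.sample_id, "group": sample.group}, fh)
    if sample.spot_meta is not None:
        sample.spot_meta.to_csv(path / "spot_meta.csv", index=False)
    return path


def read_visium_like(path: str | Path, filter_in_tissue: bool = True) -> SpatialSample:
    """Read a sample from the SpaceRanger-like layout written by
    :func:`write_visium_like`.

    Matrix columns are aligned to the barcode and position files; barcodes
    flagged not-in-tissue are dropped when ``filter_in_tissue`` is set.

    Raises
    ------
    FormatError
        If a barcode in the matrix is missing from the positions file, if
        dimensions disagree, or a positions row is malformed.
    """
    path = Path(path)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv", "tissue_positions.csv"):
        if not (path / fname).exists():
            raise FormatError(f"missing required file {fname} in {path}")
    counts = np.asarray(scipy.io.mmread(path / "matrix.mtx").todense())
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {counts.shape} but features/barcodes imply ({len(genes)}, {len(barcodes)})"
        )
    pos = pd.read_csv(path / "tissue_positions.csv")
    missing_cols = set(POSITIONS_COLUMNS) - set(pos.columns)
    if missing_cols:
        raise FormatError(f"tissue_positions.csv missing columns {sorted(missing_cols)}")
    for i, row in pos.iterrows():
        if pd.isna(row["x_um"]) or pd.isna(row["y_um"]) or pd.isna(row["barcode"]):
            raise FormatError(f"malformed tissue_positions.csv row {i}: {row.to_dict()}")
    pos = pos.set_index("barcode")
    absent = [b for b in barcodes if b not in pos.index]
    if absent:
        raise FormatError(f"barcodes missing from tissue_positions.csv: {absent[:5]}")
    pos = pos.loc[barcodes]

    meta = {"sample_id": path.name, "group": "naive"}
    if (path / "meta.yaml").exists():
        with open(path / "meta.yaml") as fh:
            meta.update(yaml.safe_load(fh))
    spot_meta = None
    if (path / "spot_meta.csv").exists():
        spot_meta = pd.read_csv(path / "spot_meta.csv")

    keep = np.ones(len(barcodes), dtype=bool)
    if filter_in_tissue:
        keep = pos["in_tissue"].to_numpy().astype(bool)
    sample = SpatialSample(
        sample_id=str(meta["sample_id"]),
        group=str(meta["group"]),
        counts=counts[:, keep],
        gene_ids=genes,
        spot_ids=barcodes[keep],
        spot_xy_um=pos[["x_um", "y_um"]].to_numpy()[keep],
        spot_meta=None if spot_meta is None else spot_meta.loc[keep].reset_index(drop=True),
    )
    return sample


def qc_filter(sample: SpatialSample, min_genes: int = 250, min_umi: int = 500) -> SpatialSample:
    """Drop spots failing either QC criterion.

    A spot is removed when it has fewer than ``min_genes`` detected genes
    OR fewer than ``min_umi`` total UMIs.  The gene set is unchanged.  The
    returned sample carries a per-spot ``qc_report`` DataFrame with the
    tallies and the pass/fail flags.  Idempotent: filtering a filtered
    sample changes nothing.
    """
    genes = sample.genes_per_spot()
    umis = sample.umi_per_spot()
    pass_genes = genes >= min_genes
    pass_umi = umis >= min_umi
    keep = pass_genes & pass_umi
    report = pd.DataFrame(
        {
            "spot_id": sample.spot_ids,
            "n_genes": genes,
            "n_umi": umis,
            "pass_genes": pass_genes,
            "pass_umi": pass_umi,
            "retained": keep,
        }
    )
    if not keep.any():
        warnings.warn(
            f"qc_filter removed all {sample.n_spots} spots of {sample.sample_id}; "
            "check min_genes/min_umi against the data",
            stacklevel=2,
        )
    out = sample.subset_spots(keep)
    out.qc_report = report
    return out


def normalize_log(sample: SpatialSample, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalize and log-transform the counts.

    Each spot's counts are scaled to a common total ``target_sum`` and
    log1p-transformed: ``x_gs = ln(1 + c_gs * target_sum / total_s)``.
    Zeros map to zero and within-spot gene ranks are preserved.  The
    result is stored on ``sample.normalized`` and returned.

    Raises
    ------
    ValueError
        If any retained spot has zero total counts (run :func:`qc_filter`
        first).
    """
    totals = sample.umi_per_spot().astype(float)
    if np.any(totals <= 0):
        bad = sample.spot_ids[totals <= 0]
        raise ValueError(
            f"spots with zero total counts: {list(bad[:5])}; apply qc_filter before normalize_log"
        )
    norm = np.log1p(sample.counts * (target_sum / totals)[None, :])
    sample.normalized = norm
    return norm
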