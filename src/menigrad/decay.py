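"""Distance statistics and power-law decay regression.

Two related analyses live here.  First, nearest-point distance
statistics between spot subclusters and the focal inflammatory cluster:
for each sample the distance from a subcluster's spot centroid to the
nearest focal-cluster spot is computed and compared between subcluster
groups with a two-tailed Student's t-test.  Second, smFISH-style
quantification: marker-positive/negative cells at known coordinates are
binned by their shortest distance to the lesion region at 50 µm
intervals, and the percent-positive fraction per bin is fit by nonlinear
least squares to the power law

    percent = a * x^b

with x the bin midpoint distance (µm).  The exponent b quantifies how
fast the signal decays away from the lesion (more negative = steeper,
i.e. shallower penetration).  The fit is initialized from an ordinary
least-squares line on (ln x, ln percent) over positive bins — exact on
noiseless power-law data — and refined on all usable bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from shapely.geometry import Point, Polygon

from .preprocess import SpatialSample

__all__ = [
    "CellField",
    "DecayFit",
    "nearest_distance",
    "subcluster_distance_test",
    "bin_cells",
    "fit_power_decay",
    "read_cell_field",
    "write_cell_field",
]


@dataclass
class CellField:
    """Point pattern of marker+/- cells with a lesion region.

    ``cells`` columns: x_um, y_um, marker, positive, sample_id.
    ``lesion`` is either a shapely Polygon or an (n, 2) array of points
    (µm); distance to a polygon is 0 for cells inside it.
    """

    cells: pd.DataFrame
    lesion: Polygon | np.ndarray

    def __post_init__(self) -> None:
        required = {"x_um", "y_um", "marker", "positive", "sample_id"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.cells[["x_um", "y_um"]].to_numpy(dtype=float))):
            raise ValueError("cell coordinates must be finite")
        if isinstance(self.lesion, Polygon):
            if self.lesion.is_empty:
                raise ValueError("lesion region must be non-empty")
        else:
            self.lesion = np.atleast_2d(np.asarray(self.lesion, float))
            if self.lesion.size == 0:
                raise ValueError("lesion region must be non-empty")


@dataclass
class DecayFit:
    """Power-law fit percent = a * x^b with diagnostics."""

    a: float
    b: float
    se_a: float
    se_b: float
    rss: float
    n_bins: int
    converged: bool


def nearest_distance(point, region) -> float:
    """Shortest Euclidean distance (µm) from a point to a region.

    The region is a point set (n, 2) or a shapely Polygon; a point
    inside a polygon has distance 0.
    """
    p = np.asarray(point, float).ravel()
    if isinstance(region, Polygon):
        if region.is_empty:
            raise ValueError("empty lesion region")
        return float(Point(p).distance(region))
    region = np.atleast_2d(np.asarray(region, float))
    if region.size == 0:
        raise ValueError("empty region point set")
    return float(np.min(np.hypot(region[:, 0] - p[0], region[:, 1] - p[1])))


def subcluster_distance_test(
    samples: list[SpatialSample],
    assignment: pd.DataFrame,
    subclusters_a: list,
    subclusters_b: list,
    focal_cluster,
) -> tuple[float, float, pd.DataFrame]:
    """Per-sample subcluster-to-focus distances and a two-sample t-test.

    For every sample containing the focal cluster, the Euclidean
    distance from each subcluster's spot centroid to the nearest focal
    spot is computed.  Distances of group-A subclusters are compared to
    group-B subclusters with a pooled-variance two-tailed t-test.
    Samples lacking the focal cluster are excluded and reported in the
    returned table with ``excluded=True``.

    ``assignment`` needs columns sample_id, spot_id, cluster and (for
    subcluster rows) subcluster.
    """
    rows = []
    for s in samples:
        sub = assignment[assignment["sample_id"] == s.sample_id]
        focal = sub[sub["cluster"] == focal_cluster]
        has_focal = len(focal) > 0
        spot_index = {b: i for i, b in enumerate(s.spot_ids)}
        focal_xy = s.spot_xy_um[[spot_index[b] for b in focal["spot_id"]]] if has_focal else None
        for grp_name, members in (("A", subclusters_a), ("B", subclusters_b)):
            for sc in members:
                spots = sub[sub["subcluster"] == sc]["spot_id"]
                if len(spots) == 0:
                    continue
                if not has_focal:
                    rows.append(
                        {"sample_id": s.sample_id, "subcluster": sc, "group": grp_name,
                         "distance_um": np.nan, "excluded": True}
                    )
                    continue
                centroid = s.spot_xy_um[[spot_index[b] for b in spots]].mean(axis=0)
                rows.append(
                    {"sample_id": s.sample_id, "subcluster": sc, "group": grp_name,
                     "distance_um": nearest_distance(centroid, focal_xy), "excluded": False}
                )
    table = pd.DataFrame(rows)
    used = table[~table["excluded"]]
    da = used[used["group"] == "A"]["distance_um"].to_numpy()
    db = used[used["group"] == "B"]["distance_um"].to_numpy()
    from .clustering import students_t  # closed-form pooled-variance t

    if len(da) < 2 or len(db) < 2:  # too few usable distances for a test
        return float("nan"), float("nan"), table
    t, p = students_t(da, db)
    return t, p, table


def bin_cells(field: CellField, bin_width_um: float = 50.0) -> pd.DataFrame:
    """Bin cells by shortest distance to the lesion region.

    Half-open bins [k*w, (k+1)*w): a cell at exactly 50.0 µm falls in
    the second 50 µm bin.  Returns one row per non-empty bin with
    columns bin_midpoint_um, n_cells, n_positive, percent_positive.
    Cell counts are conserved exactly; an empty field yields an empty
    table.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    if len(field.cells) == 0:
        return pd.DataFrame(columns=["bin_midpoint_um", "n_cells", "n_positive", "percent_positive"])
    xy = field.cells[["x_um", "y_um"]].to_numpy()
    d = np.array([nearest_distance(p, field.lesion) for p in xy])
    which = np.floor(d / bin_width_um).astype(int)
    out = []
    for k in np.unique(which):
        sel = which == k
        n = int(sel.sum())
        npos = int(field.cells["positive"].to_numpy()[sel].sum())
        out.append(
            {
                "bin_midpoint_um": (k + 0.5) * bin_width_um,
                "n_cells": n,
                "n_positive": npos,
                "percent_positive": 100.0 * npos / n,
            }
        )
    return pd.DataFrame(out)


def fit_power_decay(binned: pd.DataFrame, xtol: float = 1e-8, max_iter: int = 200) -> DecayFit:
    """Fit percent = a * x^b to a binned distance table.

    Nonlinear least squares over all bins with cells and midpoint > 0,
    initialized from OLS on (ln x, ln percent) over the bins with
    percent > 0 (zero-percent bins re-enter the NLS objective).  On
    noiseless power-law data the initializer is already the solution.

    Raises
    ------
    ValueError
        On fewer than 3 usable bins, or if every percentage is zero.
    """
    usable = binned[(binned["n_cells"] > 0) & (binned["bin_midpoint_um"] > 0)]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 non-empty bins with positive midpoints, got {len(usable)}")
    x = usable["bin_midpoint_um"].to_numpy(float)
    y = usable["percent_positive"].to_numpy(float)
    pos = y > 0
    if not pos.any():
        raise ValueError("all percentages are zero; no decay to fit")
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
        a0, b0 = float(np.exp(intercept)), float(slope)
    else:
        a0, b0 = float(y[pos][0]), -1.0

    def resid(theta):
        a, b = theta
        return a * x**b - y

    sol = optimize.least_squares(
        resid, x0=[a0, b0], xtol=xtol, ftol=xtol, gtol=1e-12, max_nfev=max_iter * 2, method="lm"
    )
    a_hat, b_hat = sol.x
    rss = float(np.sum(sol.fun**2))
    dof = max(len(x) - 2, 1)
    # standard errors from the Jacobian at the solution
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
        se_a, se_b = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_a = se_b = np.nan
    return DecayFit(
        a=float(a_hat),
        b=float(b_hat),
        se_a=float(se_a),
        se_b=float(se_b),
        rss=rss,
        n_bins=len(x),
        converged=bool(sol.status > 0 and sol.nfev <= max_iter * 2),
    )


def write_cell_field(field: CellField, cells_path, lesion_path=None) -> None:
    """Write a cell field as CSV (and the lesion polygon vertices as CSV)."""
    field.cells.to_csv(cells_path, index=False)
    if lesion_path is not None:
        if isinstance(field.lesion, Polygon):
            xs, ys = field.lesion.exterior.xy
            verts = np.column_stack([xs, ys])[:-1]
        else:
            verts = field.lesion
        pd.DataFrame(verts, columns=["x_um", "y_um"]).to_csv(lesion_path, index=False)


def read_cell_field(cells_path, lesion_path=None, lesion_as_polygon: bool = True) -> CellField:
    """Read a cell field written by :func:`write_cell_field`."""
    cells = pd.read_csv(cells_path)
    if lesion_path is None:
        lesion = np.zeros((1, 2))
    else:
        verts = pd.read_csv(lesion_path)[["x_um", "y_um"]].to_numpy()
        lesion = Polygon(verts) if lesion_as_polygon and len(verts) >= 3 else verts
    return CellField(cells=cells, lesion=lesion)
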