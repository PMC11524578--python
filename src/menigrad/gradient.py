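"""Trajectory profiling and ideal-pattern residual-AUC screening.

A straight trajectory is drawn from the focal inflammatory cluster into
the parenchyma (in the motivating experiments: from the largest region of
meningeal inflammation toward the thalamus).  Spots inside a rectangular
corridor around the trajectory axis are projected onto it, expression is
binned along the normalized coordinate t in [0, 1], min-max scaled, and
compared to ideal pattern curves.  The area under the absolute residual
curve ("residual AUC") is inversely proportional to fit: 0 means the
scaled profile equals the ideal pattern, larger values mean worse fit.

Pattern families
----------------
``gradient_descending``      1 - t          (linear decline)
``logarithmic_descending``   1 - ln(1+9t)/ln 10   (fast early decline,
                             losing half its range by t ~ 0.24)
``gradient_ascending``, ``logarithmic_ascending``: mirrored (1 - descending).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .preprocess import SpatialSample

__all__ = [
    "Trajectory",
    "TrajectoryProfile",
    "PATTERN_NAMES",
    "ideal_pattern",
    "make_trajectory",
    "project_spots",
    "bin_profile",
    "residual_auc",
    "screen_patterns",
]

#: Fixed pattern order; also the tie-break order for best-fit assignment
#: (gradient before logarithmic, descending before ascending).
PATTERN_NAMES = (
    "gradient_descending",
    "logarithmic_descending",
    "gradient_ascending",
    "logarithmic_ascending",
)


@dataclass(frozen=True)
class Trajectory:
    """Straight corridor from ``origin_xy`` to ``terminus_xy`` (µm)."""

    origin_xy: tuple[float, float]
    terminus_xy: tuple[float, float]
    corridor_width_um: float

    def __post_init__(self) -> None:
        if self.corridor_width_um <= 0:
            raise ValueError("corridor_width_um must be positive")
        if self.length_um <= 0:
            raise ValueError("trajectory must have positive length")

    @property
    def length_um(self) -> float:
        o = np.asarray(self.origin_xy, float)
        t = np.asarray(self.terminus_xy, float)
        return float(np.linalg.norm(t - o))


@dataclass
class TrajectoryProfile:
    """Binned, [0,1]-scaled expression along a trajectory.

    ``t`` holds the bin midpoints (strictly increasing, in [0,1]),
    ``values`` the scaled per-bin means, ``spots_per_bin`` the number of
    projected spots per bin.  ``degenerate`` is set when the raw values
    were constant, in which case the profile is the constant 0.5.
    """

    t: np.ndarray
    values: np.ndarray
    spots_per_bin: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.values = np.asarray(self.values, float)
        self.spots_per_bin = np.asarray(self.spots_per_bin, int)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("bin midpoints must be strictly increasing")
        if np.any((self.values < -1e-12) | (self.values > 1 + 1e-12)):
            raise ValueError("profile values must lie in [0, 1]")


def ideal_pattern(name: str, t: np.ndarray | float) -> np.ndarray:
    """Evaluate an ideal pattern curve at trajectory coordinate ``t``.

    Descending patterns satisfy f(0)=1, f(1)=0 and are strictly
    decreasing; ascending variants are 1 minus the descending curve.
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < -1e-12) | (t > 1 + 1e-12)):
        raise ValueError("t must lie in [0, 1]")
    if name == "gradient_descending":
        return 1.0 - t
    if name == "logarithmic_descending":
        return 1.0 - np.log1p(9.0 * t) / np.log(10.0)
    if name == "gradient_ascending":
        return np.asarray(t, dtype=float)
    if name == "logarithmic_ascending":
        return np.log1p(9.0 * t) / np.log(10.0)
    raise ValueError(f"unknown ideal pattern {name!r}; choose from {PATTERN_NAMES}")


def _largest_component(xy: np.ndarray) -> np.ndarray:
    """Indices of the largest connected component of a spot set.

    Spots are adjacent when within 1.3x the median nearest-neighbour
    spacing, which links hexagonal first neighbours but not second ones.
    """
    n = len(xy)
    if n == 1:
        return np.array([0])
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    spacing = np.median(d.min(axis=1))
    adj = scipy.sparse.csr_matrix(d <= 1.3 * spacing)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    return np.flatnonzero(labels == np.argmax(sizes))


def make_trajectory(
    sample: SpatialSample,
    cluster_labels: np.ndarray,
    from_cluster,
    to_cluster,
    width_um: float,
) -> Trajectory:
    """Draw a trajectory between two clusters of one sample.

    The origin is the centroid of the largest connected component of the
    ``from_cluster`` spots (ties broken by first occurrence); the terminus
    is the centroid of all ``to_cluster`` spots.
    """
    cluster_labels = np.asarray(cluster_labels)
    for c in (from_cluster, to_cluster):
        if not np.any(cluster_labels == c):
            raise ValueError(f"cluster {c!r} absent from sample {sample.sample_id}")
    src = sample.spot_xy_um[cluster_labels == from_cluster]
    comp = _largest_component(src)
    origin = src[comp].mean(axis=0)
    terminus = sample.spot_xy_um[cluster_labels == to_cluster].mean(axis=0)
    return Trajectory(tuple(origin), tuple(terminus), width_um)


def project_spots(sample: SpatialSample, traj: Trajectory) -> pd.DataFrame:
    """Project spots onto the trajectory axis.

    Returns a table with columns ``spot_id``, ``index`` (column index into
    the sample), ``t`` (scalar projection divided by trajectory length)
    and ``offset_um`` (signed perpendicular distance).  Spots are retained
    iff 0 <= t <= 1 and |offset| <= corridor_width/2.
    """
    o = np.asarray(traj.origin_xy, float)
    e = np.asarray(traj.terminus_xy, float)
    axis = (e - o) / traj.length_um
    normal = np.array([-axis[1], axis[0]])
    rel = sample.spot_xy_um - o
    t = rel @ axis / traj.length_um
    offset = rel @ normal
    eps = 1e-9  # tolerate rounding at the corridor boundary (isometry invariance)
    keep = (t >= -eps) & (t <= 1 + eps) & (np.abs(offset) <= traj.corridor_width_um / 2 + eps)
    t = np.clip(t, 0.0, 1.0)
    if not keep.any():
        raise ValueError("no spots fall inside the trajectory corridor")
    idx = np.flatnonzero(keep)
    return pd.DataFrame(
        {"spot_id": sample.spot_ids[idx], "index": idx, "t": t[idx], "offset_um": offset[idx]}
    )


def bin_profile(
    values: np.ndarray,
    ts: np.ndarray,
    n_bins: int = 20,
    smooth_window: int = 3,
) -> TrajectoryProfile:
    """Bin values along t, smooth, and min-max scale to [0, 1].

    Equal-width bins on [0, 1]; per-bin mean; empty interior bins are
    linearly interpolated (leading/trailing empty bins take the nearest
    observed value); a centred moving average of width ``smooth_window``
    is applied, with the window shrunk symmetrically at the profile ends
    so that exactly linear profiles pass through unchanged; the result
    is min-max scaled.  Constant input sets the ``degenerate`` flag and
    yields the constant profile 0.5.
    """
    values = np.asarray(values, float)
    ts = np.asarray(ts, float)
    if len(values) != len(ts) or len(values) == 0:
        raise ValueError("values and ts must be equal-length and non-empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    which = np.clip(np.digitize(ts, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    filled = counts > 0
    if not filled.all():
        means = np.interp(mids, mids[filled], means[filled])
    if smooth_window > 1:
        half = smooth_window // 2
        smoothed = np.empty_like(means)
        for i in range(n_bins):
            w = min(half, i, n_bins - 1 - i)
            smoothed[i] = means[i - w : i + w + 1].mean()
        means = smoothed
    lo, hi = means.min(), means.max()
    if hi - lo < 1e-12:
        return TrajectoryProfile(mids, np.full(n_bins, 0.5), counts, degenerate=True)
    scaled = (means - lo) / (hi - lo)
    return TrajectoryProfile(mids, scaled, counts, degenerate=False)


def residual_auc(profile: TrajectoryProfile, pattern: str) -> float:
    """Area under the absolute residual curve between profile and pattern.

    The profile is treated as piecewise linear through its bin midpoints
    and the endpoints t=0 and t=1 (endpoint values linearly extrapolated
    from the two nearest bins and clipped to [0, 1]).  The integral of
    |profile(t) - pattern(t)| over [0, 1] is computed by the trapezoid
    rule on a grid refined between the profile nodes, so that the folds
    of the absolute value inside a segment are resolved.  Zero iff the
    profile equals the pattern at every evaluation point.
    """
    t, vals = profile.t, profile.values
    if t[0] > 0:
        v0 = vals[0] + (vals[1] - vals[0]) / (t[1] - t[0]) * (0.0 - t[0]) if len(t) > 1 else vals[0]
        t = np.concatenate([[0.0], t])
        vals = np.concatenate([[np.clip(v0, 0.0, 1.0)], vals])
    if t[-1] < 1:
        v1 = (
            vals[-1] + (vals[-1] - vals[-2]) / (t[-1] - t[-2]) * (1.0 - t[-1])
            if len(t) > 1
            else vals[-1]
        )
        t = np.concatenate([t, [1.0]])
        vals = np.concatenate([vals, [np.clip(v1, 0.0, 1.0)]])
    # refine between nodes; the profile is linear there, the pattern is not
    fine = np.unique(np.concatenate([t, np.linspace(0.0, 1.0, 16 * (len(t) - 1) + 1)]))
    resid = np.abs(np.interp(fine, t, vals) - ideal_pattern(pattern, fine))
    return float(np.trapezoid(resid, fine))


def screen_patterns(
    feature_values: pd.DataFrame,
    ts: np.ndarray,
    patterns: tuple[str, ...] = PATTERN_NAMES,
    n_bins: int = 20,
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Residual-AUC screen of features against ideal patterns.

    Parameters
    ----------
    feature_values
        Per-spot scores, one column per feature (gene expression or
        gene-set scores), rows aligned with ``ts``.
    ts
        Trajectory coordinate of each spot (from :func:`project_spots`).
    patterns
        Pattern names to score; the given order is the argmin tie-break
        order.

    Returns
    -------
    DataFrame with one row per feature: a residual-AUC column per
    pattern, ``best_pattern`` (argmin residual AUC, ties broken by
    pattern order) and ``degenerate``.
    """
    if feature_values.shape[1] == 0:
        raise ValueError("no features supplied")
    rows = []
    for name in feature_values.columns:
        prof = bin_profile(feature_values[name].to_numpy(), ts, n_bins, smooth_window)
        aucs = {p: residual_auc(prof, p) for p in patterns}
        best = min(patterns, key=lambda p: (aucs[p], patterns.index(p)))
        rows.append({"feature": name, **aucs, "best_pattern": best, "degenerate": prof.degenerate})
    out = pd.DataFrame(rows).set_index("feature")
    return out
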