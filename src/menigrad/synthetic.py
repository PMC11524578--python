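"""Synthetic spot-lattice studies and cell fields.

Generates data with the statistical structure the downstream analyses
assume, so every pipeline stage is testable without downloads:

* a hexagonal Visium-like spot lattice (~100 µm pitch, ~55 µm spots);
* a two-group study (naive vs EAE) in which only EAE-like samples carry a
  contiguous inflammation focus;
* gene programs whose negative-binomial mean either (a) decays with
  distance from the focus boundary under a chosen pattern family, or
  (b) marks a discrete tissue region (focus disc / adjacent band /
  distal parenchyma) with a flat elevation — emulating the sharp
  anatomical cluster boundaries of real sections;
* point-pattern cell fields whose percent-positive fraction follows
  y = a * x^b versus distance from a disc-shaped lesion.

Counts are negative binomial parameterized by mean mu and dispersion
alpha with variance mu + alpha * mu^2 (gamma-Poisson mixture).  Per-spot
library-size factors are drawn log-normally and applied multiplicatively
so that normalization is exercised; the factors are recorded in the
output.  All randomness flows from a single integer seed: identical
config + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point

from .decay import CellField
from .gradient import ideal_pattern
from .preprocess import SpatialSample, write_visium_like

__all__ = [
    "GeneProgram",
    "SimConfig",
    "build_lattice",
    "simulate_study",
    "simulate_cell_field",
    "simulate_trajectory_features",
    "default_programs",
    "write_study",
]

DECAY_PATTERNS = (
    "flat",
    "linear_descending",
    "logarithmic_descending",
    "linear_ascending",
    "logarithmic_ascending",
)
REGIONS = ("focus", "band", "distal")

#: Map generator pattern names onto the trajectory ideal-pattern curves
#: (single source of truth for the profile shapes).
_PATTERN_TO_IDEAL = {
    "linear_descending": "gradient_descending",
    "logarithmic_descending": "logarithmic_descending",
    "linear_ascending": "gradient_ascending",
    "logarithmic_ascending": "logarithmic_ascending",
}


@dataclass(frozen=True)
class GeneProgram:
    """One gene's generating model.

    The NB mean at boundary distance d is
    ``baseline_mean * (1 + focus_amplitude * g(min(d, L) / L))`` where g
    is the decay pattern's profile (descending: g(0)=1, g(1)=0; ascending
    mirrored; flat: g = 1 everywhere).  ``group_specific`` programs are
    elevated only in EAE-like samples; naive-like samples stay at
    baseline.  If ``region`` is set the program instead marks that
    discrete region: mean = baseline * (1 + A) inside it, baseline
    elsewhere (the decay pattern is ignored).
    """

    name: str
    baseline_mean: float = 5.0
    focus_amplitude: float = 0.0
    decay_pattern: str = "flat"
    decay_length_um: float = 800.0
    group_specific: bool = False
    dispersion: float = 0.3
    region: str | None = None

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.focus_amplitude < 0:
            raise ValueError("focus_amplitude must be >= 0")
        if self.decay_length_um <= 0:
            raise ValueError("decay_length_um must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.decay_pattern not in DECAY_PATTERNS:
            raise ValueError(f"decay_pattern must be one of {DECAY_PATTERNS}")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS} or None")


def default_programs() -> list[GeneProgram]:
    """Default gene panel for the study generator.

    Eight flat marker genes per discrete region (focus markers are
    EAE-specific: naive meninges carry no inflammatory programme), eight
    EAE-specific decay programs (four linear, four logarithmic), and
    sixty background genes with baselines log-spaced over a realistic
    per-spot count range.
    """
    programs: list[GeneProgram] = []
    for i in range(8):
        programs.append(GeneProgram(f"focus_marker_{i}", 5.0, 9.0, "flat", group_specific=True, region="focus"))
        programs.append(GeneProgram(f"band_marker_{i}", 5.0, 4.0, "flat", region="band"))
        programs.append(GeneProgram(f"distal_marker_{i}", 5.0, 4.0, "flat", region="distal"))
    for i in range(4):
        programs.append(
            GeneProgram(f"grad_linear_{i}", 5.0, 2.0, "linear_descending", 800.0, group_specific=True)
        )
        programs.append(
            GeneProgram(f"grad_log_{i}", 5.0, 2.0, "logarithmic_descending", 800.0, group_specific=True)
        )
    baselines = np.geomspace(1.0, 40.0, 60)
    for i, b in enumerate(baselines):
        programs.append(GeneProgram(f"background_{i}", float(b)))
    return programs


@dataclass
class SimConfig:
    """Study-generator configuration.

    Defaults mirror the motivating study design at desk scale: five
    naive and six EAE sections, a 100 µm pitch hexagonal lattice of
    55 µm spots, and a sub-pial inflammation focus at the top tissue
    edge whose spots make up a few percent of the section.
    """

    n_naive: int = 5
    n_eae: int = 6
    lattice_rows: int = 20
    lattice_cols: int = 20
    pitch_um: float = 100.0
    spot_diameter_um: float = 55.0
    focus_center_xy: tuple[float, float] | None = None
    focus_radius_um: float = 250.0
    band_width_um: float = 300.0
    programs: list[GeneProgram] = field(default_factory=default_programs)
    library_size_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch_um <= self.spot_diameter_um or self.spot_diameter_um <= 0:
            raise ValueError("need pitch_um > spot_diameter_um > 0")
        if self.lattice_rows < 1 or self.lattice_cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if not self.programs:
            raise ValueError("program list must not be empty")
        if self.focus_center_xy is None:
            # sub-pial default: mid-top edge of the tissue
            self.focus_center_xy = ((self.lattice_cols - 1) * self.pitch_um / 2, 0.0)
        lat = build_lattice(self.lattice_rows, self.lattice_cols, self.pitch_um)
        fx, fy = self.focus_center_xy
        if not (
            lat.x_um.min() - self.pitch_um <= fx <= lat.x_um.max() + self.pitch_um
            and lat.y_um.min() - self.pitch_um <= fy <= lat.y_um.max() + self.pitch_um
        ):
            raise ValueError("focus center lies outside the lattice bounds")
        d = np.hypot(lat.x_um - fx, lat.y_um - fy)
        if not np.any(d <= self.focus_radius_um):
            raise ValueError("focus contains no lattice spots")


def build_lattice(rows: int, cols: int, pitch_um: float) -> pd.DataFrame:
    """Hexagonal Visium-like spot lattice.

    Spots sit on ``rows`` x ``cols`` grid positions; odd rows are offset
    by half a pitch in x and consecutive rows are pitch * sqrt(3)/2
    apart in y, giving equidistant first neighbours.

    Returns a table with columns array_row, array_col, x_um, y_um.
    """
    if rows < 1 or cols < 1 or pitch_um <= 0:
        raise ValueError("rows, cols must be >= 1 and pitch_um > 0")
    r, c = np.mgrid[0:rows, 0:cols]
    r, c = r.ravel(), c.ravel()
    x = c * pitch_um + (r % 2) * pitch_um / 2
    y = r * pitch_um * np.sqrt(3) / 2
    return pd.DataFrame({"array_row": r, "array_col": c, "x_um": x, "y_um": y})


def _pattern_profile(pattern: str, d: np.ndarray, length_um: float) -> np.ndarray:
    """Profile value g at boundary distance d for a decay pattern."""
    if pattern == "flat":
        return np.ones_like(d, dtype=float)
    t = np.minimum(d, length_um) / length_um
    return ideal_pattern(_PATTERN_TO_IDEAL[pattern], t)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) counts, variance mu + alpha*mu^2 (gamma-Poisson)."""
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * np.asarray(mu, float))
    return rng.poisson(lam)


def program_means(
    program: GeneProgram, d: np.ndarray, region: np.ndarray, is_eae: bool, band_width_um: float
) -> np.ndarray:
    """Generating NB mean of one program over spots at boundary distance d."""
    base = np.full(len(d), program.baseline_mean, dtype=float)
    if program.group_specific and not is_eae:
        return base
    if program.region is not None:
        active = region == program.region
        return base * np.where(active, 1.0 + program.focus_amplitude, 1.0)
    g = _pattern_profile(program.decay_pattern, np.asarray(d, float), program.decay_length_um)
    return base * (1.0 + program.focus_amplitude * g)


def simulate_study(config: SimConfig, seed: int | None = None) -> list[SpatialSample]:
    """Simulate a two-group spot study.

    EAE-like samples contain a contiguous focus (all spots within
    ``focus_radius_um`` of the focus centre); boundary distance d is 0
    inside the focus.  Per-spot log-normal library-size factors are
    applied multiplicatively and recorded in ``spot_meta`` together with
    the geometric region, the generative expression class and d.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lat = build_lattice(config.lattice_rows, config.lattice_cols, config.pitch_um)
    xy = lat[["x_um", "y_um"]].to_numpy()
    fx, fy = config.focus_center_xy
    d = np.maximum(0.0, np.hypot(xy[:, 0] - fx, xy[:, 1] - fy) - config.focus_radius_um)
    region = np.where(d == 0, "focus", np.where(d <= config.band_width_um, "band", "distal"))

    gene_ids = np.array([p.name for p in config.programs], dtype=object)
    samples: list[SpatialSample] = []
    groups = ["naive"] * config.n_naive + ["EAE"] * config.n_eae
    counters = {"naive": 0, "EAE": 0}
    for grp in groups:
        counters[grp] += 1
        sid = f"{grp.lower()}_{counters[grp]}"
        is_eae = grp == "EAE"
        lib = np.exp(rng.normal(0.0, config.library_size_sigma, size=len(xy)))
        counts = np.empty((len(config.programs), len(xy)), dtype=int)
        for gi, prog in enumerate(config.programs):
            mu = program_means(prog, d, region, is_eae, config.band_width_um) * lib
            counts[gi] = _nb_sample(rng, mu, prog.dispersion)
        expr_class = region.copy()
        if not is_eae:
            # no inflammatory programme in naive meninges: focus-disc spots
            # carry only background expression
            expr_class = np.where(region == "focus", "background", region)
        meta = pd.DataFrame(
            {
                "array_row": lat.array_row,
                "array_col": lat.array_col,
                "region": region,
                "expr_class": expr_class,
                "boundary_distance_um": d,
                "library_factor": lib,
            }
        )
        samples.append(
            SpatialSample(
                sample_id=sid,
                group=grp,
                counts=counts,
                gene_ids=gene_ids,
                spot_ids=np.array([f"{sid}_s{i:04d}" for i in range(len(xy))], dtype=object),
                spot_xy_um=xy.copy(),
                spot_meta=meta,
            )
        )
    return samples


def simulate_cell_field(
    a: float,
    b: float,
    bin_width_um: float = 50.0,
    n_bins: int = 10,
    cells_per_bin: int = 50,
    seed: int = 0,
    lesion_radius_um: float = 150.0,
    sample_id: str = "field_1",
    marker: str = "gene",
) -> CellField:
    """Point-pattern cell field with power-law percent-positive decay.

    For bin k with midpoint x_k = (k + 0.5) * bin_width, the number of
    positive cells is Binomial(cells_per_bin, clamp(a * x_k^b / 100,
    0, 1)).  Cells are placed uniformly (by area) inside their bin's
    annulus around a disc-shaped lesion of radius ``lesion_radius_um``
    centred at the origin, with a 1 µm guard so sampled distances cannot
    straddle a bin edge.
    """
    if a < 0:
        raise ValueError("amplitude a must be >= 0")
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    if cells_per_bin < 1 or n_bins < 1:
        raise ValueError("need cells_per_bin >= 1 and n_bins >= 1")
    rng = np.random.default_rng(seed)
    margin = min(1.0, bin_width_um / 4)
    rows = []
    for k in range(n_bins):
        x_mid = (k + 0.5) * bin_width_um
        p = 0.0 if a == 0 else float(np.clip(a * x_mid**b / 100.0, 0.0, 1.0))
        n_pos = rng.binomial(cells_per_bin, p)
        lo = lesion_radius_um + k * bin_width_um + margin
        hi = lesion_radius_um + (k + 1) * bin_width_um - margin
        radii = np.sqrt(rng.uniform(lo**2, hi**2, size=cells_per_bin))
        theta = rng.uniform(0, 2 * np.pi, size=cells_per_bin)
        positive = np.zeros(cells_per_bin, dtype=bool)
        positive[rng.choice(cells_per_bin, size=n_pos, replace=False)] = True
        rows.append(
            pd.DataFrame(
                {
                    "x_um": radii * np.cos(theta),
                    "y_um": radii * np.sin(theta),
                    "marker": marker,
                    "positive": positive,
                    "sample_id": sample_id,
                }
            )
        )
    cells = pd.concat(rows, ignore_index=True)
    lesion = Point(0.0, 0.0).buffer(lesion_radius_um, quad_segs=256)
    return CellField(cells=cells, lesion=lesion)


def simulate_trajectory_features(
    ts: np.ndarray,
    pattern: str,
    n_features: int = 1,
    genes_per_feature: int = 10,
    baseline_mean: float = 5.0,
    amplitude: float = 9.0,
    dispersion: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-set features whose mean follows an ideal pattern along t.

    Each feature is a set of ``genes_per_feature`` NB-distributed genes
    sharing the mean profile ``baseline * (1 + amplitude * f(t))`` where
    f is the named ideal pattern; the feature value per spot is the mean
    count over the set (emulating a per-spot gene-set score).  Returns a
    spots x features DataFrame aligned with ``ts``.
    """
    ts = np.asarray(ts, float)
    rng = np.random.default_rng(seed)
    mu = baseline_mean * (1.0 + amplitude * ideal_pattern(pattern, ts))
    data = {}
    for j in range(n_features):
        genes = np.stack(
            [_nb_sample(rng, mu, dispersion) for _ in range(genes_per_feature)]
        )
        data[f"{pattern}_{j}"] = genes.mean(axis=0)
    return pd.DataFrame(data)


def write_study(samples: list[SpatialSample], path: str | Path, config: SimConfig | None = None) -> Path:
    """Write every sample in the on-disk layout `preprocess` reads.

    One sub-directory per sample; the generating config (if given) is
    stored as ``config.yaml`` alongside.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for s in samples:
        write_visium_like(s, path / s.sample_id)
    if config is not None:
        cfg = asdict(config)
        cfg["programs"] = [asdict(p) for p in config.programs]
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
    return path
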