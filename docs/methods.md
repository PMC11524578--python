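# Methods

This note documents the models, numerical choices and limitations behind
`menigrad`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis problem

A two-group spot-transcriptomics study (healthy "naive" vs "EAE"
neuroinflammation) asks three related questions: (i) which spots form the
focal meningeal-inflammation cluster, (ii) which gene programs elevated at
the focus extend into the adjacent parenchyma and with what spatial shape,
and (iii) how fast a marker-positive cell fraction decays with distance
from the lesion. The package answers them with, respectively, SNN/Leiden
clustering plus a group-enrichment test, trajectory ideal-pattern screening
by residual AUC, and distance-binned power-law regression.

## Preprocessing

Spots with fewer than 250 detected genes **or** fewer than 500 total UMIs
are removed. The source description of this filter is ambiguous between AND
and OR; OR (drop if either criterion fails) is the standard QC semantics
and is what is implemented, with both flags recorded per spot in the QC
report. Counts are then normalized per spot to a common total
(`target_sum`, default 10⁴) and log1p-transformed:
`x_gs = ln(1 + c_gs · target_sum / total_s)`. This log-CPM-style transform
stands in for heavier variance-stabilizing transforms; it is isolated
behind `normalize_log` so an alternative can be plugged in, because every
downstream step consumes only "a normalized matrix". Coordinates are µm in
image convention (origin top-left, y downward); all distances are
Euclidean in µm.

## Clustering

The embedding is the first 10 principal components of the normalized
matrix (deterministic full-SVD solver; component signs fixed by making the
largest-magnitude loading positive). The SNN graph connects k-nearest
neighbours (k = 20, neighbour sets include the point itself) with Jaccard
edge weights |N(i)∩N(j)| / |N(i)∪N(j)|, pruning edges below 1/15 — the
defaults of the standard single-cell toolchain. Communities are found with
Leiden on the RB-configuration (modularity-with-resolution) objective at
resolution 0.3 and a fixed seed; labels are re-indexed by decreasing
community size so partitions are stable under row permutation up to
renaming. Subclustering reruns PCA + SNN/Leiden on one parent cluster's
spots and emits `parent_child` labels.

Marker genes use two-sided Wilcoxon rank-sum tests (exact for small
tie-free groups, normal approximation otherwise), BH adjustment, and
log2 fold changes on the de-logged normalized scale with pseudocount 1;
constant genes get p = 1 and log2FC = 0.

The **focal cluster** is identified operationally, without anatomical
annotation: for each cluster, per-sample spot counts (samples without any
spot contribute 0; a proportion mode is also exposed, since the published
N=11 t-test does not state whether zero-count samples were included) are
compared between groups with a pooled-variance two-tailed Student's
t-test, and the cluster with the smallest p among EAE-elevated clusters is
the focal one.

Pseudobulk differential expression sums counts per sample so that
biological replicates are the inferential units, normalizes with
median-of-ratios size factors (reference = geometric mean over genes
expressed in all samples, factors rescaled to geometric mean 1), estimates
a per-gene NB dispersion by pooled within-group method of moments
(α = max(0, (s² − μ)/μ²)), and tests ln-fold-change with a Wald z using
the delta-method variance of the group means. Dispersion shrinkage is
deliberately **not** implemented; with few replicates this test is noisier
than a shrinkage estimator and p-values should be read accordingly.

## Pathway and gene-set scoring

Footprint activity treats a pathway as its signed downstream-responsive
gene weights (supplied as data, e.g. a pathway × gene TSV — no weight
database is bundled). Per pathway the top-500 genes by |weight| measured
in the data are selected; the score of spot s is Σ_g w_g·z_g(s) over
per-gene z-scores across spots, finally z-scaled per pathway. This linear
weighted z-sum approximates the original footprint fitting procedure while
preserving the ranking behaviour exercised here.

Group comparisons aggregate spots to per-sample means first — samples, not
spots, are replicates — then run per-pathway t-tests and the
Benjamini–Krieger–Yekutieli two-stage linear step-up: stage 1 is BH at
q′ = q/(1+q), the estimated null count is m₀ = m − r₁, and stage 2 reruns
BH at q·m/m₀ (everything significant if m₀ = 0). The procedure is coded
directly from this definition and verified in the tests against an
independently written step-up oracle; on any fixed p-vector its rejection
set contains the plain-BH set.

Over-representation analysis intersects each gene set with the measured
universe, keeps sets of size 10–500, computes the hypergeometric
upper-tail p of the query overlap and BH-adjusts across retained sets.
Query genes must lie inside the universe. The per-spot gene-set score is
the mean of member-gene z-scores (deduplicated); it is the simplest score
consistent with trajectory heatmaps of "relative expression", and
alternative scorers can be passed wherever a per-spot feature vector is
accepted.

## Trajectory screening

A trajectory runs from the centroid of the largest connected component of
the source cluster (components linked at ≤1.3× the median nearest-
neighbour spacing, which joins hexagonal first neighbours only) to the
centroid of the target cluster, with a rectangular corridor (default
width 2× lattice pitch). Spots project to t = (scalar projection)/length,
kept iff 0 ≤ t ≤ 1 and |perpendicular offset| ≤ width/2, with a 1e-9
tolerance at the boundaries so rigid rotations of the coordinates cannot
drop exact-boundary spots.

Profiles use 20 equal-width bins on [0,1]: per-bin means, linear
interpolation of empty interior bins (edge value for empty end bins), a
centred moving average of window 3 whose window shrinks symmetrically at
the ends (so exactly linear profiles pass unchanged), then min-max
scaling to [0,1]. Constant input is flagged degenerate and represented as
the constant 0.5. Bin count, window and corridor width are exposed as
parameters; the defaults are package choices, not published values.

Ideal patterns are fixed functional forms on [0,1] — the published
analysis names the pattern families but not their equations:
`gradient_descending` f(t) = 1 − t and `logarithmic_descending`
f(t) = 1 − ln(1+9t)/ln 10, with ascending mirrors 1 − f. The logarithmic
curve's parameter makes it lose half its range by t ≈ 0.24, matching the
fast-early decline the pattern is meant to capture; alternative families
can be added by name.

The residual AUC is ∫₀¹|profile(t) − f(t)|dt with the profile treated as
piecewise linear through its bin midpoints (endpoint values linearly
extrapolated from the two nearest bins and clipped to [0,1]). The
integral is a trapezoid rule on a 16×-refined grid between nodes: a
node-only trapezoid can miss the folds of the absolute value inside a
segment by ~0.04 on rough profiles, while the refined rule agrees with
dense quadrature to better than 10⁻³. A side effect is that a profile
sampled from a *curved* pattern at the nodes scores ~7×10⁻⁴ rather than
exactly 0 — the chord-vs-curve gap — which we accept in exchange for
quadrature fidelity. Best-fit assignment is the argmin over patterns,
ties broken by the fixed pattern order (gradient before logarithmic,
descending before ascending).

## Distance decay

Nearest distance supports point-set regions (exhaustive minimum) and
polygon regions (0 inside). Subcluster-to-focus distances are computed per
sample from the subcluster spot centroid to the nearest focal spot;
samples lacking the focal cluster are excluded and reported.

Cell fields are binned by shortest distance to the lesion in half-open
50 µm intervals [k·w, (k+1)·w); a cell at exactly 50 µm falls in the
second bin; empty bins are omitted and counts are conserved exactly. The
fit is unweighted nonlinear least squares of percent = a·xᵇ over the bin
midpoints (25, 75, … µm; x = 0 excluded), Levenberg–Marquardt with
xtol = ftol = 10⁻⁸ and a 400-evaluation cap, initialized from OLS on
(ln x, ln percent) over positive bins — exact on noiseless power-law
data. Zero-percent bins are excluded from the initializer (log undefined)
but included in the NLS objective. Standard errors come from the Jacobian
at the solution. The model is the printed power law y = a·xᵇ, not an
exponential y = a·e^(bx), although the source text calls the procedure
"exponential regression"; per-bin cell counts are available for optional
weighting, and pooling cells across animals before fitting is the default
(per-animal fitting is a caller-side loop).

## Synthetic data

The generator defines the conditions under which the pipeline is
validated; real data differ in ways listed below.

* **Geometry.** Hexagonal lattice at 100 µm pitch with 55 µm spots;
  default 20×20 spots per section — roughly one tenth of a real capture
  area, keeping multi-seed recovery studies fast at identical geometry.
  The inflammation focus is a disc (default radius 250 µm) centred on the
  top tissue edge ("sub-pial"); its spots are ~4% of a section, inside
  the 1–5% range reported for the real focal cluster. The study has 5
  naive and 6 EAE sections, matching the published design.
* **Counts.** Negative binomial with variance μ + αμ² via a
  gamma–Poisson mixture, α = 0.3 by default (typical spot-level
  overdispersion), baselines 1–40 counts/spot, and per-spot log-normal
  library-size factors (σ = 0.35) recorded in the output so
  normalization is genuinely exercised.
* **Programs.** Distance-decay programs have mean
  baseline·(1 + A·g(min(d, L)/L)) with d the distance from the focus
  boundary (0 inside) and g the chosen pattern's profile — the *same*
  `ideal_pattern` curves used by the screening module, so recovery tests
  have a known oracle. `group_specific` programs stay at baseline in
  naive samples. Because real clusters are anatomical regions with sharp
  boundaries, and a monotone decay alone cannot produce separable
  clusters, programs may instead mark a discrete region (focus disc /
  adjacent 300 µm band / distal rest) with a flat elevation; focus
  markers are EAE-specific (naive meninges carry no inflammatory
  programme), so the generative expression class of naive focus-disc
  spots is "background". The default panel: 8 markers per region (focus
  A = 9, band/distal A = 4), 8 EAE-specific decay programs (4 linear +
  4 logarithmic, A = 2, L = 800 µm), 60 background genes.
* **Cell fields.** Bin k around a disc lesion (radius 150 µm) receives
  a fixed number of cells placed uniformly by area in its annulus (1 µm
  guard at the edges so sampled distances cannot straddle a bin), with
  Binomial(cells, clamp(a·x_kᵇ/100, 0, 1)) positives at the bin
  midpoint x_k. Recovery studies use 10 bins × 50 cells × 3 fields,
  i.e. 1,500 cells per replicate — the scale of a multi-section smFISH
  quantification.
* **Trajectory features.** `simulate_trajectory_features` parameterizes
  gene-set features directly in the trajectory coordinate t (10 NB genes
  per feature, averaged), rather than through the boundary-distance
  field, because near the trajectory origin the perpendicular corridor
  offset would otherwise dominate d and confound the planted shape.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: cell-type mixtures within spots,
spatially correlated technical noise, slide/batch effects, irregular
tissue boundaries and anatomy-dependent count depth, gene–gene
correlation beyond shared programs, and segmentation error in cell
coordinates.

## Determinism

Every stochastic step takes an explicit integer seed (generator, Leiden);
PCA uses a deterministic solver with a fixed sign convention. Identical
config + seed reproduces byte-identical synthetic data.

## Known limitations

* The pseudobulk NB test has no dispersion shrinkage and is anti-
  conservative for genes with poorly estimated dispersion at n ≈ 4 + 4.
* ORA is implemented (query = marker genes vs universe), not ranked GSEA;
  the published gene-set analysis may have used either mode.
* Trajectories are single straight segments; curved or multi-segment
  paths and atlas-registered termini are out of scope.
* The focal-cluster rule (most significant EAE enrichment) assumes one
  dominant inflammation cluster; multiple foci of similar strength would
  need manual review.
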