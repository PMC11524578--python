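# menigrad

**Penetration gradients of meningeal inflammation in spatial transcriptomics.**

In autoimmune neuroinflammation (EAE, a mouse model of multiple sclerosis),
aggregates of immune cells form in the leptomeninges — the membranes overlying
the brain — and inflammatory signals from these foci reach into the adjacent
parenchyma to varying depths. `menigrad` is a reusable, tested pipeline for
quantifying this "penetration" from Visium-style spot data (55 µm spots on a
~100 µm hexagonal lattice) in a two-group design (naive vs EAE):

1. **Preprocess** — read SpaceRanger-like output (MTX counts + barcodes /
   features TSV + tissue positions CSV), drop spots with <250 detected genes
   or <500 UMIs, log-normalize.
2. **Cluster** — PCA (10 components) → shared-nearest-neighbour graph →
   Leiden communities at resolution 0.3; subclustering with `parent_child`
   labels; Wilcoxon marker genes; the *focal cluster* (the
   meningeal-inflammation cluster) is identified operationally as the cluster
   most significantly enriched in EAE samples by a per-sample spot-count
   t-test; pseudobulk NB differential expression between groups.
3. **Score pathways** — footprint pathway activity per spot (weighted sum of
   z-scores over the top-500 weighted responsive genes), per-sample group
   comparison with the Benjamini–Krieger–Yekutieli two-stage FDR,
   hypergeometric over-representation of gene sets (GMT, sizes 10–500), and
   per-spot gene-set scores.
4. **Trajectory screening** — draw a straight corridor from the focal cluster
   into parenchyma, bin scaled expression along it and score the fit to ideal
   patterns by the **residual AUC**

   `AUC(f) = ∫₀¹ |profile(t) − f(t)| dt`,

   with `f` one of `gradient_descending` (1 − t), `logarithmic_descending`
   (1 − ln(1+9t)/ln 10), or their ascending mirrors. Lower AUC = better fit;
   the best-fit pattern family distinguishes gradual from fast-early decline.
5. **Distance decay** — nearest-point distances from subclusters to the focal
   cluster, and smFISH-style quantification: cells binned by distance to the
   lesion at 50 µm intervals and the percent-positive fraction fit by
   nonlinear least squares to the power law **y = a·xᵇ** (exponent `b` is the
   penetration rate: more negative = steeper decay).

A first-class synthetic-data generator (`menigrad.synthetic`) emulates the
study's statistical structure — hexagonal lattice, a contiguous EAE-only
inflammation focus, negative-binomial counts with log-normal library-size
factors, region-marker and distance-decay gene programs, and power-law cell
fields — so every stage is testable without downloading data.

## Worked example

```python
import pandas as pd
import menigrad as mg

# a default two-group study: 5 naive + 6 EAE sections, 400 spots each
samples = mg.simulate_study(mg.SimConfig(), seed=1)
assignment = mg.cluster_study(samples, n_pcs=10, k_neighbors=20, resolution=0.3, seed=0)
groups = {s.sample_id: s.group for s in samples}
focal = mg.find_focal_cluster(assignment, groups)
t, p, _ = mg.cluster_group_test(assignment, groups, focal)
print(f"focal cluster: {focal}  (t = {t:.2f}, p = {p:.2e})")
```

```
focal cluster: 2  (t = 66.03, p = 2.12e-13)
```

The planted inflammation focus is recovered as its own cluster and is
massively enriched in the EAE group (~15 spots per EAE section vs ~0 in
naive). Now screen gene-set scores along a trajectory from the focus into
the parenchyma:

```python
eae = next(s for s in samples if s.group == "EAE")
labels = assignment.labels_for(eae)
other = pd.Series(labels[labels != focal]).mode()[0]
traj = mg.make_trajectory(eae, labels, focal, other, width_um=400.0)
proj = mg.project_spots(eae, traj)
mg.normalize_log(eae)
sets = {"linear_set": [f"grad_linear_{i}" for i in range(4)],
        "log_set":    [f"grad_log_{i}" for i in range(4)],
        "focus_set":  [f"focus_marker_{i}" for i in range(8)]}
feats = pd.DataFrame({n: mg.spot_set_score(eae.normalized, eae.gene_ids, g)[proj["index"]]
                      for n, g in sets.items()})
print(mg.screen_patterns(feats, proj["t"].to_numpy()).round(3))
```

```
            gradient_descending  logarithmic_descending  gradient_ascending  logarithmic_ascending            best_pattern  degenerate
feature
linear_set                0.118                   0.266               0.450                  0.388     gradient_descending       False
log_set                   0.116                   0.126               0.549                  0.566     gradient_descending       False
focus_set                 0.245                   0.169               0.495                  0.599  logarithmic_descending       False
```

All three inflammation-linked sets fit descending patterns far better than
ascending ones; the step-like focus markers fit the fast-early logarithmic
decline best, while the planted linear gradient is assigned the linear
pattern. Finally, an smFISH-style power-law decay fit on three pooled
synthetic cell fields generated with a steep decay:

```python
fields = [mg.simulate_cell_field(1500, -1.13, 50, 10, 50, seed=30 + j) for j in range(3)]
pooled = mg.CellField(cells=pd.concat([f.cells for f in fields], ignore_index=True),
                      lesion=fields[0].lesion)
fit = mg.fit_power_decay(mg.bin_cells(pooled, 50))
print(f"percent = {fit.a:.0f} * x^{fit.b:.2f}")
```

```
percent = 1031 * x^-1.03
```

The exponent of the generating law (−1.13) is recovered to within sampling
error from 1,500 cells.

## Command line

A thin wrapper exposes the stages as shell commands:

```bash
menigrad simulate --out study/ --seed 1
menigrad cluster --input study/ --out assignment.csv --resolution 0.3 --n-pcs 10
menigrad score --input study/ --weights weights.tsv --top-n 500 --q 0.05 --out pathways.tsv
menigrad gradient --input study/ --assignment assignment.csv --sample-id eae_1 \
    --from-cluster 2 --to-cluster 0 --out screen.tsv
menigrad decay --cells cells.csv --lesion lesion.csv --bin 50 --out fit.tsv
```

## Layout

```
src/menigrad/
  preprocess.py   # SpatialSample, Visium-like IO, QC, normalization
  clustering.py   # PCA, SNN/Leiden, subclustering, markers, group tests, pseudobulk DE
  pathways.py     # footprint activity, BKY two-stage FDR, ORA, gene-set scores
  gradient.py     # trajectories, profiles, ideal patterns, residual AUC
  decay.py        # nearest distances, distance binning, power-law fits
  synthetic.py    # study and cell-field generators
  cli.py          # thin command-line wrapper
docs/methods.md   # models, parameters and design choices in detail
```
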