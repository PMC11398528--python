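# microquant

Reproducible quantification of two organelle read-outs from yeast
fluorescence micrographs — **lipid-droplet (LD) area per cell** from
BODIPY/MDH-stained fields, and **cortical ER membrane area per cell**
from super-resolution Sec63-type mid-sections — together with the
photobleach signal enhancement used on long time-lapses and the
heteroscedasticity-aware statistics used to compare conditions.  A
synthetic scene generator with exact ground truth makes every stage of
the pipelines verifiable without access to raw microscope data.

The package is aimed at cell biologists who quantify organelle
morphology with classic macro-style image processing and want those
pipelines scriptable, parameterised, deterministic and tested.

## The pipelines

**LD quantification** comes in two variants sharing one backbone
(rolling-ball background subtraction at radius 50 px → 8-bit →
a second rolling ball → unsharp mask σ = 3 px, weight 0.9 → intensity
threshold → particle analysis gated to 10–1000 px²):

* *big-droplet*: second rolling ball 10 px, threshold 100–255, fused
  droplets split by a Euclidean-distance-transform watershed;
* *small/no-droplet*: second rolling ball 5 px, threshold 255 (only
  saturated pixels), circularity gate 0.6–1 instead of the watershed —
  built so that membrane staining and empty fields report zero.

Each particle is assigned to the cell containing its centroid; results
are reported per cell in px² and µm².

**Cortical ER area** is measured on a maximum-intensity projection of
the three central z-slices by a dual-mask strategy: a coarse mask
(median 1 px → rolling ball 10 px → unsharp σ = 5 px, weight 0.6 →
Rényi-entropy auto-threshold → fill holes → watershed) for rings and
sheets, plus a tubule mask (mean 1 px → Hessian tubeness at σ = 0.05
calibrated units → Rényi-entropy threshold → fill holes → watershed)
for ≈1-px filaments the coarse mask misses.  The union is gated to
particles > 25 px², an explicit exclusion mask replaces manual artifact
removal, and per-cell ER area is divided by cell area.

**Bleach boost** iteratively averages each time-lapse frame with a
processed copy (mean 2 px → rolling ball 50 px → subtract 15 → unsharp
σ = 5 px, weight 0.7), lifting dim late frames for display and QC.

**Statistics** implements the standard decision tree: Shapiro–Wilk per
group; if Gaussian, Brown–Forsythe and Bartlett variance tests; both
pass → Student's t / one-way ANOVA with Šidák-adjusted pairwise
comparisons (p_adj = 1 − (1 − p)^m); otherwise Welch's t / Welch ANOVA
(plus the Brown–Forsythe F\* ANOVA) with Dunnett-T3 comparisons via the
studentized maximum modulus distribution.  Stars: \* p<0.05, \*\*
p<0.01, \*\*\* p<0.001, \*\*\*\* p<0.0001 (strict).

## Worked example

```python
import numpy as np
from microquant import (LDQuantParams, LDSceneParams, make_ld_scene,
                        quantify_ld, decide_and_test)

# a synthetic field: 10 cells, droplets of 3-8 px radius, spot SNR ~15
img, truth = make_ld_scene(LDSceneParams(), seed=1)
res = quantify_ld(img, truth.cell_labels, LDQuantParams.for_mode("big"))
print(res.per_cell.head(3).to_string(index=False))
```

```
 cell_id  cell_area_px2  n_particles  ld_area_px2  ld_area_um2
       1         3304.0            4        470.0     1.985750
       2         4172.0            3        405.0     1.711125
       3         2458.0            5        496.0     2.095600
```

Cell 1 carries four detected droplets totalling 470 px² (1.99 µm² at
0.065 µm/px); the generator's ground truth for that cell is 437 px², a
+8% measurement bias typical of threshold-based area estimation at
this noise level.  Comparing two conditions then takes one call:

```python
groups = {"wt": res.per_cell["ld_area_px2"],
          "mut": res.per_cell["ld_area_px2"] * 1.5 + 10}
report = decide_and_test(groups)
print(report.path)
print(report.pairwise[["p_adj", "stars"]].to_string(index=False))
```

which prints the branch taken (`welch` here: the scaled group fails the
variance tests) and the adjusted p-value with its star code
(`0.034197  *`).

The same pipelines are available from the shell:

```sh
microquant synthgen ld --seed 1 --out scene.tif --truth truth.json --cells cells.tif
microquant ldquant scene.tif --mode big --cells cells.tif --out ld.csv --overlay qc.png
microquant erquant stack.tif --center-slice 1 --cells cells.tif --out er.csv
microquant bleachboost movie.tif --iters 2 --out boosted.tif
microquant statcheck groups.csv --out report.json
```

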