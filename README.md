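# orgsig — per-cell 3D organelle signatures

`orgsig` quantifies the **organelle landscape of a single cell** from 3D
multi-channel label images (one channel per organelle: endoplasmic reticulum
ER, lysosomes LS, mitochondria MT, peroxisomes PO, Golgi GL, lipid droplets
LD, plus cell and nucleus masks) and screens the resulting per-cell metric
tables for differences between cell populations. It is aimed at cell
biologists comparing organelle phenotypes across cell types or perturbations
from confocal/multispectral microscopy, after segmentation has produced
per-organelle masks.

## What it computes

For each cell the pipeline measures three families of metrics, all in
real-world units (μm, μm², μm³):

* **Morphology** — objects are instanced under 26-connectivity (touching
  organelles merge; the ER, cell and nucleus are constrained to a single
  object each) and measured for volume *V*, surface area *S* (triangulated
  isosurface), *S/V*, equivalent diameter (6V/π)^⅓, extent (V over the
  bounding box), solidity (V over the convex hull), Euler number χ
  (components − tunnels + cavities on the voxel complex), and the
  ellipsoid-equivalent major axis 4√λ₁ of the second-moment matrix.
  Per-cell summaries: count, total volume, volume fraction of the cell,
  median and SD of object volumes, and the median of each shape metric.
* **Interactions** — for each of the 15 organelle pairs, connected regions
  of voxel overlap are treated as interaction sites (a proxy for membrane
  contact sites and close apposition) and summarized by count, total,
  median and SD of site volumes, plus the percentage of each partner's
  objects involved.
* **Distribution** — the cell footprint is divided into 5 concentric rings
  interpolated between nucleus edge and cell edge (ring 1 contains the
  nucleus), each ring into 8 angular wedges, and the occupied plane range
  into 10 Z bins. Object volume per region is normalized to object total
  and region size, n(r) = (raw(r)/total)/(region cell volume(r)/cell
  volume), so uniform occupancy gives n ≡ 1; each profile is summarized by
  its mode, its volume-weighted positional SD, and the median
  across-wedge coefficient of variation.

A curated **234-metric signature** (65 morphology + 60 interaction + 109
distribution metrics) feeds the statistical screen: per-metric two-sided
Mann-Whitney U tests with the two-stage Benjamini-Krieger-Yekutieli
step-up procedure at FDR 10% (tiers \*, \*\*, \*\*\*, \*\*\*\* at q ≤ 0.1,
0.05, 0.01, 0.001), log2 fold changes of group means, standardized PCA with
parallel-analysis component retention (1000 simulations, 95th percentile),
Ward (ward.D) hierarchical clustering, and Spearman correlation. A separate
module summarizes 2D particle tracks (displacement, path length,
rolling-window speed and tortuosity over 10-frame windows).

A seeded phantom generator (`orgsig.synthetic`) produces single-cell label
images with known object counts, sizes, placement biases, and planted
pairwise overlap rates, so every stage is testable without microscopy data.

## Worked example

```python
from orgsig import synthetic, quantify_cell
from orgsig.signature import curate, batch_combine, CURATED_COLUMNS
from orgsig.screen import mwu_screen

specs, inter = synthetic.preset("neuron_like")
img, truth = synthetic.generate_cell(specs, inter, seed=1)
row = curate(quantify_cell(img))
print(f"MT count: {row['MT_count']:.0f}  (planted: {truth.counts['MT']})")
print(f"MT total volume: {row['MT_total_volume']:.2f} um^3")
print(f"LS perinuclear mode (XY ring): {row['LS_XY_mode']:.0f}")
print(f"ER-MT interaction sites: {row['ER-MT_count']:.0f}")

rows, groups = [], []
for seed in range(1, 17):
    name = "neuron_like" if seed <= 8 else "astrocyte_like"
    s, i = synthetic.preset(name)
    cell, _ = synthetic.generate_cell(s, i, seed=seed)
    rows.append(quantify_cell(cell))
    groups.append(name)
table = batch_combine(rows, groups=groups)
res = mwu_screen(table, "neuron_like", "astrocyte_like", fdr=0.10,
                 metric_cols=list(CURATED_COLUMNS))
print(f"{len(res)} metrics tested, {res.significant.sum()} significant at FDR 10%")
```

prints

```
MT count: 40  (planted: 40)
MT total volume: 5.94 um^3
LS perinuclear mode (XY ring): 3
ER-MT interaction sites: 21
196 metrics tested, 42 significant at FDR 10%
```

The quantified MT count matches the generator's ground truth exactly; the
screen flags the planted mitochondrial and lysosomal contrasts (e.g.
`MT_total_volume` q ≈ 0.002 with a positive mean rank difference — higher
in the neuron-like group; `LS_total_volume` equally strong in the opposite
direction). Metrics whose comparison groups have one or fewer data points
are excluded from testing, which is why fewer than 234 metrics are tested
on small cohorts.

The same pipeline is available from the shell:

```sh
orgsig simulate --preset neuron_like --n-cells 5 --seed 1 --out sim/
orgsig quantify sim/*.tif --out cells.csv --curated
orgsig screen cells_with_groups.csv --group-a neuron_like --group-b astrocyte_like --out results/
orgsig tracks tracks.csv --out track_summaries.csv
```

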