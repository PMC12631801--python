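# Methods

This note records the models, conventions and numerical choices behind
`orgsig`, in the order the pipeline runs them.

## Conventions

All grids are indexed (Z, Y, X); the voxel spacing is carried in the same
order and all reported measurements are physical (μm, μm², μm³).
Coordinates are 0-based voxel indices; a voxel's physical position is its
index times the spacing. The pipeline's input contract is *label images*
(binary or instance-labeled masks), not raw fluorescence: intensity-based
segmentation is upstream and out of scope, though per-channel intensity
statistics are attached when intensity stacks are supplied.

One cell per image is assumed: the cell mask and nucleus are single
objects, the nucleus lies inside the cell, and all channels share shape and
spacing (violations raise a `ValidationError` naming the offending
channel).

## Instancing

Connected components are formed under 26-connectivity: two foreground
voxels belong to one object if they touch on a face, edge or corner.
Objects within one voxel's distance therefore merge, and no watershed
splitting is attempted — a segmented "object" may be a cluster of touching
organelles, which is deliberate. Labels are renumbered in raster-scan
order of each component's first voxel so instancing is deterministic. The
ER, cell and nucleus are forced to a single object regardless of
connectivity, reflecting the prior that each cell has exactly one of each.

## Morphology

Per-object metrics and their estimators:

* **Volume** — voxel count × voxel volume (exact).
* **Surface area** — marching-cubes isosurface at level 0.5 on the object
  padded by 4 background voxels and smoothed with a 1-voxel Gaussian; the
  smoothing removes the staircase artifact that otherwise inflates the
  area of smooth bodies by ~9% (a digitized radius-10 sphere measures
  within 2.4% of 4πr²; plain voxel-face counting overestimates by ~50%).
  Objects thin enough that smoothing drops them below the level are meshed
  from the raw mask instead.
* **Euler number** — computed on the cubical complex of foreground voxels
  with the 26-connectivity foreground convention, matching the instancing
  topology; an independent V − E + F − C oracle pins the convention in the
  tests.
* **Extent** — voxel count over axis-aligned bounding-box voxels. The
  ratio is invariant under per-axis scaling, so anisotropy does not enter.
* **Solidity** — voxel count over convex-hull volume, where the hull is
  taken over foreground voxel centers and its volume counted as grid
  centers inside it (boundary inclusive). A digitized convex body thus has
  solidity exactly 1 (a hull over voxel *corners*, as some regionprops
  implementations use, would bias a radius-10 sphere down to ~0.86). Flat
  or collinear objects, whose center cloud is rank-deficient, fall back to
  a corner-point hull, which keeps them well defined with solidity ≤ 1.
* **Major axis length** — 4√λ₁ with λ₁ the largest eigenvalue of the
  second central moment matrix of voxel centers in *physical* coordinates
  (the ellipsoid-equivalent axis); spacing enters before the
  eigendecomposition. A single voxel has length 0.
* **Equivalent diameter** — (6V/π)^⅓, a deterministic function of volume.

Per-cell summaries take the median of each shape metric over objects
(median of an even-length set = mean of the two central values), the count,
total volume, volume fraction (total / cell volume), median object volume,
and the SD of object volumes with the sample (n−1) denominator — undefined
and emitted as NaN for fewer than two objects. An absent organelle yields
count 0, total volume 0, and NaN for all medians.

## Interactions

For each of the 15 organelle pairs (fixed lexicographic order ER-GL …
MT-PO), the voxel intersection of the two semantic foregrounds is instanced
under the same 26-connectivity, and each site's parent instances on both
sides are recorded from the labels its voxels touch. A site spanning two
touching parent instances is kept as one site with multiple parents.
Computing the overlap on semantic foreground first keeps site topology
independent of instance boundaries. Summaries: site count, total/median/SD
of site volumes, and percent of each side's objects involved. Overlap
volumes are symmetric and conserve the voxel intersection exactly. Sites
are a proxy for membrane contact and close apposition; no distance-resolved
classification is attempted.

## Distribution

**XY rings.** The cell mask is projected to a 2D footprint (any-voxel
projection). Every footprint pixel gets a normalized radial coordinate
d = D_nuc/(D_nuc + D_edge) from Euclidean distance transforms in physical
XY units (to the nucleus footprint, and to the background outside the
footprint) — the proportional-ring construction of CellProfiler-style
radial distribution modules. The footprint is cut into 5 equal d-intervals;
ring 1 additionally absorbs the nucleus footprint, so it contains the
nucleus and the volumes above and below it. Eight 45° wedges per ring are
drawn about the nucleus centroid with angle 0 at the +x axis (half-open
sectors); wedge statistics are therefore orientation-dependent at the
margins, which is acceptable because they are only used via a per-cell
median.

**Z bins.** The planes from the lowest to the highest plane containing
cell mask are split into 10 contiguous bins whose sizes differ by at most
one plane, extra planes going to the bottom bins. With fewer planes than
bins the trailing bins are empty (volume 0).

**Normalization.** n(r) = (raw(r)/total) / (region cell volume(r)/cell
volume). Both normalizations — to object total and to region size — are
applied in one enrichment ratio whose identity (n ≡ 1 for an object that
occupies the cell uniformly, e.g. the cell mask itself) is testable.
Regions with zero cell volume get n = 0.

**Summaries.** Mode = region index of the largest n(r), ties to the
smaller index. SD is *positional*: the standard deviation of the region
index weighted by n(r)/Σn(r), i.e. the spread of the object across
regions — coherent with the mode living on the same axis (the alternative,
SD of the n(r) values themselves, was rejected as mixing units). The wedge
CV per ring is SD/mean (sample SD, expressed as a ratio, not percent) of
the normalized wedge volumes over the wedges that contain cell volume;
wedges without cell volume are excluded since the object cannot occupy
them, and rings without object volume are excluded from the per-cell
median. An empty object yields NaN for all distribution summaries.

## The 234-metric signature

Curated columns, in deterministic order:

* morphology, 6 organelles × 11 metrics − 1 = **65** (volume fraction,
  total volume, count, median volume, SD of volumes, median S/V, median
  equivalent diameter, median extent, median Euler number, median solidity,
  median major axis; the ER count is excluded because single-object ER
  segmentation makes it constant 1);
* interactions, 15 pairs × 4 = **60** (count, total, median, SD of site
  volumes);
* distribution, 21 objects (6 organelles + 15 pairs) × 5 (XY mode, XY SD,
  XY median CV, Z mode, Z SD) + 4 nucleus metrics (no wedge CV) = **109**.

The full panel additionally carries cell/nucleus morphology (including the
nucleus area fraction), intensity statistics when available,
percent-involved metrics per pair, and per-region normalized volumes. Its
exact column count is documented by the emitted manifest but not pinned to
a constant: it depends on optional inputs, and a verbatim reproduction of
any particular full enumeration is a non-goal.

## Statistical screen

* **Mann-Whitney U**, two-sided, per metric, after pairwise deletion of
  missing values; metrics where either group then has ≤ 1 data point are
  excluded. The exact null distribution is used for tie-free groups of
  size ≤ 8, the tie-corrected normal approximation otherwise — the
  behavior of common statistics packages at these sample sizes. The mean
  rank difference (group A − group B under joint ranking) is reported as
  the effect direction.
* **Multiplicity** — the two-stage Benjamini-Krieger-Yekutieli linear
  step-up at FDR q: stage 1 at q′ = q/(1+q) gives r₁ rejections; if
  r₁ ∈ {0, m} the procedure stops, otherwise stage 2 reruns the step-up at
  q′·m/(m−r₁). Implemented directly (it is the screen's core) and
  cross-checked against `statsmodels` `fdr_tsbky` in the tests. A
  metric's q-value is defined operationally as the smallest FDR level at
  which the procedure rejects it, found by bisection (the rejection set
  grows with the level); significance tiers follow q ≤ 0.1/0.05/0.01/0.001.
* **log2 fold change** — of group *means* (medians were the alternative;
  means chosen as the conventional heatmap quantity), defined only when
  both means are strictly positive, NaN otherwise.
* **PCA** — zero-variance columns dropped, remaining columns z-scored
  (mean 0, sample SD 1). Components are retained by parallel analysis
  while the observed eigenvalue exceeds the 95th percentile of the
  matching eigenvalue from 1000 i.i.d. standard-normal matrices of the same
  shape, processed identically; the normal null is the standard choice
  when a tool's simulation distribution is not specified. By construction
  the procedure retains 0 components on pure noise in ~95% of runs — the
  calibration the tests check.
* **Hierarchical clustering** — ward.D on Euclidean distances, as in R's
  `hclust`: the Lance-Williams Ward update applied to *unsquared*
  distances. SciPy's `ward` applies the update to squared inputs, so
  distances are passed through a square root and the merge heights squared
  back; the transform is verified against a frozen R `hclust` run in the
  tests.
* **Spearman correlation** with tie handling and two-sided p per column
  pair.

## Track dynamics

Input is a point-track table (x, y in μm per frame, 5 s default interval);
detection and linking are upstream. Displacement is first-to-last
straight-line distance; total distance the sum of step lengths; step speed
= step length / frame interval. Rolling statistics use 10-point windows at
stride 1: each window's median speed, sample SD of speed, and tortuosity
(window path length / window net displacement, ≥ 1, undefined at zero net
displacement); windows are aggregated across the track by the *median*
(the robust choice; the aggregation of the original tooling is not
specified). Tracks shorter than the window use one whole-track window and
are flagged. Group comparisons reuse the MWU/BKY screen.

## Synthetic phantoms

The generator emulates what the measurement code consumes: an adherent
cell's label geometry, not its optics (no intensities, PSF or spectral
mixing). The scaffold is a smoothed random-blob footprint (low-order
harmonics on the radius, relative amplitude 0.15) extruded with a dome
profile — full footprint at the base plane, elliptical cap above — with an
interior ellipsoidal nucleus. The default grid is 112 × 112 × 24 voxels at
0.10 × 0.10 × 0.25 μm (cell radius 4.8 μm, dome 5.5 μm, nucleus radii
1.4/1.4/1.1 μm): Z-anisotropic like a confocal stack, near-isotropic in
XY, and sized so the preset organelle populations place without crowding
failures across seeds. The measurement code itself is spacing-agnostic and
is exercised at other anisotropies in the tests.

Organelles are placed by rejection sampling: the radial position d ∈ [0,1]
is drawn from a per-organelle Beta distribution over the same normalized
radial coordinate the distribution module measures, the height from a Beta
over the column's cytoplasm extent. Spheres and rods (random azimuth,
limited tilt) are carved into the cytoplasm; same-channel objects keep a
one-voxel gap so instancing recovers the planted count exactly, unless a
clustering event (per-object probability) deliberately places an object
adjacent to an existing one, merging them. The ER is one connected tube
network — a target-seeking random walk through the cytoplasm dilated to
~0.12 μm tubes — which gives it nontrivial topology (negative Euler
numbers) for the shape metrics. Planted pairwise overlaps place a chosen
fraction of source objects centered on a target object's voxels (≥ depth
voxels of interpenetration) while all other source objects avoid the
target, so the realized overlap fraction equals the planted rate. Each
object has a 1000-attempt budget; exhaustion raises an explicit
infeasible-placement error rather than degrading silently.

The two presets plant the documented contrasts: `neuron_like` has more and
larger mitochondria (40 rods vs 16) and a higher MT-on-ER overlap rate
(0.45 vs 0.10); `astrocyte_like` a larger (24 vs 13), bigger-radius,
perinuclear (Beta(1,6) radial bias), partly clustered (rate 0.25) lysosome
population and a higher PO-on-LS overlap rate (0.55 vs 0.08). Counts and
sizes are desk-scale: an order of magnitude below real cells, chosen so a
40-cell cohort generates and quantifies in tens of seconds.

What passing tests show — and what they do not: the planted-recovery suite
demonstrates that the pipeline detects known differences of this effect
size under clean label geometry. It says nothing about segmentation error,
intensity crosstalk, imaging anisotropy beyond the tested spacings, or
biological effect sizes, all of which real data add on top.

## Problem sizes and tolerances

Tests and the acceptance script use: random oracle masks ≤ 16³ (100+
masks); a digitized radius-10 sphere (volume within 2%, surface area
within 5%, equivalent diameter within 1% of closed form); exact MWU
enumeration for group sizes ≤ 5; FDR simulations with m = 200 over 500
replicates; 100 seeded parallel-analysis runs on 20 × 10 noise matrices
with 300 simulations each; and a 20 + 20 phantom cohort for end-to-end
recovery. Conservation identities (region volumes, label counts) are
asserted exactly or at float precision.

## Known limitations

* Touching organelles are measured as one object by design; counts are
  lower bounds in crowded cells.
* Wedge statistics depend on the angular origin at the margins.
* The positional-SD and ratio-CV conventions for distribution summaries
  are one defensible reading of histogram "mode/SD/CV" summaries; both are
  documented above and pinned by tests, but other implementations may
  differ.
* Surface area of objects ~1-2 voxels thick is estimator-dominated and
  should be compared only within a fixed pipeline version.
* The q-value bisection assumes rejection monotone in the FDR level,
  which holds for the two-stage step-up in all tested configurations.
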