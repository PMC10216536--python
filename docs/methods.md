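# Methods

## Scope and design

`ctcmorph` reproduces, as a fully synthetic and therefore testable pipeline,
an image-based workflow for discovering morphometric subtypes of circulating
tumor cells (CTCs): three-channel 3D fluorescence stacks of single cells →
per-component segmentation → a ~500-feature morphometric vector → table
conditioning → hierarchical clustering into three subtypes (SLR, SSR, LSS) →
an in-silico emulation of the FACS strategy used to sort those subtypes.
Because no public image data accompany the original protocol, the package
ships a phantom generator whose ground truth doubles as the oracle for every
downstream stage.

## The phantom generator

Each cell is rendered on a voxel grid with anisotropic spacing
(0.9 μm optical sections, 0.3 μm in-plane; both configurable) in a
30×80×80 frame, one cell per frame, three channels in the fixed order
(cytoplasm, nucleus, mitochondria).

* **Cell body** — a sphere of sampled radius whose boundary radius is
  modulated by a band-limited Gaussian random field (correlation length
  0.4 R, amplitude = `roughness_amplitude`, clipped at ±2.5 sd).  The shape
  is star-convex, hence always connected.
* **Nucleus** — the k voxels of the 1-voxel-eroded cell closest to a
  randomly offset center under a mildly anisotropic ellipsoidal metric,
  with k = round(nuc_cell_ratio × cell voxels).  Choosing voxels by rank
  makes the Nuc/Cell voxel ratio exact up to one voxel.
* **Dense-nuclear foci / mitochondria** — the top quantile of a smoothed
  noise field (foci scale ≈ 0.8 μm and 0.5 μm respectively) inside the
  nucleus / cytoplasmic shell, again hitting the drawn volume ratio exactly.
* **Intensities** — piecewise-constant foreground means per channel
  (cytoplasm 100; the cytoplasmic channel is dimmed to 0.6× over the nuclear
  region; nucleus 110 with dense foci at 1.8×; mitochondria per archetype),
  multiplied by a per-batch staining factor (defaults 1.0 and 1.4 over two
  randomly assigned batches) plus additive Gaussian noise with sd = 5% of
  the channel's foreground mean, clipped at zero.

Determinism: a cohort seed fans out through `numpy.random.SeedSequence`
into one child per cell plus separate streams for mixture/batch assignment
and noise, so cohorts are bit-reproducible and cells are independently
rerunnable.

### Archetype defaults

The source protocol characterizes its three subtypes only qualitatively
(z-score boxplots), so the numeric defaults below are this package's
operationalization, chosen once so that the published qualitative contrasts
hold by construction and kept fixed thereafter:

| parameter (mean ± sd) | SLR | SSR | LSS |
|---|---|---|---|
| mixture weight | 0.319 | 0.624 | 0.057 |
| cell radius (μm) | 5.0 ± 0.30 | 5.6 ± 0.40 | 8.0 ± 0.45 |
| Nuc/Cell volume ratio | 0.52 ± 0.04 | 0.28 ± 0.035 | 0.52 ± 0.04 |
| DenseNuc/Nuc volume ratio | 0.38 ± 0.035 | 0.30 ± 0.035 | 0.16 ± 0.03 |
| Mito/Cell volume ratio | 0.20 ± 0.015 | 0.05 ± 0.012 | 0.05 ± 0.012 |
| membrane roughness | 0.14 | 0.06 | 0.02 |
| mito channel intensity | 170 | 110 | 110 |

Notes on deliberate choices:

* The published subtype proportions (32%, 62.6%, 5.7%) sum to 100.3%; the
  mixture weights are those proportions normalized to sum to 1.
* SLR and LSS share the same Nuc/Cell mean, making that contrast null by
  construction (the protocol reports it as non-significant).
* All sampling distributions are truncated normals (±3 sd; ratios clipped
  to (0.001, 0.999)).  The spreads are set so the three archetypes'
  (volume, Mito/Cell) centroids sit ≥ 3 within-group SD apart after
  cohort-wide standardization — separable by construction — and so the
  rare LSS group is not erased by the 3×IQR winsorization fence.
* The mitochondrial load of a cell is drawn as an *absolute* volume
  (ratio × archetype-typical cell volume) and converted to a per-cell
  ratio.  Within an archetype, total mitochondrial content is therefore
  roughly conserved rather than proportional to cell size, which is what
  lets small high-mito cells land in the top decile of whole-cell
  Mito-Tracker signal — the property the FACS sorting strategy relies on.
  The SLR mitochondrial channel is brighter per voxel (170 vs 110),
  emulating the membrane-potential dependence of the dye.

What the generator does **not** emulate: optics (no point-spread function,
the sectioning function of the source microscope is taken at face value),
multi-cell fields of view, non-multiplicative batch artifacts, autofluorescence,
segmentation-hostile debris, and any correlation structure between features
beyond what geometry induces.  Tests passing on these phantoms therefore
validate the *pipeline machinery and its statistics*, not performance on
real micrographs.

## Segmentation and features

Each channel is segmented independently: the Otsu threshold is estimated on
a lightly smoothed copy (σ = 1 voxel in-plane) and applied to the raw
intensities — so a binary input reproduces itself exactly.  Cell and nucleus
keep the largest connected component; hole closing (3×3×3 closing followed
by interior-cavity filling) is applied to the cell and nucleus masks but not
to dense-nuclear foci or mitochondria.  Dense-nuclear foci are a second,
higher Otsu split of the within-nucleus intensities.  Nesting is enforced by
intersection (nucleus ∩ cell, densenuc ∩ nucleus).

The feature registry pins "around 500 features" to exactly 500 named
features (see `ctcmorph.registry` for the complete inventory): per-component
volume, iso-surface mesh area (marching cubes on a smoothed mask, with
anisotropic spacing, falling back to the raw binary surface for structures
too thin to survive smoothing), intensity summaries, eleven 2D shape
descriptors on the most-centered section (the z-slice of the component
centroid) plus a boundary-roughness index for the cell, a 16-scale
granularity spectrum (iterative grayscale opening granulometry), 13 Haralick
co-occurrence statistics at 4 in-plane directions × 2 offsets (1 offset for
the small DenseNuc component — this trim is what makes the total exactly
500), and seven cross-component ratio features.  *Main Features* are all
categories except granularity and texture (72 features); they alone enter
dimensionality reduction and clustering.  Empty components propagate as
missing values, never zeros.

## Table conditioning

Fixed order, enforced at runtime: (1) QC — drop all-missing rows/columns;
(2) mean imputation per feature; (3) signed log1p, sign(x)·ln(1+|x|), which
is monotone and defined for the negative-valued texture statistics;
(4) per-staining-batch z-scoring (sample sd; constant features flagged and
set to 0); (5) winsorization with quartile fences at multiplier 3, values
outside a fence replaced by the adjacent quartile.  Quartiles use linear
interpolation.  The protocol's printed lower-fence formula (Q1 + 3·IQR)
places the lower fence above Q3 whenever IQR > 0; the default "corrected"
mode uses Q1 − 3·IQR, and the printed "literal" mode is retained behind a
flag so both behaviors stay auditable.  Winsorization parameters are pooled
across batches because it runs after batch normalization.

## Subtype discovery

Agglomerative clustering on Euclidean distances over Main Features; the
number of groups is the argmax of mean silhouette width over cuts of one
tree, k ∈ 2..10 (clamped for small cohorts).  Ward linkage is the default:
complete linkage — the default of the heatmap tools this emulates — proved
diameter-sensitive on these tables, splicing the larger cells of the
small-cell SLR group into the large-cell cluster, while Ward recovers the
generator's partition exactly; `method="complete"` reproduces the
heatmap-tool behavior when wanted.  The three-cluster solution is mapped to
archetypes deterministically: LSS = largest mean cell volume; of the
remaining two, SLR = higher mean Mito/Cell volume ratio (exact volume ties
break toward lower Mito/Cell for LSS, with a logged warning).  Group
characterization reports per-cluster feature means on the z-scored scale and
pairwise two-sided pooled-variance Student's t-tests at α = 0.05 with **raw**
p-values — the source protocol applies no multiple-testing correction, and
the output column is named `p_raw` so users can opt into FDR themselves.

PCA (centered, full SVD) over Main Features or all features is retained for
inspection; it plays no role in the clustering itself.

## FACS emulation

Gates are quantiles with linear interpolation: Small = size proxy ≤ 10th
percentile, Large = ≥ 90th; Small/High = Small ∩ (mito proxy ≥ 90th
percentile), Small/Low = Small ∩ (≤ 40th percentile); everything else is
ungated, mirroring the sorter's discarded middle.  FACS measures whole-cell
fluorescence, so the default proxies are the integrated cytoplasm and
mitochondria channel intensities.  The mitochondrial reference population is
all cells by default (`mito_ref="small"` restricts it to the Small gate;
the protocol's phrasing supports either reading).  Within the pipeline,
gating is applied per staining batch — a sort is one cytometer run, and
per-batch quantiles are invariant to multiplicative staining shifts.
Degenerate gates (all cells tied on the size proxy) return every cell
ungated with a warning rather than fabricating a partition.

Expected behavior on the default mixture: the Small gate is dominated by
SLR cells, so Small/High is small but nearly pure SLR, Small/Low is a
sliver of SSR, and the Large gate captures essentially all LSS plus the
upper tail of SSR (purity ≈ LSS prevalence / 10%, by construction of a
10% gate over a 5.7% subtype).

## Numerical choices and problem sizes

* Cohort sizes: 500 cells for subtype-structure analyses (three replicate
  seeds), 1000 cells for gating; chosen to match the protocol's processed
  cohort and to keep a full replicate around a minute of CPU.
* Surface areas: marching cubes at level 0.5 on a Gaussian-smoothed (σ = 1
  voxel) padded mask; ≈ 1–2% of the analytic value for spheres of radius
  ≥ 10 voxels.
* Texture quantization: 32 gray levels over the within-mask intensity
  range; background is held out of the co-occurrence counts via a reserved
  level.  Degenerate statistics (correlation of a constant patch) are NaN,
  which the conditioning chain imputes.
* Silhouette ties and cluster relabeling: partitions are deterministic
  given the input order; tests assert invariance up to relabeling under row
  permutation.
* Proliferation rates: N_t / (N_{t−1} − removed_{t−1}), missing (with a
  warning) when the denominator is ≤ 0.

## Known limitations

* The generator's archetype geometry is an idealization; none of the
  absolute feature values should be compared to real CTC measurements —
  only the relative structure (group contrasts, proportions) is meaningful.
* Complete linkage remains available but is not robust on these tables
  (see above); silhouette-based k selection inherits any such linkage
  pathology.
* The 500-feature registry is a versioned contract: adding or removing a
  feature is a schema change, not a patch.
* Real-data stages of the source workflow (single-cell RNA-seq, in-vivo
  tumorigenicity, survival analysis) are out of scope.
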