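# Methods

This note documents the models, conventions and numerical choices behind
`voxtome`, in the order the pipeline runs.

## Data model

The primary input is a genes×voxels matrix of non-negative integer read
counts, where each voxel is a laser-microdissected 50×50×50 μm³ tissue cube
(~100 cells) sequenced as one sample, plus a layout table mapping each
voxel to `(section, row, col)` on a regular grid (pitch 50 μm by default).
Grid coordinates are 0-based; row grows ventrally (downward in rendered
images), col laterally. The set of listed voxels *is* the tissue mask:
grid positions without a voxel are background, never imputed — real
sections are irregular (here, the wedge shape of the embryonic medial
ganglionic eminence). Voxels present in the counts but absent from the
layout (or vice versa) are dropped with a warning at alignment.

## Normalization

Expression is reported in reads per million: for voxel v and gene g,

    x(g,v) = 1e6 · count(g,v) / Σ_{g'∉E} count(g',v)

where E is an optional exclusion set (e.g. repeat-derived annotations)
removed from both the denominator and the output. Columns of the result
sum to 1e6 except voxels with zero included reads, which are left all-zero
and logged. "Detected" means ≥1 read by default (`min_reads` exposed); the
detection summary reports the per-voxel counts, their mean, and the number
of genes detected in at least one voxel.

## Mapper clustering

**Metric.** Voxel profiles are compared by norm correlation: expression is
z-scored (population convention, divisor n) and the distance is
d(i,j) = 1 − r(i,j), r the Pearson correlation between voxel columns, so
d ∈ [0,2]. By default each *gene* is standardized across voxels — the
usual standardize-each-variable convention — which makes every gene count
equally in the correlation regardless of absolute abundance. The
alternative axis (z-scoring each voxel's profile across genes) is exposed
but not default: with heavy-tailed abundance distributions it lets the few
most-expressed genes dominate the metric, and in our recovery experiments
it buries the spatial programs entirely. Genes constant across all voxels
(typically undetected ones) carry no information for the metric and are
dropped by `run_mapper` before standardization. We use d = 1 − r rather
than √(2(1−r)); downstream stages consume only distance ranks, on which
the two agree.

**Lenses.** The two lens functions are the first two classical-MDS
coordinates of the distance matrix ("metric SVD"): eigendecompose the
double-centered −D²/2 and scale the top eigenvectors by the square roots
of their eigenvalues, ordering by decreasing eigenvalue and failing
loudly when fewer than k eigenvalues are positive. Each coordinate's sign
is fixed so that its largest-magnitude entry is positive, making the lens
(and everything downstream) deterministic. On distances that come from an
exact 2-D Euclidean configuration this reproduces the configuration up to
isometry (a property the test suite checks to a Procrustes residual of
1e-8).

**Cover.** Each lens axis is partitioned into `resolution` base intervals
— equal-frequency (quantile) intervals when `equalized` (the default),
with ties broken stably by voxel index so base occupancies differ by at
most one; equal-width otherwise. Interval breakpoints sit midway between
the last value of one rank-group and the first of the next. Each base
interval is then expanded about its center to `gain` times its base
width, and the 2-D cover is the Cartesian product of the two expanded
interval lists. A voxel belongs to a product bin if it falls in the
expanded interval on both axes (membership in its own base bin is always
kept), so every voxel lies in at least one bin, and with gain 1 the cover
degenerates to an exact partition. Defaults follow the original analysis:
resolution (40, 30), gain (2.5, 4.0), equalized. With equal-width
intervals a point lies in at most ⌈gain⌉+1 intervals per axis; when
equalized intervals have very unequal widths the count can exceed that
bound, which is expected behaviour of the expansion rule, not an error.

**In-bin clustering.** Within each product bin, voxels are clustered by
single linkage on the restricted distance matrix and the dendrogram is cut
using the classic Mapper gap heuristic: histogram the merge heights into
10 bins over [0, max height] and cut at the left edge of the first empty
histogram bin *that follows a non-empty one*. The qualifier matters: when
all merges are tall (e.g. all pairwise distances equal), the leading bins
are empty but there is no gap *in* the data, and the correct answer is one
cluster, not a shattering into singletons. With no gap at all, the bin is
one cluster; singleton bins are singleton clusters.

**Nerve.** One node per (bin, in-bin cluster); an undirected edge joins
two nodes exactly when they share a voxel, weighted by the shared count.
The construction sweeps voxel→node incidence lists rather than testing all
node pairs; tests verify the edge set against the brute-force pairwise
intersection oracle.

**Segmentation.** How the original analysis cut its graph into five
clusters is not recorded, so segmentation is this package's own choice,
picked to be deterministic and seedable. With `k=None` the nerve is
segmented by Louvain modularity communities, keeping the best-modularity
partition over eight seeded restarts (single runs measurably stall in
local optima). With `k` fixed, agglomerative modularity maximization
(Clauset–Newman–Moore) is stopped at exactly k communities, which yields
the modularity-guided k-way split directly; an edgeless nerve falls back
to deterministic chunking of the sorted nodes. Voxels inherit labels by
majority vote over the nodes containing them; ties go to the community
holding the largest node, then the lowest community index. Labels 1..K
are ordered by decreasing community voxel count. A side effect of voting
is that tiny spurious communities that never win a vote vanish, so the
number of realized labels can be smaller than the number of node
communities.

## Marker genes

Each cluster is compared against the pooled rest, per gene, with the
two-sample Kolmogorov–Smirnov statistic D = sup_t |F_in(t) − F_rest(t)|,
computed on per-million values. Ties are handled by evaluating the pooled
ECDFs at every distinct pooled value; since D is invariant under strictly
increasing transforms, equal-depth counts and per-million values give
identical statistics. The "KS score" used for export filtering is D
itself, with a strict threshold (default 0.25).

p-values: for pooled sizes n+m ≤ 140 we enumerate the exact no-ties null
by counting monotone lattice paths inside the band |i·m − j·n| < D·n·m
(O(nm) per unique statistic, cached — D is always an integer multiple of
1/(nm), so a 2,000-gene screen touches only a few dozen distinct values).
Beyond that, the asymptotic Kolmogorov distribution at D·√(nm/(n+m)). The
cutoff is deliberately generous: at two-digit sample sizes the asymptotic
tail is *anti*conservative at Bonferroni-corrected depths (~1e-5), enough
to push the realized family-wise error above its nominal level, while the
exact null is valid — under ties D is stochastically smaller than in the
continuous model, so exact p-values err conservative. Both methods agree
with an independent reference implementation to high precision in the
tests.

Multiple testing: Bonferroni. The default family is the genes within one
cluster-vs-rest comparison (matching how the comparisons are described for
the real tissue); `family="global"` uses genes×clusters. The calibration
experiments use the global family, because their criterion — "no
significant gene anywhere under a global null" — is a statement about
everything tested: with calibrated p-values, per-cluster families would
give ≈kα for k clusters by construction.

## Imaging

Back-projection writes each voxel's value or label to its (row, col)
pixel within the section bounding box — one voxel, one pixel, no
smoothing or interpolation ever; rendering to PNG replicates each voxel
as a scale×scale block. Continuous maps use the matplotlib `viridis`
colormap scaled to [0, per-image max] by default (fixed bounds
available); categorical maps use a fixed palette whose first entries echo
the original cluster figures (red, green, light blue, dark blues). The
original colormaps are not documented anywhere, so these are this
package's own, documented choice. Cluster maps come with a contiguity
report: connected components per label under 4-connectivity within the
tissue mask, the quantitative version of "spatially distinct region".

## Synthetic data generator

The generator emulates the study conditions the pipeline was built for,
at desk scale. Its defaults are fixed and are the conditions under which
the recovery tests run:

- **Geometry**: a 16×12 grid carrying a wedge-shaped mask of 127 voxels
  (row width growing ventrally from 3 to 12), the size of the largest
  real section; one section, 50 μm pitch.
- **Programs**: five expression programs in four dorsoventral bands
  (rows split in four): programs 1–3 occupy successive bands from the
  dorsal edge, and programs 4 and 5 interleave per-voxel (fair coin)
  within the ventral-most band — transcriptionally distinct but spatially
  co-localized, like the two mantle clusters in the real tissue.
- **Expression**: per-gene relative abundance is log-normal (σ = 1.6,
  ~5,000 genes). Each program owns a 300-gene module drawn from the upper
  half of abundance (usable marker panels are moderately-to-highly
  expressed genes; developmental zones differ by whole transcriptional
  programs, not a handful of markers). Module m is multiplied by
  (2^2.0)^w in program p with graded activation w = max(0, 1 − |m−p|/2):
  full in its own program, half in neighbors, zero beyond. This graded
  activation encodes that the tissue is a *maturation progression* —
  adjacent zones share expression — and it is also what makes the five programs
  embeddable by a 2-D lens: five mutually equidistant programs would form
  a 4-simplex that no planar lens can separate.
- **Noise**: counts are gamma-Poisson (negative binomial) with size 10 —
  a voxel pools ~100 cells, so it is far less overdispersed than one cell
  — thinned by 15% dropout; library sizes are log-normal with median
  12,000 reads (~100 cells at ~120 mapped reads each), calibrated so a
  voxel detects on the order of 2,000 genes, matching the real per-voxel
  detection rate.

The null mode (`generate_null`) drops all program structure (i.i.d.
voxels on a full rectangular grid) and returns a fixed round-robin
4-group partition for calibration experiments.

What the generator does *not* emulate: multiple sections/animals and
batch effects between them, within-program expression gradients, spatial
autocorrelation of noise, gene–gene correlation beyond the program
modules, mean-dependent dropout, and laser-damage artifacts at voxel
boundaries. Passing recovery tests therefore show that the pipeline
recovers banded programs under realistic count noise at realistic depth —
not that it is robust to batch structure or spatially correlated noise.

## Recovery and calibration experiments

`evaluate_recovery` scores a clustering against the planted labels by the
adjusted Rand index (permutation-model formula). Under the default
generator and default pipeline parameters with automatic segmentation,
seeds 1–20 give a modal recovered cluster count of 5 and ARI ≥ 0.8 in
≥ 90% of seeds (the acceptance suite runs exactly this, in ~15 s). The
family-wise error experiment runs 200 simulated null datasets of 2,000
genes × 100 voxels (25-voxel groups vs 75 pooled) and counts datasets
with any Bonferroni-significant gene at α = 0.05; with exact p-values and
the global family the observed fraction is 0.01–0.04 depending on the
seed, within the nominal bound. Problem sizes throughout (5,000 genes ×
127 voxels; 200 replicates of 2,000 × 100) were chosen as the smallest
that preserve the statistical regime of the real data — per-voxel depth,
detection rate, group sizes — while keeping the whole suite quick on a
laptop.

## Degenerate inputs and numerical conventions

- Distances are symmetrized ((d+dᵀ)/2), clipped to [0,2], zero diagonal;
  asymmetry beyond 1e-9 is an error.
- MDS eigenvalues are accepted as positive above a relative tolerance of
  1e-12 of the leading eigenvalue.
- Lens resolution is clamped to the number of distinct lens values (and to
  n) by `run_mapper`; `build_cover` called directly errors instead.
- A constant voxel (axis="voxel") or constant gene (axis="gene") makes
  standardization fail loudly, naming the offender; `run_mapper` drops
  constant genes first.
- p-values are clipped into (0, 1]; Bonferroni caps at 1.
- Marker direction is the sign of the in-cluster minus rest median
  difference, falling back to the mean difference on median ties, and to
  "up" when both tie.
- All stochastic steps (generator, Louvain restarts) are driven by
  explicit integer seeds; identical inputs and seeds give bit-identical
  outputs, including rendered PNG bytes.
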