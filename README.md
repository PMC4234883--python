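# voxtome

Spatially resolved transcriptome imaging of laser-microdissected tissue
voxels.

`voxtome` analyzes RNA-seq data collected by cutting a tissue section into a
regular grid of 50×50×50 μm³ cubes ("voxels", each holding ~100 cells) and
sequencing every cube as if it were a single cell. Because each voxel keeps
its grid coordinates, any gene's expression can be projected back onto the
section as an image — a whole-genome *in situ* hybridization — and clustering
voxels by expression reveals the spatial architecture of the tissue. The
package was built around the embryonic medial ganglionic eminence (MGE), a
wedge-shaped forebrain structure organized as a dorsoventral maturation
gradient from the proliferative ventricular zone to the mantle zone, but
works for any genes×voxels count matrix with a grid layout.

## What it does

- **Normalization** — raw counts → reads per million per voxel
  (`normalize_per_million`), with optional exclusion of repeat-derived
  genes from the scaling denominator.
- **Mapper/TDA clustering** (`run_mapper`) — the topological-data-analysis
  construction used to find transcriptional subregions:
  1. z-score expression and form the *norm-correlation* distance
     d(i,j) = 1 − r(i,j) between voxel profiles;
  2. project voxels through two lens functions: the first two classical-MDS
     ("metric SVD") coordinates of the distance matrix;
  3. cover the lens plane with overlapping bins — equal-frequency
     ("equalized") intervals at resolution 40 / gain 2.5× on lens 1 and
     resolution 30 / gain 4× on lens 2;
  4. single-linkage cluster each bin's voxels (first-gap histogram cutoff);
  5. build the nerve graph (nodes = in-bin clusters, edges = shared
     voxels) and segment it into communities by modularity, automatically
     or at a fixed k.
- **Marker detection** (`cluster_markers`) — for every (cluster, gene), the
  two-sample Kolmogorov–Smirnov statistic D = sup|F_in − F_rest| of the
  cluster against the pooled rest, with exact or asymptotic p-values and
  Bonferroni correction at α = 0.05; `filter_markers` exports per-cluster
  gene lists (KS score > 0.25) for external GO/enrichment tools.
- **Imaging** (`project_gene`, `project_clusters`, `render`) — back-project
  expression values or cluster labels onto the section grid, one voxel per
  pixel, with a 4-connectivity contiguity report per cluster.
- **Synthetic data** (`generate_fixture`, `generate_null`) — a seeded
  generator of count matrices with five expression programs planted in four
  dorsoventral bands (programs 4 and 5 interleaved within the ventral-most
  band), negative-binomial noise, log-normal libraries and dropout, plus
  ground-truth labels and an i.i.d. null mode for calibration experiments.

## Worked example

Simulate a tissue section, normalize, cluster into five groups, find
markers, and draw the cluster map:

```sh
voxtome simulate --seed 1 --out-prefix mge
voxtome normalize --counts mge.counts.tsv --layout mge.layout.csv --out expr.tsv
voxtome mapper --expr expr.tsv --k 5 --seed 0 --out-labels labels.tsv
voxtome de --expr expr.tsv --labels labels.tsv --out markers.tsv --gene-lists lists/
voxtome render --labels labels.tsv --layout mge.layout.csv --section S1 --out clusters.png
```

which prints:

```
simulated 5000 genes x 127 voxels (seed 1)
normalized 5000 genes x 127 voxels; mean detected genes/voxel 1932, expressed in >=1 voxel: 4956
nerve: 409 nodes; 5 clusters over 127 voxels
911 significant (cluster, gene) pairs at alpha=0.05
cluster 1: 4 connected component(s)
cluster 2: 1 connected component(s)
cluster 3: 1 connected component(s)
cluster 4: 8 connected component(s)
cluster 5: 1 connected component(s)
wrote clusters.png
```

The 127 voxels form a wedge-shaped section; each detects ~1,900 genes. The
five recovered clusters match the five planted programs (adjusted Rand
index 0.95 against `mge.truth.tsv`); three map to contiguous bands (one
connected component each) while the two programs planted as a salt-and-
pepper mixture in the ventral band come out spatially fragmented (4 and 8
components) — transcriptionally separable but not spatially segregated.
`markers.tsv` lists each cluster's discriminating genes by descending KS
score; `lists/cluster_*.txt` hold the significant genes with score > 0.25,
one id per line, ready for an enrichment tool.

Everything is available as a library too, e.g.:

```python
from voxtome import (SyntheticConfig, generate_fixture, normalize_per_million,
                     run_mapper, cluster_markers, evaluate_recovery)

counts, grid, truth = generate_fixture(SyntheticConfig(seed=1))
expr = normalize_per_million(counts)
graph, labels = run_mapper(expr)          # automatic segmentation
print(labels.k, evaluate_recovery(labels, truth))
```

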