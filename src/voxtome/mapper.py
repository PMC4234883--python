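"""Mapper (topological data analysis) clustering of voxel transcriptomes.

The construction follows the classic Mapper recipe applied to expression
profiles:

1. z-score each voxel's profile across genes and take the norm-correlation
   distance d = 1 - Pearson(r) between profiles (d in [0, 2]);
2. project voxels through two lens functions — the first two classical-MDS
   ("metric SVD") coordinates of the distance matrix;
3. cover the 2-D lens space with a Cartesian product of overlapping
   intervals, equal-frequency ("equalized") base intervals expanded by the
   gain factor (defaults: resolution 40, gain 2.5x on lens 1; resolution
   30, gain 4x on lens 2);
4. single-linkage cluster the voxels inside each cover bin, cutting the
   dendrogram at the first gap of the merge-height histogram;
5. form the nerve graph: one node per in-bin cluster, edges between nodes
   sharing voxels, weighted by the shared count;
6. segment the nerve into communities (seeded Louvain modularity, with
   optional forcing to exactly k) and assign each voxel the label of the
   community that holds the majority of its nodes.

The result is a graph linking groups of voxels with shared expression
patterns plus a hard per-voxel cluster labelling that can be projected back
onto the tissue grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .normalize import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "LensValues",
    "CoverAxis",
    "Cover",
    "MapperGraph",
    "ClusterLabels",
    "MapperParams",
    "standardize_profiles",
    "pairwise_norm_correlation",
    "metric_svd_lens",
    "build_cover",
    "cluster_bin",
    "build_nerve",
    "segment_nerve",
    "run_mapper",
]


@dataclass
class DistanceMatrix:
    """Symmetric norm-correlation distances between voxel profiles."""

    voxel_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.voxel_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with voxel ids")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if d.size:
            if not np.all(np.diag(d) == 0):
                raise ValueError("distance matrix diagonal must be exactly 0")
            if d.min() < -1e-12 or d.max() > 2 + 1e-9:
                raise ValueError("distances must lie in [0, 2]")
        self.d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.voxel_ids)

    def restrict(self, indices: Sequence[int]) -> np.ndarray:
        idx = np.asarray(indices, dtype=int)
        return self.d[np.ix_(idx, idx)]


@dataclass
class LensValues:
    """Per-voxel lens coordinates (columns ordered by decreasing eigenvalue)."""

    voxel_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[0] != len(self.voxel_ids):
            raise ValueError("lens coords shape inconsistent with voxel ids")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite lens coordinates")
        self.coords = coords


@dataclass
class CoverAxis:
    """One lens dimension of the cover.

    ``base_intervals`` partition the lens range at equal-frequency
    breakpoints; ``intervals`` are the same intervals expanded about their
    centers to ``gain`` times the base width. ``base_assignment`` maps each
    voxel to its rank-based base interval, which guarantees occupancies
    differing by at most one regardless of ties.
    """

    resolution: int
    gain: float
    equalized: bool
    base_intervals: list[tuple[float, float]]
    intervals: list[tuple[float, float]]
    base_assignment: np.ndarray  # voxel index -> base interval index

    def memberships(self, values: np.ndarray) -> list[np.ndarray]:
        """Per-interval boolean membership over the voxels."""
        out = []
        for b, (lo, hi) in enumerate(self.intervals):
            if self.gain <= 1.0:
                member = self.base_assignment == b
            else:
                member = (self.base_assignment == b) | ((values >= lo) & (values <= hi))
            out.append(member)
        return out


@dataclass
class Cover:
    """Product cover of the 2-D (or k-D) lens space."""

    axes: list[CoverAxis]
    lens: LensValues

    def bin_members(self) -> dict[tuple[int, ...], np.ndarray]:
        """Map product-bin index to the array of member voxel indices.

        Only non-empty bins are returned; every voxel belongs to at least
        its own base product bin.
        """
        per_axis = [
            axis.memberships(self.lens.coords[:, dim])
            for dim, axis in enumerate(self.axes)
        ]
        bins: dict[tuple[int, ...], np.ndarray] = {}

        def recurse(dim: int, prefix: tuple[int, ...], mask: np.ndarray) -> None:
            if dim == len(per_axis):
                idx = np.nonzero(mask)[0]
                if idx.size:
                    bins[prefix] = idx
                return
            for b, member in enumerate(per_axis[dim]):
                sub = mask & member
                if sub.any():
                    recurse(dim + 1, prefix + (b,), sub)

        recurse(0, (), np.ones(len(self.lens.voxel_ids), dtype=bool))
        return bins


@dataclass
class MapperGraph:
    """The nerve of the cover: nodes are in-bin voxel clusters, edges link
    nodes sharing voxels (weight = shared-voxel count)."""

    graph: nx.Graph
    voxel_ids: list[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def node_members(self, node: int) -> frozenset[int]:
        return self.graph.nodes[node]["members"]

    def nodes_of_voxel(self, voxel_index: int) -> list[int]:
        return [n for n, data in self.graph.nodes(data=True) if voxel_index in data["members"]]


@dataclass
class ClusterLabels:
    """Hard per-voxel cluster assignment, labels 1..K."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        if self.labels:
            ks = set(self.labels.values())
            if min(ks) < 1:
                raise ValueError("labels must be >= 1")

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def as_array(self, voxel_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.labels[str(v)] for v in voxel_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"voxel {e} has no cluster label") from None


def standardize_profiles(
    expr: ExpressionMatrix | np.ndarray, axis: str = "gene"
) -> np.ndarray:
    """z-score expression values with the population (divisor n) convention.

    ``axis='gene'`` (default) standardizes each gene across voxels — the
    usual convention of standardizing each variable, so every gene
    contributes on an equal footing to the subsequent profile correlation
    regardless of its absolute abundance. ``axis='voxel'`` standardizes
    each voxel's vector across genes instead. Constant vectors along the
    chosen axis are an error; callers working with raw count data should
    drop undetected genes first (:func:`run_mapper` does).
    """
    if isinstance(expr, ExpressionMatrix):
        values = np.asarray(expr.values, dtype=float)
        voxel_names, gene_names = expr.voxel_ids, expr.gene_ids
    else:
        values = np.asarray(expr, dtype=float)
        voxel_names = [str(j) for j in range(values.shape[1])]
        gene_names = [str(i) for i in range(values.shape[0])]
    if axis == "voxel":
        mean = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, ddof=0, keepdims=True)
        flat = np.nonzero(sd[0] == 0)[0]
        if flat.size:
            raise ValueError(
                f"voxel {voxel_names[flat[0]]!r} has constant expression across genes"
            )
    elif axis == "gene":
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=0, keepdims=True)
        flat = np.nonzero(sd[:, 0] == 0)[0]
        if flat.size:
            raise ValueError(f"gene {gene_names[flat[0]]!r} has constant expression")
    else:
        raise ValueError("axis must be 'voxel' or 'gene'")
    if values.shape[0] < 2:
        raise ValueError("need >= 2 genes to standardize profiles")
    return (values - mean) / sd


def pairwise_norm_correlation(
    standardized: np.ndarray, voxel_ids: Sequence[str]
) -> DistanceMatrix:
    """Norm-correlation distance d = 1 - r between voxel profiles.

    ``standardized`` is the genes x voxels output of
    :func:`standardize_profiles`; r is the Pearson correlation between
    profile columns.
    """
    std = np.asarray(standardized, dtype=float)
    r = np.corrcoef(std, rowvar=False)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite correlation between voxel profiles")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(map(str, voxel_ids)), np.clip((d + d.T) / 2, 0.0, 2.0))


def metric_svd_lens(D: DistanceMatrix, k: int = 2) -> LensValues:
    """Classical multidimensional scaling (metric SVD) lens coordinates.

    Double-centers -D^2/2 and returns the top-k spectral coordinates ordered
    by decreasing eigenvalue. Each coordinate's sign is fixed so that its
    largest-magnitude entry is positive, making the lens deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = D.n
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} voxels for a {k}-dimensional lens")
    d2 = D.d ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(eigvals[0], 0.0) * 1e-12 + 1e-15
    if np.sum(eigvals > tol) < k:
        raise ValueError(
            f"only {int(np.sum(eigvals > tol))} positive eigenvalue(s); use a smaller k"
        )
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return LensValues(list(D.voxel_ids), coords)


def _cover_axis(values: np.ndarray, resolution: int, gain: float, equalized: bool) -> CoverAxis:
    n = values.size
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if gain < 1:
        raise ValueError("gain must be >= 1")
    distinct = np.unique(values).size
    if resolution > distinct:
        raise ValueError(
            f"resolution {resolution} exceeds number of distinct lens values ({distinct})"
        )
    if equalized:
        # stable rank split: ties broken by voxel index, occupancies differ <= 1
        order = np.argsort(values, kind="stable")
        assignment = np.empty(n, dtype=int)
        groups = np.array_split(order, resolution)
        edges = np.empty(resolution + 1)
        edges[0] = values.min()
        edges[-1] = values.max()
        for b, grp in enumerate(groups):
            assignment[grp] = b
            if b > 0:
                prev_last = values[groups[b - 1][-1]]
                first = values[grp[0]]
                edges[b] = (prev_last + first) / 2.0
    else:
        lo, hi = values.min(), values.max()
        edges = np.linspace(lo, hi, resolution + 1)
        assignment = np.clip(
            np.searchsorted(edges[1:-1], values, side="right"), 0, resolution - 1
        )
    base = [(float(edges[b]), float(edges[b + 1])) for b in range(resolution)]
    expanded = []
    for lo, hi in base:
        c, half = (lo + hi) / 2.0, gain * (hi - lo) / 2.0
        expanded.append((c - half, c + half))
    return CoverAxis(resolution, float(gain), equalized, base, expanded, assignment)


def build_cover(
    lens: LensValues,
    resolution: tuple[int, ...] = (40, 30),
    gain: tuple[float, ...] = (2.5, 4.0),
    equalized: bool = True,
) -> Cover:
    """Build a product cover of the lens space.

    Per dimension, base intervals are equal-frequency (quantile) partitions
    into ``resolution`` bins (equal-width if ``equalized`` is False), then
    expanded about their centers to ``gain`` times the base width. The 2-D
    cover is the Cartesian product of the per-dimension interval lists;
    every voxel lies in at least its own base product bin.
    """
    kdim = lens.coords.shape[1]
    if len(resolution) != kdim or len(gain) != kdim:
        raise ValueError("resolution/gain must match the lens dimensionality")
    axes = [
        _cover_axis(lens.coords[:, d], int(resolution[d]), float(gain[d]), equalized)
        for d in range(kdim)
    ]
    return Cover(axes, lens)


def cluster_bin(
    member_indices: Sequence[int],
    D: DistanceMatrix,
    histogram_bins: int = 10,
) -> list[list[int]]:
    """Partition one cover bin's voxels by single linkage with a histogram cut.

    A single-linkage dendrogram is built on the restricted distance matrix
    and cut at the first empty bin of the merge-height histogram
    (``histogram_bins`` bins over [0, max merge height]) that follows a
    non-empty bin — the standard Mapper gap heuristic. With no such gap all
    members form one cluster; singleton bins yield one singleton cluster.
    """
    idx = list(map(int, member_indices))
    if not idx:
        raise ValueError("empty cover bin")
    if len(idx) == 1:
        return [idx]
    sub = D.restrict(idx)
    Z = linkage(squareform(sub, checks=False), method="single")
    heights = Z[:, 2]
    hmax = heights.max()
    if hmax <= 0:
        return [idx]
    hist, edges = np.histogram(heights, bins=histogram_bins, range=(0.0, hmax))
    threshold = None
    seen_data = False
    for b in range(histogram_bins):
        if hist[b] > 0:
            seen_data = True
        elif seen_data:
            threshold = edges[b]
            break
    if threshold is None:
        return [idx]
    flat = fcluster(Z, t=threshold, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for local, lab in enumerate(flat):
        clusters.setdefault(int(lab), []).append(idx[local])
    return [clusters[lab] for lab in sorted(clusters)]


def build_nerve(
    bin_partitions: dict[tuple[int, ...], list[list[int]]],
    voxel_ids: Sequence[str],
) -> MapperGraph:
    """Assemble the nerve graph from per-bin partitions.

    One node per (bin, in-bin cluster); an undirected edge joins two nodes
    exactly when their member sets intersect, weighted by the intersection
    size. No self-edges.
    """
    g = nx.Graph()
    members: list[frozenset[int]] = []
    for bin_id in sorted(bin_partitions):
        for cluster in bin_partitions[bin_id]:
            if not cluster:
                raise ValueError(f"empty cluster in bin {bin_id}")
            node = len(members)
            mem = frozenset(int(i) for i in cluster)
            members.append(mem)
            g.add_node(node, bin=bin_id, members=mem)
    # sweep voxel -> nodes to avoid the quadratic all-pairs intersection
    by_voxel: dict[int, list[int]] = {}
    for node, mem in enumerate(members):
        for v in mem:
            by_voxel.setdefault(v, []).append(node)
    for nodes in by_voxel.values():
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1)
    return MapperGraph(g, list(map(str, voxel_ids)))


def _community_sizes(graph: MapperGraph, comms: list[set[int]]) -> list[int]:
    return [len(frozenset().union(*(graph.node_members(n) for n in c))) for c in comms]


def _best_modularity_communities(
    g: nx.Graph, seed: int, restarts: int = 8
) -> list[set[int]]:
    """Best-of-restarts Louvain: highest-modularity partition over seeded
    runs (deterministic given seed; single runs can stall in local optima)."""
    if g.number_of_edges() == 0:
        return [{n} for n in g.nodes]
    best, best_q = None, -np.inf
    for i in range(restarts):
        comms = [set(c) for c in nx.community.louvain_communities(g, weight="weight", seed=seed + i)]
        q = nx.community.modularity(g, comms, weight="weight")
        if q > best_q + 1e-12:
            best, best_q = comms, q
    return best


def segment_nerve(
    graph: MapperGraph, k: int | None = None, seed: int = 0
) -> ClusterLabels:
    """Segment the nerve into voxel clusters.

    With ``k=None`` (automatic), nodes are grouped by seeded Louvain
    modularity communities on the weighted nerve, keeping the best
    modularity over several restarts. With ``k`` given, agglomerative
    modularity maximization (Clauset-Newman-Moore) is stopped at exactly k
    communities, i.e. the modularity-guided k-way split of the graph. Each
    voxel's label is the majority community over the nodes containing it;
    ties go to the community holding the largest node, then to the lowest
    community index. Final labels 1..K are ordered by decreasing community
    voxel count.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty mapper graph")
    if k is not None and k > g.number_of_nodes():
        raise ValueError(f"k={k} exceeds number of nodes ({g.number_of_nodes()})")
    if k is None:
        comms = _best_modularity_communities(g, seed)
    elif g.number_of_edges() == 0:
        # edgeless nerve carries no grouping information: deterministic
        # chunking of the sorted nodes
        comms = [set(c) for c in np.array_split(sorted(g.nodes), k)]
    else:
        comms = [
            set(c)
            for c in nx.community.greedy_modularity_communities(
                g, weight="weight", cutoff=k, best_n=k
            )
        ]
    # deterministic community order: by voxel count desc, then lowest node id
    sizes = _community_sizes(graph, comms)
    order = sorted(range(len(comms)), key=lambda i: (-sizes[i], min(comms[i])))
    comms = [comms[i] for i in order]
    node_comm = {n: ci for ci, c in enumerate(comms) for n in c}
    node_size = {n: len(graph.node_members(n)) for n in g.nodes}

    votes: dict[int, dict[int, int]] = {}
    for n in g.nodes:
        for v in graph.node_members(n):
            votes.setdefault(v, {}).setdefault(node_comm[n], 0)
            votes[v][node_comm[n]] += 1
    raw_label: dict[int, int] = {}
    for v, tally in votes.items():
        top = max(tally.values())
        tied = sorted(ci for ci, c in tally.items() if c == top)
        if len(tied) == 1:
            raw_label[v] = tied[0]
        else:
            # tie: community containing the largest node among this voxel's
            # nodes, then lowest community index
            best = max(
                (n for n in graph.nodes_of_voxel(v) if node_comm[n] in tied),
                key=lambda n: (node_size[n], -node_comm[n]),
            )
            raw_label[v] = node_comm[best]
    used = sorted(set(raw_label.values()))
    remap = {ci: i + 1 for i, ci in enumerate(used)}
    labels = {
        graph.voxel_ids[v]: remap[ci] for v, ci in raw_label.items()
    }
    missing = set(graph.voxel_ids) - set(labels)
    if missing:
        raise ValueError(f"voxels missing from every node: {sorted(missing)[:5]}")
    return ClusterLabels(labels)


def _drop_constant_genes(expr: ExpressionMatrix, axis: str) -> ExpressionMatrix:
    if axis != "gene":
        return expr
    sd = expr.values.std(axis=1)
    if np.all(sd > 0):
        return expr
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes are constant across voxels")
    return ExpressionMatrix(
        [g for g, k in zip(expr.gene_ids, keep) if k],
        list(expr.voxel_ids),
        expr.values[keep],
        expr.excluded_genes,
    )


@dataclass
class MapperParams:
    """Parameters of the full Mapper pipeline (defaults follow the original
    analysis: equalized covers at resolution 40 / gain 2.5x and resolution
    30 / gain 4x over the first two metric-SVD lenses of the
    norm-correlation metric)."""

    resolution: tuple[int, int] = (40, 30)
    gain: tuple[float, float] = (2.5, 4.0)
    equalized: bool = True
    histogram_bins: int = 10
    k: int | None = None
    seed: int = 0
    standardize_axis: str = "gene"


def run_mapper(
    expr: ExpressionMatrix, params: MapperParams | None = None
) -> tuple[MapperGraph, ClusterLabels]:
    """Run the full Mapper pipeline on a normalized expression matrix.

    Genes that are constant across all voxels (typically undetected ones)
    carry no information for the correlation metric and are dropped before
    standardization.
    """
    params = params or MapperParams()
    expr = _drop_constant_genes(expr, axis=params.standardize_axis)
    std = standardize_profiles(expr, axis=params.standardize_axis)
    D = pairwise_norm_correlation(std, expr.voxel_ids)
    n = D.n
    # resolution cannot exceed the number of distinct lens values at desk scale
    resolution = tuple(min(r, max(1, n)) for r in params.resolution)
    lens = metric_svd_lens(D, k=len(resolution))
    for dim in range(lens.coords.shape[1]):
        distinct = np.unique(lens.coords[:, dim]).size
        if resolution[dim] > distinct:
            resolution = tuple(
                min(r, distinct) if d == dim else r for d, r in enumerate(resolution)
            )
    cover = build_cover(lens, resolution=resolution, gain=params.gain, equalized=params.equalized)
    partitions = {
        bin_id: cluster_bin(members, D, histogram_bins=params.histogram_bins)
        for bin_id, members in cover.bin_members().items()
    }
    graph = build_nerve(partitions, expr.voxel_ids)
    labels = segment_nerve(graph, k=params.k, seed=params.seed)
    return graph, labels
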