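"""Back-projection of per-voxel quantities onto the section grid.

Each voxel occupies exactly one pixel of the section raster (no
interpolation or smoothing — the maps are raw voxel heatmaps, optionally
block-replicated for display). Continuous gene maps use the matplotlib
``viridis`` colormap scaled to the per-image maximum by default; categorical
cluster maps use a fixed palette echoing the original figures (cluster 1
red = ventricular zone, 2 green, 3 light blue, 4/5 dark blues).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy import ndimage

from .io import VoxelGrid
from .mapper import ClusterLabels
from .normalize import ExpressionMatrix

__all__ = ["VoxelImage", "project_gene", "project_clusters", "render", "CLUSTER_PALETTE"]

# fixed categorical palette (RGB), cycled for labels beyond its length
CLUSTER_PALETTE: list[tuple[int, int, int]] = [
    (214, 39, 40),   # red
    (44, 160, 44),   # green
    (107, 174, 214), # light blue
    (8, 48, 107),    # dark blue
    (66, 100, 198),  # second dark blue
    (255, 127, 14),
    (148, 103, 189),
    (140, 86, 75),
]
BACKGROUND_RGB = (230, 230, 230)


@dataclass
class VoxelImage:
    """A section raster: one voxel per pixel inside the tissue mask.

    ``array`` has the shape of the section's bounding box
    (rows x cols, offset by ``origin``); ``mask`` flags tissue pixels.
    ``kind`` is 'continuous' (expression values) or 'categorical' (labels).
    """

    section_id: str
    array: np.ndarray
    mask: np.ndarray
    kind: str
    origin: tuple[int, int]
    pitch_um: float = 50.0
    colormap: str = "viridis"

    def __post_init__(self) -> None:
        if self.array.shape != self.mask.shape:
            raise ValueError("array and mask shapes differ")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError("kind must be 'continuous' or 'categorical'")

    def value_at(self, row: int, col: int):
        """Look up the voxel value at absolute grid coordinates."""
        r, c = row - self.origin[0], col - self.origin[1]
        if not (0 <= r < self.array.shape[0] and 0 <= c < self.array.shape[1]) or not self.mask[r, c]:
            raise KeyError(f"no tissue voxel at ({row}, {col})")
        return self.array[r, c]


def _section_frame(grid: VoxelGrid, section: str):
    sub = grid.section_table(str(section))
    r0, c0 = int(sub["row"].min()), int(sub["col"].min())
    shape = (int(sub["row"].max()) - r0 + 1, int(sub["col"].max()) - c0 + 1)
    return sub, r0, c0, shape


def project_gene(
    expr: ExpressionMatrix, grid: VoxelGrid, gene: str, section: str
) -> VoxelImage:
    """Render one gene's per-million expression as a section image.

    Pixel (row, col) carries the gene's normalized value in the voxel at
    that grid position; positions without a voxel are background.
    """
    vec = expr.gene_vector(gene)  # raises KeyError on unknown gene
    by_voxel = dict(zip(expr.voxel_ids, vec))
    sub, r0, c0, shape = _section_frame(grid, section)
    array = np.zeros(shape, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    for _, rec in sub.iterrows():
        if rec.voxel_id not in by_voxel:
            raise KeyError(f"voxel {rec.voxel_id!r} missing from expression matrix")
        array[rec.row - r0, rec.col - c0] = by_voxel[rec.voxel_id]
        mask[rec.row - r0, rec.col - c0] = True
    return VoxelImage(str(section), array, mask, "continuous", (r0, c0), grid.pitch_um)


def project_clusters(
    labels: ClusterLabels, grid: VoxelGrid, section: str
) -> tuple[VoxelImage, dict[int, int]]:
    """Categorical cluster map of a section plus a contiguity report.

    Returns the label image and, per label, the number of 4-connected
    components it forms within the tissue mask — the quantitative version
    of "spatially distinct region".
    """
    sub, r0, c0, shape = _section_frame(grid, section)
    array = np.zeros(shape, dtype=int)
    mask = np.zeros(shape, dtype=bool)
    for _, rec in sub.iterrows():
        if rec.voxel_id not in labels.labels:
            raise ValueError(f"voxel {rec.voxel_id!r} in section {section!r} is unlabeled")
        array[rec.row - r0, rec.col - c0] = labels.labels[rec.voxel_id]
        mask[rec.row - r0, rec.col - c0] = True
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    report = {}
    for lab in sorted(set(array[mask])):
        _, n_comp = ndimage.label((array == lab) & mask, structure=structure)
        report[int(lab)] = int(n_comp)
    img = VoxelImage(str(section), array, mask, "categorical", (r0, c0), grid.pitch_um)
    return img, report


def _to_rgb(image: VoxelImage, vmin: float | None, vmax: float | None) -> np.ndarray:
    rgb = np.empty(image.array.shape + (3,), dtype=np.uint8)
    rgb[:] = BACKGROUND_RGB
    if image.kind == "categorical":
        for lab in sorted(set(image.array[image.mask])):
            color = CLUSTER_PALETTE[(int(lab) - 1) % len(CLUSTER_PALETTE)]
            rgb[(image.array == lab) & image.mask] = color
    else:
        lo = 0.0 if vmin is None else float(vmin)
        hi = float(image.array[image.mask].max()) if vmax is None else float(vmax)
        span = hi - lo if hi > lo else 1.0
        cmap = colormaps[image.colormap]
        scaled = np.clip((image.array - lo) / span, 0.0, 1.0)
        colors = (cmap(scaled)[..., :3] * 255).round().astype(np.uint8)
        rgb[image.mask] = colors[image.mask]
    return rgb


def render(
    image: VoxelImage,
    path: str | Path,
    scale: int = 1,
    vmin: float | None = None,
    vmax: float | None = None,
) -> Path:
    """Write the image as a PNG with scale x scale pixel blocks per voxel.

    Continuous images map values through the image's colormap between
    ``vmin`` (default 0) and ``vmax`` (default the per-image maximum over
    the mask); categorical images use the fixed palette. Output bytes are
    deterministic for identical inputs.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    rgb = _to_rgb(image, vmin, vmax)
    if scale > 1:
        rgb = np.kron(rgb, np.ones((scale, scale, 1), dtype=np.uint8))
    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return path
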