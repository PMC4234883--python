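"""Reading and writing of count matrices, voxel layouts, labels and marker tables.

On-disk conventions
-------------------
Count matrices are genes x voxels. The canonical TSV dialect is
tab-separated UTF-8 with no quoting: header cell (1,1) is the literal
``gene``, remaining header cells are voxel ids, and each subsequent row is a
gene id followed by integer counts. MatrixMarket (``.mtx``) matrices carry
two sidecar files, ``<stem>.genes.txt`` and ``<stem>.voxels.txt``, one id
per line. Voxel layouts are CSV with columns
``voxel_id,section_id,row,col``; grid coordinates are 0-based, row
increasing ventrally (downward in the rendered image) and col laterally
(rightward). Voxels absent from the layout are dropped from analysis —
the tissue mask is irregular, so missing positions are real, not holes to
impute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "VoxelGrid",
    "ParseError",
    "read_count_matrix",
    "write_count_matrix",
    "read_voxel_layout",
    "write_voxel_layout",
    "align",
    "load_geo_series_matrix",
    "read_labels",
    "write_labels",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or field."""


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x voxels.

    Each column is one laser-microdissected 50 um voxel (~100 cells)
    profiled as a single RNA-seq sample.
    """

    gene_ids: list[str]
    voxel_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.voxel_ids = [str(v) for v in self.voxel_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.voxel_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.voxel_ids)} voxels"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.voxel_ids)) != len(self.voxel_ids):
            raise ValueError("duplicate voxel ids")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("negative count")
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    def subset_voxels(self, voxel_ids: list[str]) -> "CountMatrix":
        idx = {v: i for i, v in enumerate(self.voxel_ids)}
        cols = [idx[v] for v in voxel_ids]
        return CountMatrix(list(self.gene_ids), list(voxel_ids), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.voxel_ids)


@dataclass
class VoxelGrid:
    """Maps voxel ids to (section, row, col) positions on a regular grid.

    The set of listed voxels IS the tissue mask; positions inside the
    bounding rectangle but not listed are background.
    """

    table: pd.DataFrame  # columns: voxel_id, section_id, row, col
    pitch_um: float = 50.0

    def __post_init__(self) -> None:
        required = ["voxel_id", "section_id", "row", "col"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"layout missing columns: {missing}")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be > 0")
        t = self.table[required].copy()
        t["voxel_id"] = t["voxel_id"].astype(str)
        t["section_id"] = t["section_id"].astype(str)
        for c in ("row", "col"):
            vals = t[c]
            if not np.all(np.equal(np.mod(pd.to_numeric(vals), 1), 0)):
                raise ValueError(f"non-integer {c} coordinate")
            t[c] = pd.to_numeric(vals).astype(int)
            if (t[c] < 0).any():
                raise ValueError(f"negative {c} coordinate")
        if t["voxel_id"].duplicated().any():
            dup = t.loc[t["voxel_id"].duplicated(), "voxel_id"].iloc[0]
            raise ValueError(f"duplicate voxel_id {dup!r}")
        pos_dup = t.duplicated(subset=["section_id", "row", "col"])
        if pos_dup.any():
            r = t.loc[pos_dup].iloc[0]
            raise ValueError(
                f"duplicate position ({r.section_id}, {r.row}, {r.col})"
            )
        self.table = t.reset_index(drop=True)

    @property
    def voxel_ids(self) -> list[str]:
        return self.table["voxel_id"].tolist()

    def sections(self) -> list[str]:
        return list(dict.fromkeys(self.table["section_id"]))

    def section_table(self, section_id: str) -> pd.DataFrame:
        sub = self.table[self.table["section_id"] == str(section_id)]
        if sub.empty:
            raise KeyError(f"unknown section {section_id!r}")
        return sub

    def position(self, voxel_id: str) -> tuple[str, int, int]:
        row = self.table[self.table["voxel_id"] == str(voxel_id)]
        if row.empty:
            raise KeyError(f"unknown voxel {voxel_id!r}")
        r = row.iloc[0]
        return r.section_id, int(r.row), int(r.col)

    def subset(self, voxel_ids: list[str]) -> "VoxelGrid":
        keep = self.table[self.table["voxel_id"].isin(set(voxel_ids))]
        order = pd.CategoricalIndex(keep["voxel_id"], categories=voxel_ids, ordered=True)
        keep = keep.iloc[order.argsort()]
        return VoxelGrid(keep.reset_index(drop=True), self.pitch_um)


def read_count_matrix(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a genes x voxels count matrix from TSV or MatrixMarket MTX.

    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "mtx":
        return _read_mtx(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> CountMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cells = header.split("\t")
        if len(cells) < 2 or cells[0] != "gene":
            raise ParseError(f"{path}:1: malformed header (expected 'gene\\t<voxel ids>')")
        voxel_ids = cells[1:]
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cells):
                raise ParseError(f"{path}:{lineno}: expected {len(cells)} fields, got {len(parts)}")
            gene_ids.append(parts[0])
            try:
                vals = [int(x) for x in parts[1:]]
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer count ({e})") from None
            if any(v < 0 for v in vals):
                raise ParseError(f"{path}:{lineno}: negative count")
            rows.append(vals)
    counts = np.array(rows, dtype=np.int64).reshape(len(gene_ids), len(voxel_ids))
    try:
        return CountMatrix(gene_ids, voxel_ids, counts)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from None


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.voxels.txt")


def _read_mtx(path: Path) -> CountMatrix:
    genes_path, voxels_path = _sidecars(path)
    for p in (genes_path, voxels_path):
        if not p.exists():
            raise ParseError(f"missing sidecar file {p}")
    gene_ids = genes_path.read_text(encoding="utf-8").splitlines()
    voxel_ids = voxels_path.read_text(encoding="utf-8").splitlines()
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    try:
        return CountMatrix(gene_ids, voxel_ids, np.asarray(mat))
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from None


def write_count_matrix(counts: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write in the canonical TSV dialect (byte-stable) or MatrixMarket MTX."""
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene\t" + "\t".join(counts.voxel_ids) + "\n")
            for g, row in zip(counts.gene_ids, counts.counts):
                fh.write(g + "\t" + "\t".join(str(int(x)) for x in row) + "\n")
    elif format == "mtx":
        genes_path, voxels_path = _sidecars(path)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.counts))
        genes_path.write_text("\n".join(counts.gene_ids) + "\n", encoding="utf-8")
        voxels_path.write_text("\n".join(counts.voxel_ids) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_voxel_layout(path: str | Path, pitch_um: float = 50.0) -> VoxelGrid:
    """Read a voxel layout CSV (voxel_id, section_id, row, col)."""
    try:
        table = pd.read_csv(path, dtype={"voxel_id": str, "section_id": str})
    except Exception as e:  # pandas raises several parser exception types
        raise ParseError(f"{path}: {e}") from None
    try:
        return VoxelGrid(table, pitch_um=pitch_um)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from None


def write_voxel_layout(grid: VoxelGrid, path: str | Path) -> None:
    grid.table.to_csv(path, index=False)


def align(counts: CountMatrix, grid: VoxelGrid) -> tuple[CountMatrix, VoxelGrid]:
    """Restrict counts and layout to their shared voxels, ordered identically.

    Voxels present in only one input are dropped with a logged warning;
    an empty intersection is an error. Idempotent.
    """
    layout_ids = set(grid.voxel_ids)
    shared = [v for v in counts.voxel_ids if v in layout_ids]
    if not shared:
        raise ValueError("no voxels shared between count matrix and layout")
    only_counts = [v for v in counts.voxel_ids if v not in layout_ids]
    only_layout = [v for v in grid.voxel_ids if v not in set(counts.voxel_ids)]
    if only_counts:
        logger.warning("dropping %d voxel(s) absent from layout: %s", len(only_counts), only_counts[:5])
    if only_layout:
        logger.warning("dropping %d voxel(s) absent from counts: %s", len(only_layout), only_layout[:5])
    return counts.subset_voxels(shared), grid.subset(shared)


def load_geo_series_matrix(path: str | Path) -> CountMatrix:
    """Parse a GEO series-matrix export into a CountMatrix.

    Accepts the standard layout: ``!``-prefixed metadata lines, then a table
    delimited by ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
    whose header is ``"ID_REF"`` followed by quoted sample ids. Also accepts
    a bare processed genes x samples table (header line starting with ID_REF
    or gene) as deposited in some supplementary files.
    """
    path = Path(path)
    gene_ids: list[str] = []
    rows: list[list[int]] = []
    voxel_ids: list[str] | None = None
    in_table = False
    saw_end = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                saw_end = True
                break
            if line.startswith("!") or line.startswith("#"):
                continue
            parts = [p.strip().strip('"') for p in line.split("\t")]
            if voxel_ids is None:
                if parts[0] not in ("ID_REF", "gene", "Gene", "GENE"):
                    raise ParseError(f"{path}:{lineno}: unrecognized header line {line[:60]!r}")
                voxel_ids = parts[1:]
                if not voxel_ids:
                    raise ParseError(f"{path}:{lineno}: header has no sample columns")
                continue
            if len(parts) != len(voxel_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(voxel_ids) + 1} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            try:
                vals = [float(x) for x in parts[1:]]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from None
            if any(v < 0 for v in vals):
                raise ParseError(f"{path}:{lineno}: negative count")
            if any(v != int(v) for v in vals):
                raise ParseError(f"{path}:{lineno}: non-integer count")
            rows.append([int(v) for v in vals])
    if voxel_ids is None or not rows:
        raise ParseError(f"{path}: no expression table found")
    if in_table and not saw_end:
        raise ParseError(f"{path}: truncated file (missing !series_matrix_table_end)")
    try:
        return CountMatrix(gene_ids, voxel_ids, np.array(rows, dtype=np.int64))
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from None


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a voxel_id -> cluster label TSV (two columns, with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"voxel_id": str})
    if "voxel_id" not in df.columns or "label" not in df.columns:
        raise ParseError(f"{path}: expected columns voxel_id, label")
    return dict(zip(df["voxel_id"], df["label"].astype(int)))


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"voxel_id": list(labels), "label": [labels[v] for v in labels]}
    ).to_csv(path, sep="\t", index=False)
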