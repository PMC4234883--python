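"""Per-million normalization of voxel read counts.

Raw STRT read counts are converted to reads per million by dividing each
gene's count by the voxel's total reads over included genes (repeat-derived
genes may be excluded from both the denominator and the output, mirroring
how the source protocol drops repeats from its mapped-read total). Each
voxel column of the result sums to 1e6 unless the voxel had no included
reads at all, in which case the column is zero and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "normalize_per_million", "detected_genes_per_voxel", "DetectionSummary"]

SCALE = 1_000_000.0


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x voxels, in reads per million."""

    gene_ids: list[str]
    voxel_ids: list[str]
    values: np.ndarray
    excluded_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.voxel_ids)):
            raise ValueError("values shape inconsistent with id lists")
        if values.size and values.min() < 0:
            raise ValueError("negative expression value")
        self.values = values
        self.excluded_genes = frozenset(self.excluded_genes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    def gene_vector(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(str(gene_id))
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.voxel_ids)


def normalize_per_million(
    counts: CountMatrix, exclude: set[str] | None = None
) -> ExpressionMatrix:
    """Scale each voxel's counts to reads per million over included genes.

    Parameters
    ----------
    counts
        Raw integer counts, genes x voxels.
    exclude
        Gene ids omitted from the scaling denominator and from the output
        (e.g. repeat-derived annotations). Must be a subset of the matrix's
        gene ids.

    Returns
    -------
    ExpressionMatrix whose included-gene columns each sum to 1e6, except
    voxels with zero included reads, which come back all-zero (logged).
    """
    exclude = set(map(str, exclude or ()))
    unknown = exclude - set(counts.gene_ids)
    if unknown:
        raise ValueError(f"exclusion list contains unknown gene ids: {sorted(unknown)[:5]}")
    keep = [g for g in counts.gene_ids if g not in exclude]
    if not keep:
        raise ValueError("exclusion list removes all genes")
    keep_idx = [i for i, g in enumerate(counts.gene_ids) if g not in exclude]
    sub = counts.counts[keep_idx, :].astype(float)
    totals = sub.sum(axis=0)
    zero = totals == 0
    if zero.any():
        dead = [v for v, z in zip(counts.voxel_ids, zero) if z]
        logger.warning("%d voxel(s) with zero included reads left all-zero: %s", len(dead), dead[:5])
    safe = np.where(zero, 1.0, totals)
    values = sub * (SCALE / safe)
    values[:, zero] = 0.0
    return ExpressionMatrix(keep, list(counts.voxel_ids), values, frozenset(exclude))


@dataclass
class DetectionSummary:
    """Per-voxel detected-gene counts plus dataset-level summaries."""

    per_voxel: pd.Series  # index voxel_id, value n detected genes
    mean_detected: float
    union_detected: int  # genes detected in >=1 voxel


def detected_genes_per_voxel(counts: CountMatrix, min_reads: int = 1) -> DetectionSummary:
    """Count genes with >= min_reads reads in each voxel.

    Also reports the mean across voxels and the number of genes detected in
    at least one voxel (the dataset's expressed-gene count).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    detected = counts.counts >= min_reads
    per_voxel = pd.Series(detected.sum(axis=0), index=counts.voxel_ids, name="n_detected")
    union = int(detected.any(axis=1).sum())
    return DetectionSummary(per_voxel, float(per_voxel.mean()) if len(per_voxel) else 0.0, union)
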