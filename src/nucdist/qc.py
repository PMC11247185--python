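"""Quality control and pseudonegative-control construction.

A pseudonegative control is a cell-type-restricted subset of a real (or
simulated) data set: within one labeled type, biological heterogeneity is
reduced, so the residual gene-level variation upper-bounds the technical
measurement error the count models of :mod:`nucdist.distributions` are
meant to capture.

Filtering order in :func:`qc_pipeline` is cells first, then genes; the
order matters because removing cells can empty gene rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import EmptyMatrixError, UMICountMatrix

#: Package defaults; real analyses should set thresholds per data set.
DEFAULT_MIN_LIBRARY_SIZE = 100
DEFAULT_MIN_EXPRESSED_GENES = 100


@dataclass(frozen=True)
class QCThresholds:
    min_library_size: int = DEFAULT_MIN_LIBRARY_SIZE
    min_expressed_genes: int = DEFAULT_MIN_EXPRESSED_GENES

    def __post_init__(self) -> None:
        if self.min_library_size < 0 or self.min_expressed_genes < 0:
            raise ValueError("QC thresholds must be >= 0")


def filter_cells(m: UMICountMatrix, thresholds: QCThresholds) -> UMICountMatrix:
    """Keep cells with library size AND detected-gene count above threshold."""
    keep = (m.library_sizes >= thresholds.min_library_size) & (
        m.genes_detected >= thresholds.min_expressed_genes
    )
    if not keep.any():
        raise EmptyMatrixError(
            f"no cells pass QC (min_library_size={thresholds.min_library_size}, "
            f"min_expressed_genes={thresholds.min_expressed_genes})"
        )
    return m.select_cells(keep)


def drop_zero_genes(m: UMICountMatrix) -> UMICountMatrix:
    """Discard genes with zero counts across all cells; order preserved."""
    return m.select_genes(m.gene_totals > 0)


def subset_by_celltype(m: UMICountMatrix, celltype: str) -> UMICountMatrix:
    """Restrict to cells of one labeled type, then drop now-empty genes."""
    if m.labels is None:
        raise ValueError("matrix has no cell-type labels")
    available = sorted(set(m.labels))
    if celltype not in available:
        raise ValueError(
            f"unknown cell type {celltype!r}; available: {available}"
        )
    keep = (m.labels.values == celltype)
    return drop_zero_genes(m.select_cells(np.asarray(keep)))


def qc_pipeline(
    m: UMICountMatrix,
    thresholds: QCThresholds | None = None,
    celltype: str | None = None,
) -> UMICountMatrix:
    """Cells-then-genes QC, optionally followed by a cell-type subset."""
    out = filter_cells(m, thresholds or QCThresholds())
    out = drop_zero_genes(out)
    if celltype is not None:
        out = subset_by_celltype(out, celltype)
    return out
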