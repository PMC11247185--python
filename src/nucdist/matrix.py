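"""Sparse UMI count matrix container.

The matrix is stored gene x cell (rows are genes), matching the orientation
of the 10x MatrixMarket triplet on disk. Library size ``s_c`` of a cell is
its column sum and is the offset used by every count model in
:mod:`nucdist.distributions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class EmptyMatrixError(ValueError):
    """Raised when an operation would produce or received an empty matrix."""


@dataclass
class UMICountMatrix:
    """Gene x cell matrix of nonnegative integer UMI counts.

    Parameters
    ----------
    counts
        Sparse (or dense, coerced to CSR) gene x cell count matrix.
    gene_ids
        Unique gene identifiers, one per row.
    barcodes
        Unique cell barcodes, one per column.
    labels
        Optional cell-type label per barcode (pandas Series indexed by
        barcode, or any mapping barcode -> label).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.data.size and not np.allclose(
            self.counts.data, np.round(self.counts.data)
        ):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.counts.eliminate_zeros()
        if self.counts.data.size and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"shape mismatch: counts {self.counts.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if self.labels is not None:
            labels = pd.Series(self.labels)
            missing = [b for b in self.barcodes if b not in labels.index]
            if missing:
                raise ValueError(f"labels missing for barcodes: {missing[:5]}")
            self.labels = labels.reindex(self.barcodes)

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-cell total UMIs (column sums), the offset s_c."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    @property
    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with nonzero count."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    @property
    def gene_totals(self) -> np.ndarray:
        """Per-gene total counts across all cells (row sums)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    # -- subsetting ------------------------------------------------------
    def select_genes(self, index) -> "UMICountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return UMICountMatrix(
            counts=self.counts[index, :],
            gene_ids=self.gene_ids[index],
            barcodes=self.barcodes,
            labels=self.labels,
        )

    def select_cells(self, index) -> "UMICountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        barcodes = self.barcodes[index]
        labels = self.labels.reindex(barcodes) if self.labels is not None else None
        return UMICountMatrix(
            counts=self.counts[:, index],
            gene_ids=self.gene_ids,
            barcodes=barcodes,
            labels=labels,
        )

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def to_anndata(self):
        """Cells x genes AnnData view of the matrix (transposed convention)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        if self.labels is not None:
            adata.obs["celltype"] = self.labels.values
        return adata
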