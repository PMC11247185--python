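"""Marker-based cell-type annotation and label concordance.

A deliberately minimal reference-based annotator: each cell is compared to
per-type mean-expression profiles by Spearman correlation over the union
of marker genes, labeled with the best-correlated type, and left
"unassigned" when the margin between the best and second-best correlation
falls below a pruning threshold. This is the rank-correlation core of
reference-based annotators (without iterative fine-tuning), sufficient to
measure how quantification choices shift label assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import UMICountMatrix

UNASSIGNED = "unassigned"


@dataclass
class MarkerSet:
    """Cell type -> marker gene ids."""

    markers: Dict[str, List[str]]

    def __post_init__(self) -> None:
        for ct, genes in self.markers.items():
            if not genes:
                raise ValueError(f"marker list for {ct!r} is empty")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "MarkerSet":
        """Build from a (celltype, gene_id) long table."""
        grouped = table.groupby("celltype")["gene_id"].apply(list).to_dict()
        return cls(grouped)

    def resolve(self, gene_ids: Sequence[str]) -> "MarkerSet":
        """Drop markers absent from the matrix, warning about them."""
        present = set(gene_ids)
        resolved = {}
        dropped = []
        for ct, genes in self.markers.items():
            kept = [g for g in genes if g in present]
            dropped += [g for g in genes if g not in present]
            if not kept:
                raise ValueError(f"no markers of {ct!r} found in the matrix")
            resolved[ct] = kept
        if dropped:
            warnings.warn(
                f"{len(dropped)} marker gene(s) not in matrix, dropped: "
                f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                stacklevel=2,
            )
        return MarkerSet(resolved)

    @property
    def union(self) -> List[str]:
        seen: Dict[str, None] = {}
        for genes in self.markers.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)


def marker_ratio(
    m: UMICountMatrix,
    markers_num: Sequence[str],
    markers_den: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-cell ratio of UMI counts in one marker set over another.

    (sum over numerator markers + pseudocount) / (sum over denominator
    markers + pseudocount); the pseudocount guards against empty
    denominators.
    """
    index = {g: i for i, g in enumerate(m.gene_ids)}
    num_idx = [index[g] for g in markers_num if g in index]
    den_idx = [index[g] for g in markers_den if g in index]
    if not num_idx or not den_idx:
        raise ValueError("marker lists must resolve to at least one gene each")
    num = np.asarray(m.counts[num_idx, :].sum(axis=0)).ravel()
    den = np.asarray(m.counts[den_idx, :].sum(axis=0)).ravel()
    return pd.Series(
        (num + pseudocount) / (den + pseudocount),
        index=pd.Index(m.barcodes, name="barcode"),
        name="marker_ratio",
    )


def reference_profiles_from_labels(m: UMICountMatrix) -> pd.DataFrame:
    """Per-type mean expression profiles (genes x types) from labeled data."""
    if m.labels is None:
        raise ValueError("matrix has no labels")
    profiles = {}
    labels = m.labels.values
    for ct in sorted(set(labels)):
        cols = np.flatnonzero(labels == ct)
        profiles[ct] = np.asarray(m.counts[:, cols].mean(axis=1)).ravel()
    return pd.DataFrame(profiles, index=pd.Index(m.gene_ids, name="gene_id"))


def spearman_annotate(
    m: UMICountMatrix,
    reference_profiles: pd.DataFrame,
    markers: MarkerSet | Mapping[str, List[str]],
    prune_delta: float = 0.05,
) -> pd.Series:
    """Assign each cell the reference type with the highest Spearman
    correlation over the marker-gene union; prune ambiguous labels.

    A cell is left ``unassigned`` when (best - second best) correlation is
    below ``prune_delta``, or when its expression over the marker union is
    constant (rank correlation undefined).
    """
    if not isinstance(markers, MarkerSet):
        markers = MarkerSet(dict(markers))
    if reference_profiles.shape[1] < 2:
        raise ValueError("need at least 2 reference types")
    markers = markers.resolve(m.gene_ids)
    union = [g for g in markers.union if g in set(reference_profiles.index)]
    if not union:
        raise ValueError("marker union does not overlap the reference profiles")
    index = {g: i for i, g in enumerate(m.gene_ids)}
    rows = [index[g] for g in union]
    x = m.counts[rows, :].toarray().astype(float)  # markers x cells
    ref = reference_profiles.loc[union]  # markers x types

    # rank once (average ranks for ties), correlate ranks by Pearson
    ref_ranks = rankdata(ref.to_numpy(), axis=0)
    ref_ranks = (ref_ranks - ref_ranks.mean(axis=0)) / ref_ranks.std(axis=0)
    n_constant = 0
    labels = []
    types = list(ref.columns)
    for j in range(x.shape[1]):
        v = x[:, j]
        if np.all(v == v[0]):
            n_constant += 1
            labels.append(UNASSIGNED)
            continue
        r = rankdata(v)
        r = (r - r.mean()) / r.std()
        cors = r @ ref_ranks / len(union)
        order = np.argsort(cors)[::-1]
        best, second = cors[order[0]], cors[order[1]]
        labels.append(UNASSIGNED if best - second < prune_delta else types[order[0]])
    if n_constant:
        warnings.warn(
            f"{n_constant} cell(s) constant over the marker union: unassigned",
            stacklevel=2,
        )
    return pd.Series(
        labels, index=pd.Index(m.barcodes, name="barcode"), name="assigned"
    )


def concordance(
    labels_ref: pd.Series,
    labels_assigned: pd.Series,
    merge_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Cross-tabulate reference labels (rows) vs assigned labels (columns).

    ``merge_map`` renames labels before tabulation (e.g. collapsing
    excitatory and inhibitory neurons into one "Neurons" type); it applies
    to both label sets. The table always carries an explicit
    ``unassigned`` column.
    """
    ref = pd.Series(labels_ref)
    asn = pd.Series(labels_assigned)
    if set(ref.index) != set(asn.index):
        raise ValueError("reference and assigned labels cover different cells")
    asn = asn.reindex(ref.index)
    if merge_map:
        ref = ref.replace(dict(merge_map))
        asn = asn.replace(dict(merge_map))
    table = pd.crosstab(ref, asn)
    if UNASSIGNED not in table.columns:
        table[UNASSIGNED] = 0
    table.index.name = "reference"
    table.columns.name = "assigned"
    return table
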