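"""Gene-length bias diagnostics.

Two gene lengths are distinguished: the "preandmrna" length (full genomic
span of the gene, exons + introns) and the "transcript" length (exonic
bases only); both are summarized per gene as the maximum over its
isoforms. Genes are binned into equal-count length bins and the
distribution of total counts per bin is summarized by quartiles; overall
bias strength is the Pearson correlation of log10 totals vs log10 length.

Internal poly-A detection counts maximal A-runs of at least n bases in
every spliced and unspliced transcript sequence and takes the gene-level
maximum; genes are then dichotomized by "has at least one internal poly-A
n-mer" vs none — the stratification used to separate internal-priming
signal from residual length bias.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genes import GeneModelSet
from .matrix import UMICountMatrix
from .reference import spliced_transcript_sequences, unspliced_transcript_sequences

POLYA_NMER_SIZES = (6, 8, 10, 12)


def gene_lengths(models: GeneModelSet) -> pd.DataFrame:
    """Per-gene preandmrna (span) and transcript (exonic) lengths.

    Per transcript the unspliced length is last exon end minus first exon
    start and the spliced length is the sum of exon lengths; both are
    summarized per gene as the maximum over its transcripts.
    """
    rows = []
    for gid, gene in models.genes.items():
        pre = max(
            exons[-1][1] - exons[0][0] for exons in gene.transcripts.values()
        )
        tx = max(
            sum(e - s for s, e in exons) for exons in gene.transcripts.values()
        )
        rows.append((gid, pre, tx))
    df = pd.DataFrame(
        rows, columns=["gene_id", "preandmrna_length", "transcript_length"]
    ).set_index("gene_id")
    return df.sort_index()


def total_gene_counts(m: UMICountMatrix) -> pd.Series:
    """Per-gene total counts summed across all cells."""
    return pd.Series(
        m.gene_totals, index=pd.Index(m.gene_ids, name="gene_id"), name="total"
    )


def bin_by_length(lengths: pd.Series, n_bins: int = 10) -> pd.Series:
    """Assign genes to equal-count bins by ascending length (1 = shortest).

    Bin sizes differ by at most one (the first G mod n_bins bins take the
    extra gene); ties in length are broken by gene id so the assignment is
    deterministic.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    g = len(lengths)
    if n_bins > g:
        raise ValueError(f"n_bins ({n_bins}) exceeds number of genes ({g})")
    ids = lengths.index.to_numpy(dtype=object)
    order = np.lexsort((ids.astype(str), lengths.to_numpy()))
    base, extra = divmod(g, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:extra] += 1
    bin_sorted = np.repeat(np.arange(1, n_bins + 1), sizes)
    bins = np.empty(g, dtype=np.int64)
    bins[order] = bin_sorted
    return pd.Series(bins, index=lengths.index, name="bin_id")


def bin_summary(totals: pd.Series, bin_ids: pd.Series) -> pd.DataFrame:
    """Median and quartiles (linear interpolation) of totals per bin."""
    df = pd.DataFrame({"total": totals, "bin_id": bin_ids})
    if df["total"].isna().any() or df["bin_id"].isna().any():
        raise ValueError("totals and bin_ids must align without missing values")
    out = (
        df.groupby("bin_id")["total"]
        .agg(
            median="median",
            q25=lambda v: np.percentile(v, 25),
            q75=lambda v: np.percentile(v, 75),
            n_genes="size",
        )
        .reset_index()
    )
    if (out["n_genes"] == 0).any():
        raise ValueError("empty length bin")
    return out


def polyA_nmer_count(sequence: str, n: int, convention: str = "runs") -> int:
    """Count internal poly-A n-mers in a sequence.

    ``runs`` (default) counts maximal runs of consecutive A of length >= n
    — the natural unit for the "has at least one internal poly-A n-mer"
    dichotomy. ``windows`` counts every (overlapping) window of n A's, so a
    run of length L contributes L - n + 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    runs = re.findall(f"A{{{n},}}", sequence.upper())
    if convention == "runs":
        return len(runs)
    if convention == "windows":
        return sum(len(r) - n + 1 for r in runs)
    raise ValueError(f"unknown convention {convention!r}")


def gene_polyA_max(
    models: GeneModelSet,
    genome: Mapping[str, str],
    n: int,
    convention: str = "runs",
) -> pd.Series:
    """Per-gene maximum poly-A n-mer count over all spliced and unspliced
    transcript sequences."""
    spliced = spliced_transcript_sequences(models, genome)
    unspliced = unspliced_transcript_sequences(models, genome)
    best: dict = {gid: 0 for gid in models.genes}
    for entry in list(spliced.entries) + list(unspliced.entries):
        cnt = polyA_nmer_count(entry.sequence, n, convention)
        if cnt > best[entry.gene_id]:
            best[entry.gene_id] = cnt
    return pd.Series(best, name=f"polyA_max_{n}").rename_axis("gene_id").sort_index()


@dataclass
class CorrelationResult:
    r: float
    n_used: int
    n_excluded: int  # zero-total genes left out of the log-scale correlation


def log_length_correlation(totals, lengths) -> CorrelationResult:
    """Pearson r of log10(total) vs log10(length) over expressed genes.

    Genes with zero total are excluded (log10 undefined); their count is
    reported in the result.
    """
    totals = np.asarray(totals, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if totals.shape != lengths.shape:
        raise ValueError("totals and lengths must align")
    keep = totals > 0
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError(f"need >= 3 genes with positive totals, have {n_used}")
    r = float(
        np.corrcoef(np.log10(totals[keep]), np.log10(lengths[keep]))[0, 1]
    )
    return CorrelationResult(r=r, n_used=n_used, n_excluded=int((~keep).sum()))


def trend_curve(
    x_lengths,
    y_totals,
    span: float = 0.75,
    grid: Optional[np.ndarray] = None,
    n_grid: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """Loess-style trend: local linear regression with tricube weights.

    Inputs are expected on the log10-log10 scale already. Returns (grid,
    fitted) with the curve evaluated on an even grid over the x-range.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    x = np.asarray(x_lengths, dtype=float)
    y = np.asarray(y_totals, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for a trend curve")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = lowess(y, x, frac=span, it=0, xvals=np.asarray(grid, dtype=float))
    return np.asarray(grid, dtype=float), np.asarray(fitted, dtype=float)


@dataclass
class LengthBiasResult:
    per_gene: pd.DataFrame  # lengths, total, bin_id, polyA_max, has_polyA
    per_bin: pd.DataFrame  # bin_id, median, q25, q75, n_genes
    pearson_r_preandmrna: float
    pearson_r_transcript: float
    n_zero_excluded: int
    nmer: int


def length_bias_analysis(
    m: UMICountMatrix,
    models: GeneModelSet,
    genome: Mapping[str, str],
    nmer: int = 8,
    n_bins: int = 10,
) -> LengthBiasResult:
    """Full length-bias workup for one count matrix + annotation.

    Genes present in both the matrix and the annotation are analyzed:
    lengths on both definitions, equal-count binning by preandmrna length,
    per-bin quartiles of total counts, per-gene internal poly-A maxima,
    and log-scale Pearson correlations against both length definitions.
    """
    lens = gene_lengths(models)
    totals = total_gene_counts(m)
    shared = lens.index.intersection(totals.index)
    if len(shared) < max(3, n_bins):
        raise ValueError(
            f"only {len(shared)} genes shared between matrix and annotation"
        )
    df = lens.loc[shared].copy()
    df["total"] = totals.loc[shared]
    df["bin_id"] = bin_by_length(df["preandmrna_length"], n_bins)
    polya = gene_polyA_max(models, genome, nmer)
    df["polyA_max"] = polya.reindex(shared).fillna(0).astype(int)
    df["has_polyA"] = df["polyA_max"] >= 1
    per_bin = bin_summary(df["total"], df["bin_id"])
    r_pre = log_length_correlation(df["total"], df["preandmrna_length"])
    r_tx = log_length_correlation(df["total"], df["transcript_length"])
    return LengthBiasResult(
        per_gene=df,
        per_bin=per_bin,
        pearson_r_preandmrna=r_pre.r,
        pearson_r_transcript=r_tx.r,
        n_zero_excluded=r_pre.n_excluded,
        nmer=nmer,
    )
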