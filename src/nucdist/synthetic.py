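"""Seeded synthetic inputs with the statistical structure the analyses assume.

Four generators cover the pipeline's input surface:

- :func:`simulate_counts` — gene x cell UMI matrices under binomial /
  Poisson / NB / gene-wise NB / zero-inflated NB sampling with
  heterogeneous library sizes and gamma-distributed gene abundances;
- :func:`simulate_annotation` — small multi-isoform gene models over
  random genomes, with controllable intron lengths and optional internal
  poly-A tract insertion;
- :func:`simulate_length_bias_totals` — per-gene totals with a log-linear
  length effect;
- :func:`simulate_celltype_mixture` — a labeled mixture of cell types with
  marker genes elevated by a known fold change.

Every generator is a pure function of its config + seed (bit-identical
reruns). Simulation truth (abundances, dispersions, size factors) is
returned alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genes import GeneModel, GeneModelSet
from .matrix import UMICountMatrix

COUNT_MODELS = ("binomial", "poisson", "nb", "nb_genewise", "zinb")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimCountConfig:
    """Conditions for a synthetic UMI count matrix.

    ``mean_library_size`` and ``libsize_cv`` set a lognormal distribution
    of per-cell totals; ``abundance_shape`` is the gamma shape of the gene
    relative-abundance profile (normalized to sum 1; shape 1 gives the
    standard heavy-tailed exponential profile); ``phi`` is the NB
    dispersion in Var = mu + mu^2/phi (for ``nb_genewise``, per-gene phi_g
    are lognormal around phi with log-sd ``genewise_phi_logsd``);
    ``zero_inflation_pi`` is the structural-zero probability and is only
    meaningful for the ``zinb`` model.
    """

    n_genes: int
    n_cells: int
    model: str = "nb"
    mean_library_size: float = 5000.0
    libsize_cv: float = 0.3
    abundance_shape: float = 1.0
    phi: float = 1.0
    genewise_phi_logsd: float = 0.5
    zero_inflation_pi: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        if self.model not in COUNT_MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {COUNT_MODELS}")
        if self.mean_library_size <= 0 or self.abundance_shape <= 0:
            raise ValueError("mean_library_size and abundance_shape must be > 0")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be >= 0")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.zero_inflation_pi is not None:
            if self.model != "zinb":
                raise ValueError(
                    "zero_inflation_pi is only valid for model='zinb'"
                )
            if not 0 <= self.zero_inflation_pi <= 1:
                raise ValueError("zero_inflation_pi must be in [0, 1]")


@dataclass
class SimCountTruth:
    """Simulation-truth parameters returned with the matrix."""

    pi: np.ndarray  # gene relative abundances (sum 1)
    phi: Optional[float] = None  # global dispersion (nb / zinb)
    phi_gene: Optional[np.ndarray] = None  # per-gene dispersions (nb_genewise)
    s_c: np.ndarray = field(default_factory=lambda: np.empty(0))  # drawn sizes
    zero_inflation_pi: float = 0.0


def _draw_libsizes(rng, n_cells, mean, cv):
    if cv == 0:
        return np.full(n_cells, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n_cells)


def simulate_counts(config: SimCountConfig) -> Tuple[UMICountMatrix, SimCountTruth]:
    """Draw a gene x cell UMI matrix under the configured count model.

    All models share the mean structure mu_cg = s_c * pi_g. The binomial
    model conditions on integer cell totals (drawn lognormal, rounded) and
    samples each cell multinomially so column sums equal s_c exactly; the
    Poisson/NB models treat the drawn s_c as the expected total, and the
    matrix's realized library sizes are the column sums. ZINB applies an
    independent Bernoulli(zero_inflation_pi) forced-zero mask on top of NB
    draws (after the NB draws, so zinb with pi0=0 reproduces nb exactly at
    the same seed).
    """
    rng = np.random.default_rng(config.seed)
    g, c = config.n_genes, config.n_cells
    s = _draw_libsizes(rng, c, config.mean_library_size, config.libsize_cv)
    pi = rng.gamma(config.abundance_shape, 1.0, size=g)
    pi = pi / pi.sum()
    truth = SimCountTruth(pi=pi, s_c=s)

    if config.model == "binomial":
        s_int = np.maximum(1, np.round(s)).astype(np.int64)
        truth.s_c = s_int.astype(float)
        counts = rng.multinomial(s_int, pi).T  # genes x cells
    elif config.model == "poisson":
        counts = rng.poisson(pi[:, None] * s[None, :])
    else:  # nb, nb_genewise, zinb
        mu = pi[:, None] * s[None, :]
        if config.model == "nb_genewise":
            phi_g = rng.lognormal(np.log(config.phi), config.genewise_phi_logsd, g)
            truth.phi_gene = phi_g
            phi = phi_g[:, None]
        else:
            truth.phi = config.phi
            phi = config.phi
        p = phi / (phi + mu)
        counts = rng.negative_binomial(np.broadcast_to(phi, mu.shape), p)
        if config.model == "zinb":
            pi0 = config.zero_inflation_pi or 0.0
            truth.zero_inflation_pi = pi0
            mask = rng.random(size=mu.shape) < pi0
            counts = np.where(mask, 0, counts)

    gene_ids = np.array([f"G{i:05d}" for i in range(g)], dtype=object)
    barcodes = np.array([f"CELL{j:05d}" for j in range(c)], dtype=object)
    m = UMICountMatrix(sp.csr_matrix(counts), gene_ids, barcodes)
    return m, truth


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimAnnotationConfig:
    """Conditions for a synthetic genome + multi-isoform annotation.

    Exon/intron lengths are drawn uniformly from the given base-pair
    ranges; each gene receives a master exon chain and
    ``isoforms_per_gene`` isoforms formed by dropping internal exons.
    With probability ``polyA_insert_prob`` each master intron receives an
    A-run of ``polyA_run_length`` bases (written on the gene strand, so
    the run appears as poly-A in the transcript sequence).
    """

    n_chromosomes: int = 2
    n_genes: int = 10
    isoforms_per_gene: Tuple[int, int] = (1, 2)
    exons_per_gene: Tuple[int, int] = (1, 4)
    exon_length_range: Tuple[int, int] = (30, 200)
    intron_length_range: Tuple[int, int] = (50, 500)
    gc_content: float = 0.42
    polyA_insert_prob: float = 0.0
    polyA_run_length: int = 10
    chromosome_length: Optional[int] = None  # None: auto-sized to fit
    intergenic_gap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ValueError("n_chromosomes and n_genes must be positive")
        for name in ("isoforms_per_gene", "exons_per_gene",
                     "exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 <= self.polyA_insert_prob <= 1:
            raise ValueError("polyA_insert_prob must be in [0, 1]")
        if self.polyA_run_length < 1:
            raise ValueError("polyA_run_length must be >= 1")
        if (
            self.polyA_insert_prob > 0
            and self.intron_length_range[0] < self.polyA_run_length
        ):
            raise ValueError(
                "polyA_run_length exceeds the minimum intron length; "
                "runs could not be placed inside introns"
            )


def _random_sequence(rng, length, gc):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=probs)


def simulate_annotation(
    config: SimAnnotationConfig,
) -> Tuple[GeneModelSet, Dict[str, str]]:
    """Generate a small genome plus a multi-isoform annotation over it."""
    rng = np.random.default_rng(config.seed)
    gap = config.intergenic_gap

    # master exon chains per gene
    plans = []
    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length_range[0],
                                 config.exon_length_range[1] + 1, n_exons)
        intron_lens = rng.integers(config.intron_length_range[0],
                                   config.intron_length_range[1] + 1,
                                   max(0, n_exons - 1))
        plans.append((exon_lens, intron_lens))

    # round-robin assignment of genes to chromosomes
    chrom_of = [i % config.n_chromosomes for i in range(config.n_genes)]
    genome_parts: Dict[str, list] = {}
    offsets: Dict[str, int] = {}
    genes: Dict[str, GeneModel] = {}
    chrom_names = [f"chr{k + 1}" for k in range(config.n_chromosomes)]
    for name in chrom_names:
        offsets[name] = gap

    span_of = [
        int(el.sum() + il.sum()) for el, il in plans
    ]
    for k, name in enumerate(chrom_names):
        need = sum(
            span_of[i] + gap for i in range(config.n_genes) if chrom_of[i] == k
        ) + gap
        length = config.chromosome_length or need
        if length < need:
            raise ValueError(
                f"requested gene lengths exceed chromosome size on {name}: "
                f"need {need} bp, have {length}"
            )
        genome_parts[name] = list(_random_sequence(rng, length, config.gc_content))

    for i in range(config.n_genes):
        name = chrom_names[chrom_of[i]]
        exon_lens, intron_lens = plans[i]
        start = offsets[name]
        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        offsets[name] = pos + gap
        strand = "+" if rng.random() < 0.5 else "-"

        gid = f"GENE{i:04d}"
        gene = GeneModel(chromosome=name, strand=strand)
        n_iso = int(rng.integers(config.isoforms_per_gene[0],
                                 config.isoforms_per_gene[1] + 1))
        for j in range(n_iso):
            if j == 0 or len(exons) < 3:
                iso = list(exons)
            else:
                # drop a random nonempty subset of internal exons
                internal = exons[1:-1]
                keep = rng.random(len(internal)) < 0.5
                iso = [exons[0]] + [e for e, k in zip(internal, keep) if k] + [exons[-1]]
            gene.transcripts[f"{gid}.t{j + 1}"] = iso
        genes[gid] = gene

        # poly-A insertion inside master introns, on the gene strand
        run_char = "A" if strand == "+" else "T"
        for j in range(len(intron_lens)):
            if rng.random() < config.polyA_insert_prob:
                istart, iend = exons[j][1], exons[j + 1][0]
                run = config.polyA_run_length
                lo = istart
                hi = iend - run
                at = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                genome_parts[name][at : at + run] = [run_char] * run

    genome = {name: "".join(chars) for name, chars in genome_parts.items()}
    return GeneModelSet(genes), genome


# ---------------------------------------------------------------------------
# length-bias totals
# ---------------------------------------------------------------------------

def simulate_length_bias_totals(
    n_genes: int,
    beta: float,
    sigma: float,
    length_range: Tuple[float, float] = (1e3, 1e6),
    seed: int = 0,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Per-gene (length, total) pairs with a log-linear length effect.

    log10(total + 1) = alpha + beta * log10(length) + Normal(0, sigma);
    lengths are log-uniform over ``length_range``; totals are rounded to
    integers. Returns a DataFrame indexed by gene_id with columns
    ``length`` and ``total``.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(seed)
    log_len = rng.uniform(np.log10(lo), np.log10(hi), size=n_genes)
    lengths = np.maximum(1, np.round(10.0**log_len)).astype(np.int64)
    y = alpha + beta * np.log10(lengths) + rng.normal(0.0, sigma, size=n_genes)
    totals = np.maximum(0, np.round(10.0**y - 1.0)).astype(np.int64)
    return pd.DataFrame(
        {"length": lengths, "total": totals},
        index=pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id"),
    )


# ---------------------------------------------------------------------------
# cell-type mixture
# ---------------------------------------------------------------------------

def simulate_celltype_mixture(
    n_types: int,
    markers_per_type: int,
    fold_change: float,
    n_cells_per_type: int,
    seed: int = 0,
    n_background_genes: int = 200,
    mean_library_size: float = 2000.0,
    libsize_cv: float = 0.3,
) -> Tuple[UMICountMatrix, pd.Series, pd.DataFrame]:
    """Labeled mixture of cell types with known marker fold changes.

    Each type owns ``markers_per_type`` exclusive marker genes whose
    relative abundance is ``fold_change`` times baseline in cells of that
    type (then renormalized); counts are multinomial given lognormal cell
    totals. Returns (matrix with labels, true label Series, marker table
    with columns celltype / gene_id).
    """
    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    types = [f"type{t + 1}" for t in range(n_types)]
    marker_ids = [
        f"MK{t + 1}_{j:03d}" for t in range(n_types) for j in range(markers_per_type)
    ]
    background_ids = [f"BG{i:05d}" for i in range(n_background_genes)]
    gene_ids = np.array(marker_ids + background_ids, dtype=object)
    g = len(gene_ids)

    base = rng.gamma(1.0, 1.0, size=g) + 0.05  # baseline abundance weights
    profiles = np.tile(base, (n_types, 1))
    for t in range(n_types):
        sl = slice(t * markers_per_type, (t + 1) * markers_per_type)
        profiles[t, sl] *= fold_change
    profiles /= profiles.sum(axis=1, keepdims=True)

    n_cells = n_types * n_cells_per_type
    s = np.maximum(
        1, np.round(_draw_libsizes(rng, n_cells, mean_library_size, libsize_cv))
    ).astype(np.int64)
    labels_arr = np.repeat(types, n_cells_per_type)
    counts = np.empty((g, n_cells), dtype=np.int64)
    for j in range(n_cells):
        t = j // n_cells_per_type
        counts[:, j] = rng.multinomial(s[j], profiles[t])

    barcodes = np.array(
        [f"CELL{t + 1}_{i:04d}" for t in range(n_types) for i in range(n_cells_per_type)],
        dtype=object,
    )
    labels = pd.Series(labels_arr, index=barcodes, name="celltype")
    m = UMICountMatrix(sp.csr_matrix(counts), gene_ids, barcodes, labels=labels)
    marker_table = pd.DataFrame(
        {
            "celltype": np.repeat(types, markers_per_type),
            "gene_id": marker_ids,
        }
    )
    return m, labels, marker_table
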