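# Methods

This note documents the statistical models, the synthetic-data conditions,
the numerical choices, and the known limitations of `nucdist`.

## Count models and estimation

All four candidate models for the UMI count `X_cg` of gene *g* in cell *c*
share one mean structure,

    mu_cg = s_c * pi_g,

where `s_c` is the cell's library size (total UMIs, used as an offset) and
`pi_g` the gene's relative abundance. Abundances are estimated once by the
plug-in multinomial estimate `pi_g = total_g / grand_total` (so they sum to
one) and are held fixed across models; only dispersions are optimized. This
keeps the models nested and their likelihoods comparable:

| model        | distribution                | free parameters |
|--------------|-----------------------------|-----------------|
| binomial     | Binom(s_c, pi_g)            | G               |
| poisson      | Pois(mu_cg)                 | G               |
| nb_global    | NB(mu_cg, phi)              | G + 1           |
| nb_genewise  | NB(mu_cg, phi_g)            | 2G              |

The NB is parameterized by its dispersion (size) `phi`, with

    Var[X] = mu + mu^2 / phi,      P(X = 0) = (phi / (phi + mu))^phi,

so `phi -> infinity` recovers the Poisson. Dispersion MLEs come from
bounded Brent search on `log(phi)` over `[1e-8, 1e8]` with tolerance 1e-6
on the log scale — the profile likelihood in `phi` is unimodal, so a 1-D
bounded search is exact enough and cannot diverge. Genes with zero
empirical variance have no interior NB MLE; their `phi_g` is pinned to the
upper bound with a warning.

Log-pmfs are evaluated from `gammaln`/`xlogy` directly (cross-checked
against `scipy.stats` in the test suite). For dispersions above 1e6 with
integer counts, the term `gammaln(x + phi) - gammaln(phi)` is computed as
`x*log(phi) + sum_k log1p(k/phi)`: subtracting two gammaln values of order
1e9 loses ~8 digits to cancellation, which would otherwise dominate the
Poisson-limit comparison.

Model comparison uses `BIC = k * ln(n_obs) - 2 * loglik` with
`n_obs = G * C` — every count is an observation and genes are treated as
independent. On overdispersed data the global-NB model wins; the gene-wise
NB characteristically ranks last because its `2G` parameters cost more
penalty than the per-gene likelihood gain is worth at realistic cell
counts.

### Goodness of fit

The per-gene Pearson statistic under the Poisson model is
`sum_c (x_cg - mu_cg)^2 / mu_cg`, referred to a chi-squared distribution
with `C - 1` degrees of freedom (one abundance estimated per gene; the
shared library-size offsets remove a negligible additional fraction of a
degree of freedom per gene). QQ pairs use plotting positions
`(i - 0.5) / G`. Genes with estimated abundance exactly zero have no
defined statistic and are excluded and reported.

### Zero-inflation detection

Zero inflation is detected, never fitted: a gene is flagged when its
observed zero fraction exceeds the expected zero fraction under the fitted
NB, averaged over cells at `mu_cg = s_c * pi_g`. The comparison uses the
**gene-wise** NB fit. Zero inflation is a per-gene phenomenon, and the
gene-wise fit is the sharper null: with a single global dispersion,
dispersion misfit at individual genes masquerades as zero excess or
deficit. Empirically (see `scripts/acceptance.py`), the gene-wise
comparison flags ~98% of well-expressed genes on data simulated with 30%
structural zeros and ~50% — chance — on pure NB data.

## Synthetic data conditions

The generators define the study conditions for every test; their defaults
are chosen once as a realistic droplet snRNA-seq regime:

- **Library sizes**: lognormal with mean 5 000 UMIs/cell and CV 0.3 —
  typical post-QC depth for 10x-style nuclei data. For binomial sampling
  the drawn sizes are rounded and cells are sampled multinomially, so
  column sums equal the drawn totals exactly; for Poisson/NB the drawn
  size is the expected total and realized library sizes are the column
  sums.
- **Abundances**: gamma(shape 1) draws normalized to sum one — a standard
  heavy-tailed expression profile; with 500 genes this gives per-gene
  means spanning roughly 0.1–100.
- **Dispersion**: global `phi = 1` unless stated (strong but realistic
  overdispersion); gene-wise `phi_g` lognormal around `phi` with log-sd
  0.5.
- **Structural zeros** (ZINB only): independent Bernoulli masks applied
  after the NB draw, so `pi0 = 0` reproduces the NB stream bit for bit.
- **Annotations**: uniform exon lengths 30–200 bp and intron lengths
  50–500 bp over auto-sized chromosomes with 100 bp intergenic gaps;
  isoforms share their gene's first and last exon and drop internal exons
  at random. Poly-A runs are written on the gene strand inside master
  introns (a minus-strand gene receives a genomic T-run), so inserted
  runs appear in unspliced transcript sequences.
- **Length-bias totals**: `log10(total + 1) = 1.0 + beta * log10(L) +
  N(0, sigma)` with lengths log-uniform on [1e3, 1e6] bp; the implied
  log-scale Pearson correlation has the closed form
  `r = beta * sd(log L) / sqrt(beta^2 var(log L) + sigma^2)`, which the
  recovery tests compare against.
- **Cell-type mixtures**: exclusive marker blocks per type elevated by a
  known fold change over a shared gamma baseline, multinomial sampling at
  mean 2 000 UMIs/cell.

What the simulations do **not** model: ambient RNA, doublets, UMI
collisions, residual within-type substructure (real pseudonegative
controls retain some, so real-data dispersion estimates are upper bounds
on technical noise), batch effects, and any read-level process (the
package starts from counts, not FASTQs). Passing tests therefore
demonstrate correctness of the estimators and constructions under the
stated generative models — not that any particular real data set follows
them.

## Reference construction

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
format's 1-based closed convention. The four reference kinds:

- *transcripts*: exon concatenations per transcript (minus-strand genes
  reverse-complemented).
- *preandmrna*: adds, per transcript, the full genomic span from first
  exon start to last exon end — so every unspliced target is at least as
  long as its spliced counterpart, which is asserted as an invariant.
- *intronseparate*: one target per exon gap per transcript. These may
  overlap sibling isoforms' exons by construction.
- *introncollapse*: per gene, the maximal intervals of the gene span that
  are exonic in no isoform (exon-union complement within the span).

Flanks (default 50 bp, one read length, to catch junction-spanning reads)
are applied to the *final* intron intervals — after collapsing, in the
collapse mode — and clipped at chromosome bounds. Flank-extended intervals
of one transcript that come to overlap are deliberately **not** merged:
each mirrors one gap of the transcript and remains a distinct target. This
choice (and the alternative) is visible in the outputs and documented so
results are reproducible. Intron targets inherit the gene strand. Output
order is a stable sort by (gene id, transcript id, interval start). Every
bundle carries the transcript-to-gene table and a decoy list naming all
genome sequences; building a mapping index is out of scope.

Both intron definitions are verified against an independent per-base
brute-force classifier on random annotations, with and without flanks.

## Length bias

The *preandmrna* length of a gene is its genomic span (exons + introns),
the *transcript* length the exonic bases only; both are summarized per
gene as the **maximum** over isoforms (one declared choice among max / sum
/ union; the max tracks the longest product the gene can emit and keeps
the span >= exonic invariant trivially).

Genes are sorted by length (ties broken by gene id, so binning is
deterministic) and split into ten equal-count bins; per-bin medians and
quartiles use type-7 linear interpolation. Overall bias strength is the
Pearson correlation of `log10(total)` vs `log10(length)` over genes with
positive totals — zero-total genes are excluded (no pseudocount) and
counted. Trends are local linear regressions with tricube weights
(statsmodels lowess, robustness iterations off) evaluated on an even grid
over the x-range.

Poly-A counting is **run-based** by default: maximal runs of >= n
consecutive A anywhere in the transcript body (annotated sequences carry
no templated tail, so no 3' exclusion window is needed). The
sliding-window alternative (a run of length L counts L - n + 1 times) is
implemented for comparison; the two conventions agree on the dichotomy
"has at least one internal poly-A n-mer", which is all the downstream
stratification uses. Gene-level counts take the maximum over all spliced
and unspliced transcript sequences of the gene, so an A-run created by a
splice junction (or one confined to an intron) is caught.

## Annotation and concordance

The annotator is the rank-correlation core of reference-based cell-type
classifiers: Spearman correlation (average ranks for ties) between a
cell's counts and each per-type mean profile over the union of marker
genes, argmax assignment, and a margin prune — cells whose best and
second-best correlations differ by less than `prune_delta` (default 0.05)
stay "unassigned", as do cells constant over the marker union. Iterative
fine-tuning and built-in references of production annotators are
deliberately out of scope. The marker-ratio statistic uses a pseudocount
of 1 in numerator and denominator to keep empty denominators finite.
Concordance tables are full cross-tabulations with an explicit
"unassigned" column and optional label merging applied to both sides.

## QC

Cells are filtered first (library size AND detected genes above
thresholds, both defaulting to 100 — explicit package defaults, meant to
be overridden per data set), then all-zero genes are dropped; the order
matters and is fixed because removing cells can empty gene rows.
Subsetting to one labeled cell type re-drops all-zero genes, since genes
unexpressed within the subset carry no information for the fits.

## Problem sizes and determinism

The bundled analyses run at desk scale by design: dispersion recovery at
500 genes x 1 000 cells, model selection at 300 x 600 over replicate
seeds, GOF calibration at 500 x 500, oracle checks over ~100 toy
annotations and 10^4 random sequences. Model fitting densifies the count
matrix, so it targets QC'd pseudonegative controls (up to ~10^6 entries),
not whole-experiment matrices. Every random quantity flows from explicit
integer seeds (the pipeline expands one root seed into per-stage seeds),
and pipeline outputs are byte-identical across reruns, which the manifest
checksums make verifiable.

## Known limitations

- The binomial model conditions on realized library sizes; alternative
  conventions (e.g. conditioning on a common depth) would change its
  likelihood but not the qualitative comparisons.
- The plug-in abundance estimate ignores its own sampling noise; at the
  bundled sizes the induced bias in `phi` is well below the tolerance of
  the recovery checks.
- Gene-wise dispersion fitting is a per-gene loop (hundreds of 1-D
  optimizations); it is the slow path and scales linearly in G.
- The GTF reader supports the GTF dialect only (GFF3 is out of scope) and
  expects explicit transcript and exon features.
- Non-ACGT genome characters are uppercased and passed through (N stays
  N in targets); they never count as poly-A.
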