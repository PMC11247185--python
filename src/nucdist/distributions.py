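"""Distribution adequacy for UMI counts.

Four candidate measurement-error models for the count ``X_cg`` of gene g in
cell c share the mean structure ``mu_cg = s_c * pi_g``, where ``s_c`` is
the cell's library size (used as an offset) and ``pi_g`` the gene's
relative abundance, estimated by the plug-in multinomial estimate
``pi_g = total_g / grand_total``:

- ``binomial``:    X_cg ~ Binom(s_c, pi_g)
- ``poisson``:     X_cg ~ Pois(mu_cg)
- ``nb_global``:   X_cg ~ NB(mu_cg, phi), one dispersion for the data set
- ``nb_genewise``: X_cg ~ NB(mu_cg, phi_g), one dispersion per gene

The NB is parameterized by its dispersion (size) phi with
``Var[X] = mu + mu^2 / phi`` and zero probability
``P(X=0) = (phi / (phi + mu))^phi``; phi -> infinity recovers the Poisson.
Only dispersions are optimized (bounded 1-D likelihood maximization on the
log-phi scale), which keeps the four models nested and comparable by BIC
with ``n_obs = G * C`` (genes treated as independent).

Zero inflation is *detected*, not fitted: a gene whose observed zero
fraction exceeds the fitted-NB expectation carries more zeros than the NB
allows (see :func:`detect_zero_inflation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, xlog1py, xlogy
from scipy.stats import chi2

from .matrix import UMICountMatrix

MODELS = ("binomial", "poisson", "nb_global", "nb_genewise")

PHI_MIN = 1e-8
PHI_MAX = 1e8
_PHI_XATOL = 1e-6  # tolerance on log(phi)


class FitError(RuntimeError):
    """Raised when a dispersion optimization does not converge."""


# ---------------------------------------------------------------------------
# empirical summaries
# ---------------------------------------------------------------------------

def gene_summaries(m: UMICountMatrix) -> pd.DataFrame:
    """Per-gene empirical mean, sample variance (ddof=1) and zero fraction."""
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells for gene summaries")
    x = m.counts
    c = m.n_cells
    mean = np.asarray(x.sum(axis=1)).ravel() / c
    sq = np.asarray(x.multiply(x).sum(axis=1)).ravel()
    variance = (sq - c * mean**2) / (c - 1)
    variance = np.maximum(variance, 0.0)  # guard fp negatives
    nnz = np.asarray((x > 0).sum(axis=1)).ravel()
    return pd.DataFrame(
        {
            "empirical_mean": mean,
            "empirical_variance": variance,
            "zero_fraction": 1.0 - nnz / c,
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )


def estimate_abundance(m: UMICountMatrix) -> np.ndarray:
    """Plug-in relative abundances pi_g = total_g / grand_total (sum to 1)."""
    totals = m.gene_totals.astype(float)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("matrix has no counts")
    return totals / grand


# ---------------------------------------------------------------------------
# log-pmfs (gammaln/xlogy forms; cross-checked against scipy.stats in tests)
# ---------------------------------------------------------------------------

def nb_logpmf(x, mu, phi):
    """NB log-pmf in the (mu, dispersion phi) parameterization.

    Entries with mu == 0 contribute 0 when x == 0 and -inf otherwise.
    For scalar phi above 1e6 and integer counts, the Pochhammer term
    gammaln(x + phi) - gammaln(phi) is evaluated as
    x*log(phi) + sum_k log1p(k/phi) to avoid the catastrophic cancellation
    of two huge gammaln values, so the Poisson limit phi -> inf is reached
    to near machine precision.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if (
        phi.ndim == 0
        and phi > 1e6
        and x.size
        and float(x.max()) < 5e6
        and np.all(x == np.floor(x))
    ):
        xi = x.astype(np.int64)
        k = np.arange(int(x.max()))
        cum = np.concatenate([[0.0], np.cumsum(np.log1p(k / phi))])
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                cum[xi]
                - gammaln(x + 1)
                - (phi + x) * np.log1p(mu / phi)
                + xlogy(x, mu)
            )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                gammaln(x + phi)
                - gammaln(phi)
                - gammaln(x + 1)
                + phi * np.log(phi / (phi + mu))
                + xlogy(x, mu / (phi + mu))
            )
    zero_mu = np.broadcast_to(mu, ll.shape) == 0
    if np.any(zero_mu):
        ll = np.where(zero_mu, np.where(x == 0, 0.0, -np.inf), ll)
    return ll


def poisson_logpmf(x, mu):
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return xlogy(x, mu) - mu - gammaln(x + 1)


def binomial_logpmf(x, n, p):
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    return (
        gammaln(n + 1)
        - gammaln(x + 1)
        - gammaln(n - x + 1)
        + xlogy(x, p)
        + xlog1py(n - x, -p)
    )


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: str
    pi: np.ndarray
    loglik_total: float
    n_params: int
    n_obs: int
    phi_global: Optional[float] = None
    phi_gene: Optional[np.ndarray] = None
    gene_ids: Optional[np.ndarray] = None

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik_total


def _optimize_phi(objective) -> float:
    """Maximize a 1-D NB profile likelihood over log(phi), bounded."""
    res = optimize.minimize_scalar(
        lambda z: -objective(np.exp(z)),
        bounds=(np.log(PHI_MIN), np.log(PHI_MAX)),
        method="bounded",
        options={"xatol": _PHI_XATOL},
    )
    if not res.success:
        raise FitError(f"dispersion optimization failed: {res.message}")
    return float(np.exp(res.x))


def fit_model(m: UMICountMatrix, model: str) -> FitResult:
    """Fit one of the four count models by (profile) maximum likelihood.

    Abundances are the plug-in estimates; for the NB variants the
    dispersion(s) maximize the likelihood by bounded 1-D search. Counts are
    densified internally, so the routine targets QC'd pseudonegative
    controls (up to ~10^6 entries), not whole-experiment matrices.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; one of {MODELS}")
    pi = estimate_abundance(m)
    s = m.library_sizes.astype(float)
    x = m.dense().astype(float)
    mu = pi[:, None] * s[None, :]
    g, c = x.shape
    n_obs = g * c

    if model == "poisson":
        ll = float(poisson_logpmf(x, mu).sum())
        return FitResult("poisson", pi, ll, g, n_obs, gene_ids=m.gene_ids)

    if model == "binomial":
        ll = float(binomial_logpmf(x, s[None, :], pi[:, None]).sum())
        return FitResult("binomial", pi, ll, g, n_obs, gene_ids=m.gene_ids)

    if model == "nb_global":
        phi_hat = _optimize_phi(lambda phi: nb_logpmf(x, mu, phi).sum())
        ll = float(nb_logpmf(x, mu, phi_hat).sum())
        return FitResult(
            "nb_global", pi, ll, g + 1, n_obs, phi_global=phi_hat,
            gene_ids=m.gene_ids,
        )

    # nb_genewise: independent 1-D MLE per gene
    phi_gene = np.empty(g)
    ll = 0.0
    n_degenerate = 0
    for i in range(g):
        xi, mui = x[i], mu[i]
        if np.var(xi) == 0.0:
            # zero empirical variance: NB MLE runs to the Poisson limit
            phi_gene[i] = PHI_MAX
            n_degenerate += 1
        else:
            try:
                phi_gene[i] = _optimize_phi(
                    lambda phi, xi=xi, mui=mui: nb_logpmf(xi, mui, phi).sum()
                )
            except FitError as err:
                raise FitError(f"gene index {i} ({m.gene_ids[i]}): {err}") from err
        ll += float(nb_logpmf(xi, mui, phi_gene[i]).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} gene(s) with zero variance: phi_g set to the "
            f"upper bound {PHI_MAX:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return FitResult(
        "nb_genewise", pi, ll, 2 * g, n_obs, phi_gene=phi_gene,
        gene_ids=m.gene_ids,
    )


# ---------------------------------------------------------------------------
# theoretical curves
# ---------------------------------------------------------------------------

def expected_variance(model, mu, phi=None, mean_libsize=None):
    """Theoretical Var[X] at mean mu for the display curves.

    poisson: mu; nb: mu + mu^2/phi; binomial: mu * (1 - mu / s_bar) with
    s_bar the mean library size (curve convention: a binomial with n =
    mean library size).
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be >= 0")
    if model == "poisson":
        return mu.copy()
    if model in ("nb", "nb_global", "nb_genewise"):
        if phi is None or np.any(np.asarray(phi) <= 0):
            raise ValueError("nb variance requires phi > 0")
        return mu + mu**2 / phi
    if model == "binomial":
        if mean_libsize is None or mean_libsize <= 0:
            raise ValueError("binomial variance requires mean_libsize > 0")
        return mu * (1.0 - mu / mean_libsize)
    raise ValueError(f"unknown model {model!r}")


def expected_zero_fraction(model, pi_g, libsizes, phi=None):
    """Expected share of zero counts for one gene: the model's zero
    probability at mu_c = s_c * pi_g, averaged over cells."""
    s = np.asarray(libsizes, dtype=float)
    if np.any(s <= 0):
        raise ValueError("library sizes must be positive")
    if not 0 <= pi_g <= 1:
        raise ValueError("pi_g must be in [0, 1]")
    mu = s * pi_g
    if model == "poisson":
        return float(np.mean(np.exp(-mu)))
    if model == "binomial":
        return float(np.mean((1.0 - pi_g) ** s))
    if model in ("nb", "nb_global", "nb_genewise"):
        if phi is None or phi <= 0:
            raise ValueError("nb zero fraction requires phi > 0")
        return float(np.mean((phi / (phi + mu)) ** phi))
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# model comparison and goodness of fit
# ---------------------------------------------------------------------------

def bic_compare(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits by BIC = n_params * ln(n_obs) - 2 * loglik (best first)."""
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits computed on different n_obs: {sorted(n_obs)}")
    df = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "loglik": [f.loglik_total for f in fits],
            "n_params": [f.n_params for f in fits],
            "bic": [f.bic for f in fits],
        }
    ).sort_values("bic", kind="stable", ignore_index=True)
    df["delta_bic"] = df["bic"] - df["bic"].iloc[0]
    return df


@dataclass
class GOFResult:
    """Per-gene Pearson statistics under the Poisson model plus QQ pairs."""

    table: pd.DataFrame  # gene_id (index), pearson_stat, dof
    qq: pd.DataFrame  # theoretical, observed
    excluded: list = field(default_factory=list)


def poisson_gof(m: UMICountMatrix) -> GOFResult:
    """Pearson goodness-of-fit statistic per gene under the Poisson model.

    stat_g = sum_c (x_cg - mu_cg)^2 / mu_cg with mu_cg = s_c * pi_g; under
    the Poisson null the statistic is approximately chi-squared with
    C - 1 degrees of freedom (one abundance estimated per gene). QQ pairs
    use plotting positions (i - 0.5) / G.
    """
    pi = estimate_abundance(m)
    s = m.library_sizes.astype(float)
    keep = pi > 0
    excluded = list(m.gene_ids[~keep])
    x = m.dense().astype(float)[keep]
    mu = pi[keep][:, None] * s[None, :]
    stat = (((x - mu) ** 2) / mu).sum(axis=1)
    dof = m.n_cells - 1
    table = pd.DataFrame(
        {"pearson_stat": stat, "dof": dof},
        index=pd.Index(m.gene_ids[keep], name="gene_id"),
    )
    g = len(stat)
    probs = (np.arange(1, g + 1) - 0.5) / g
    qq = pd.DataFrame(
        {"theoretical": chi2.ppf(probs, dof), "observed": np.sort(stat)}
    )
    return GOFResult(table=table, qq=qq, excluded=excluded)


def summary_with_expectations(
    m: UMICountMatrix, fits: Sequence[FitResult]
) -> pd.DataFrame:
    """Per-gene empirical summaries plus, for each fitted model, the
    theoretical variance and expected zero fraction at the gene's mean.

    This is the table behind the mean-variance and mean-zero-fraction
    display panels.
    """
    out = gene_summaries(m)
    s = m.library_sizes.astype(float)
    s_bar = float(s.mean())
    for fit in fits:
        mu = fit.pi * s_bar
        if fit.model == "poisson":
            var = expected_variance("poisson", mu)
        elif fit.model == "binomial":
            var = expected_variance("binomial", mu, mean_libsize=s_bar)
        elif fit.model == "nb_global":
            var = expected_variance("nb", mu, phi=fit.phi_global)
        else:
            var = expected_variance("nb", mu, phi=fit.phi_gene)
        zf = np.empty(m.n_genes)
        for i in range(m.n_genes):
            if fit.model in ("nb_global", "nb_genewise"):
                phi = fit.phi_global if fit.model == "nb_global" else fit.phi_gene[i]
                zf[i] = expected_zero_fraction("nb", fit.pi[i], s, phi)
            else:
                zf[i] = expected_zero_fraction(fit.model, fit.pi[i], s)
        out[f"expected_variance_{fit.model}"] = var
        out[f"expected_zero_fraction_{fit.model}"] = zf
    return out


def detect_zero_inflation(m: UMICountMatrix, fit: FitResult) -> pd.DataFrame:
    """Flag genes whose observed zero fraction exceeds the fitted-NB
    expectation — the operational meaning of "zero-inflated".

    ``fit`` must be an NB fit (global or gene-wise); the expected zero
    fraction per gene averages the fitted zero probability over cells.
    """
    if fit.model not in ("nb_global", "nb_genewise"):
        raise ValueError("zero-inflation detection needs an NB fit")
    summaries = gene_summaries(m)
    s = m.library_sizes
    expected = np.empty(m.n_genes)
    for i in range(m.n_genes):
        phi = fit.phi_global if fit.model == "nb_global" else fit.phi_gene[i]
        expected[i] = expected_zero_fraction("nb", fit.pi[i], s, phi)
    out = summaries.copy()
    out["expected_zero_fraction"] = expected
    out["excess_zeros"] = out["zero_fraction"] > expected
    return out
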