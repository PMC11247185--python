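"""Display panels: mean-variance, mean-zero-fraction, BIC bars, Poisson
QQ, binned length-bias quartiles, and the poly-A stratified trend."""

from __future__ import annotations

from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")  # headless rendering; figures are saved, not shown

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .lengthbias import trend_curve

_MODEL_COLORS = {
    "binomial": "tab:green",
    "poisson": "tab:orange",
    "nb_global": "tab:blue",
    "nb_genewise": "tab:red",
}


def _log10p(v):
    return np.log10(np.asarray(v, dtype=float) + 1e-8)


def plot_mean_variance(summary: pd.DataFrame, ax=None):
    """Empirical mean vs variance per gene with theoretical curves."""
    ax = ax or plt.gca()
    ax.scatter(
        _log10p(summary["empirical_mean"]),
        _log10p(summary["empirical_variance"]),
        s=4, alpha=0.4, color="gray", label="genes",
    )
    order = np.argsort(summary["empirical_mean"].to_numpy())
    for col in summary.columns:
        if col.startswith("expected_variance_"):
            model = col.removeprefix("expected_variance_")
            ax.plot(
                _log10p(summary["empirical_mean"].to_numpy()[order]),
                _log10p(summary[col].to_numpy()[order]),
                label=model, color=_MODEL_COLORS.get(model),
            )
    ax.set_xlabel("log10 empirical mean")
    ax.set_ylabel("log10 variance")
    ax.legend(fontsize=7)
    return ax


def plot_zero_fraction(summary: pd.DataFrame, ax=None):
    """Empirical mean vs observed zero fraction with expected curves."""
    ax = ax or plt.gca()
    ax.scatter(
        _log10p(summary["empirical_mean"]),
        summary["zero_fraction"],
        s=4, alpha=0.4, color="gray", label="genes",
    )
    order = np.argsort(summary["empirical_mean"].to_numpy())
    for col in summary.columns:
        if col.startswith("expected_zero_fraction_"):
            model = col.removeprefix("expected_zero_fraction_")
            ax.plot(
                _log10p(summary["empirical_mean"].to_numpy()[order]),
                summary[col].to_numpy()[order],
                label=model, color=_MODEL_COLORS.get(model),
            )
    ax.set_xlabel("log10 empirical mean")
    ax.set_ylabel("fraction of zeros")
    ax.legend(fontsize=7)
    return ax


def plot_bic(comparison: pd.DataFrame, ax=None):
    """BIC per model (lower is better)."""
    ax = ax or plt.gca()
    colors = [_MODEL_COLORS.get(mdl, "gray") for mdl in comparison["model"]]
    ax.bar(comparison["model"], comparison["bic"], color=colors)
    ax.set_ylabel("BIC")
    ax.tick_params(axis="x", rotation=30)
    return ax


def plot_gof_qq(qq: pd.DataFrame, ax=None):
    """Observed Pearson statistics vs theoretical chi-squared quantiles."""
    ax = ax or plt.gca()
    ax.scatter(qq["theoretical"], qq["observed"], s=5, alpha=0.5)
    lim = [
        min(qq["theoretical"].min(), qq["observed"].min()),
        max(qq["theoretical"].max(), qq["observed"].max()),
    ]
    ax.plot(lim, lim, color="black", linewidth=0.8)
    ax.set_xlabel("theoretical chi-squared quantile")
    ax.set_ylabel("observed statistic")
    return ax


def plot_length_bins(per_bin: pd.DataFrame, ax=None, label=None, color=None):
    """Median (points) and quartiles (dashed) of totals per length bin."""
    ax = ax or plt.gca()
    x = per_bin["bin_id"]
    ax.plot(x, _log10p(per_bin["median"]), "o-", label=label, color=color)
    ax.plot(x, _log10p(per_bin["q25"]), "--", alpha=0.6, color=color)
    ax.plot(x, _log10p(per_bin["q75"]), "--", alpha=0.6, color=color)
    ax.set_xlabel("length bin (1 = shortest)")
    ax.set_ylabel("log10 total counts")
    if label:
        ax.legend(fontsize=7)
    return ax


def plot_polya_trend(per_gene: pd.DataFrame, span: float = 0.75, ax=None):
    """Totals vs length, stratified by internal poly-A presence, with a
    loess-style trend per group."""
    ax = ax or plt.gca()
    for flag, color, label in ((True, "tab:red", "has internal poly-A"),
                               (False, "tab:blue", "no internal poly-A")):
        sub = per_gene[(per_gene["has_polyA"] == flag) & (per_gene["total"] > 0)]
        if sub.empty:
            continue
        x = np.log10(sub["preandmrna_length"].to_numpy(dtype=float))
        y = np.log10(sub["total"].to_numpy(dtype=float))
        ax.scatter(x, y, s=4, alpha=0.3, color=color, label=label)
        if len(sub) >= 10:
            gx, gy = trend_curve(x, y, span=span)
            ax.plot(gx, gy, color=color)
    ax.set_xlabel("log10 preandmrna length")
    ax.set_ylabel("log10 total counts")
    ax.legend(fontsize=7)
    return ax
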