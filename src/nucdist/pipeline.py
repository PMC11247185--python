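"""End-to-end orchestration of the synthetic / QC / model-fit / length-bias
/ cell-type stages with one root seed, structured logging and an output
manifest (inputs, parameters, per-stage seeds, file checksums).

Stage outputs are pure functions of (config, seed): re-running the same
config reproduces byte-identical text outputs, which the manifest's
checksums make checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import distributions as dist
from . import io as nio
from .concordance import (
    MarkerSet,
    concordance,
    marker_ratio,
    reference_profiles_from_labels,
    spearman_annotate,
)
from .lengthbias import length_bias_analysis
from .qc import QCThresholds, qc_pipeline
from .reference import build_reference
from .synthetic import (
    SimAnnotationConfig,
    SimCountConfig,
    simulate_annotation,
    simulate_celltype_mixture,
    simulate_counts,
)

logger = logging.getLogger("nucdist.pipeline")

#: Fixed execution (and seed-derivation) order of the known stages.
STAGE_ORDER = (
    "simulate_annotation",
    "simulate_counts",
    "qc",
    "fit_dist",
    "reference",
    "length_bias",
    "celltype",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "nucdist_out"
    stages: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "nucdist_out")),
            stages={k: (v or {}) for k, v in (raw.get("stages") or {}).items()},
        )


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    idx = STAGE_ORDER.index(stage)
    return int(np.random.default_rng([root_seed, idx]).integers(2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def demo_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """A self-contained small synthetic run exercising every stage."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        stages={
            "simulate_annotation": {
                "n_chromosomes": 2,
                "n_genes": 120,
                "isoforms_per_gene": [1, 2],
                "exons_per_gene": [1, 4],
                "polyA_insert_prob": 0.3,
                "polyA_run_length": 10,
            },
            "simulate_counts": {"n_genes": 120, "n_cells": 300, "model": "nb",
                                "phi": 1.0},
            "qc": {"min_library_size": 100, "min_expressed_genes": 20},
            "fit_dist": {"models": ["binomial", "poisson", "nb_global",
                                    "nb_genewise"]},
            "reference": {"kind": "preandmrna", "flank_bp": 50},
            "length_bias": {"nmer": 8, "n_bins": 10},
            "celltype": {"n_types": 3, "markers_per_type": 20,
                         "fold_change": 10.0, "n_cells_per_type": 100},
        },
    )


def run_pipeline(config: PipelineConfig | str) -> dict:
    """Execute the configured stages in dependency order; return (and
    write) the manifest. A failing stage halts the run with the stage
    named; outputs of completed stages are retained."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in config.stages}
    files: Dict[str, str] = {}
    state: Dict[str, object] = {}

    def record(*paths):
        for p in paths:
            files[os.path.relpath(p, out)] = _sha256(p)

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = dict(config.stages[stage])
        t0 = time.monotonic()
        logger.info("stage %s starting", stage)
        try:
            if stage == "simulate_annotation":
                cfg = SimAnnotationConfig(
                    **{k: tuple(v) if isinstance(v, list) else v
                       for k, v in params.items()},
                    seed=seeds[stage],
                )
                models, genome = simulate_annotation(cfg)
                gtf = os.path.join(out, "annotation.gtf")
                fa = os.path.join(out, "genome.fa")
                models.to_gtf(gtf)
                nio.write_genome_fasta(genome, fa)
                state["models"], state["genome"] = models, genome
                record(gtf, fa)

            elif stage == "simulate_counts":
                cfg = SimCountConfig(**params, seed=seeds[stage])
                m, truth = simulate_counts(cfg)
                if "models" in state:
                    anno_genes = np.array(sorted(state["models"].genes),
                                          dtype=object)
                    if len(anno_genes) == m.n_genes:
                        # align gene ids with the simulated annotation so the
                        # length-bias stage can join counts to gene models
                        m.gene_ids = anno_genes
                paths = nio.write_mtx_dir(m, os.path.join(out, "counts"))
                truth_path = os.path.join(out, "truth.json")
                with open(truth_path, "w") as fh:
                    json.dump(
                        {
                            "pi": truth.pi.tolist(),
                            "phi": truth.phi,
                            "phi_gene": None if truth.phi_gene is None
                            else truth.phi_gene.tolist(),
                            "s_c": truth.s_c.tolist(),
                            "zero_inflation_pi": truth.zero_inflation_pi,
                        },
                        fh, sort_keys=True,
                    )
                state["counts"] = m
                record(*paths.values(), truth_path)

            elif stage == "qc":
                m = state.get("counts")
                if m is None:
                    raise ValueError("qc needs a simulate_counts stage (or input)")
                thresholds = QCThresholds(
                    min_library_size=int(params.get("min_library_size", 100)),
                    min_expressed_genes=int(params.get("min_expressed_genes", 100)),
                )
                m = qc_pipeline(m, thresholds, params.get("celltype"))
                paths = nio.write_mtx_dir(m, os.path.join(out, "qc_counts"))
                state["qc_counts"] = m
                record(*paths.values())

            elif stage == "fit_dist":
                m = state.get("qc_counts") or state.get("counts")
                if m is None:
                    raise ValueError("fit_dist needs counts")
                model_names = params.get("models", list(dist.MODELS))
                fits = [dist.fit_model(m, name) for name in model_names]
                summary = dist.summary_with_expectations(m, fits)
                comparison = dist.bic_compare(fits)
                gof = dist.poisson_gof(m)
                p_sum = os.path.join(out, "summary.tsv")
                p_cmp = os.path.join(out, "model_comparison.json")
                p_gof = os.path.join(out, "gof.tsv")
                p_qq = os.path.join(out, "gof_qq.tsv")
                summary.to_csv(p_sum, sep="\t")
                with open(p_cmp, "w") as fh:
                    json.dump(
                        {
                            "models": comparison.to_dict(orient="records"),
                            "best_model": comparison["model"].iloc[0],
                            "phi_global": next(
                                (f.phi_global for f in fits
                                 if f.model == "nb_global"), None
                            ),
                        },
                        fh, sort_keys=True, indent=2,
                    )
                gof.table.to_csv(p_gof, sep="\t")
                gof.qq.to_csv(p_qq, sep="\t", index=False)
                state["fits"], state["gof"] = fits, gof
                record(p_sum, p_cmp, p_gof, p_qq)

            elif stage == "reference":
                if "models" not in state:
                    raise ValueError("reference needs a simulate_annotation stage")
                bundle = build_reference(
                    state["models"], state["genome"],
                    kind=params.get("kind", "preandmrna"),
                    flank_bp=int(params.get("flank_bp", 50)),
                )
                paths = bundle.write(
                    os.path.join(out, f"reference_{params.get('kind', 'preandmrna')}")
                )
                record(*paths.values())

            elif stage == "length_bias":
                m = state.get("qc_counts") or state.get("counts")
                if m is None or "models" not in state:
                    raise ValueError(
                        "length_bias needs counts and a simulated annotation"
                    )
                result = length_bias_analysis(
                    m, state["models"], state["genome"],
                    nmer=int(params.get("nmer", 8)),
                    n_bins=int(params.get("n_bins", 10)),
                )
                p_gene = os.path.join(out, "lengthbias_per_gene.tsv")
                p_bin = os.path.join(out, "lengthbias_per_bin.tsv")
                p_cor = os.path.join(out, "lengthbias_correlations.json")
                result.per_gene.to_csv(p_gene, sep="\t")
                result.per_bin.to_csv(p_bin, sep="\t", index=False)
                with open(p_cor, "w") as fh:
                    json.dump(
                        {
                            "pearson_r_preandmrna": result.pearson_r_preandmrna,
                            "pearson_r_transcript": result.pearson_r_transcript,
                            "n_zero_excluded": result.n_zero_excluded,
                            "nmer": result.nmer,
                        },
                        fh, sort_keys=True, indent=2,
                    )
                record(p_gene, p_bin, p_cor)

            elif stage == "celltype":
                m, labels, markers = simulate_celltype_mixture(
                    n_types=int(params.get("n_types", 3)),
                    markers_per_type=int(params.get("markers_per_type", 20)),
                    fold_change=float(params.get("fold_change", 10.0)),
                    n_cells_per_type=int(params.get("n_cells_per_type", 100)),
                    seed=seeds[stage],
                )
                profiles = reference_profiles_from_labels(m)
                marker_set = MarkerSet.from_table(markers)
                assigned = spearman_annotate(
                    m, profiles, marker_set,
                    prune_delta=float(params.get("prune_delta", 0.05)),
                )
                table = concordance(labels, assigned)
                types = sorted(marker_set.markers)
                ratio = marker_ratio(
                    m, marker_set.markers[types[0]], marker_set.markers[types[1]]
                )
                mix_paths = nio.write_mtx_dir(m, os.path.join(out, "mixture_counts"))
                p_asn = os.path.join(out, "assigned_labels.tsv")
                p_con = os.path.join(out, "concordance.tsv")
                p_rat = os.path.join(out, "marker_ratio.tsv")
                nio.write_labels_tsv(assigned, p_asn)
                table.to_csv(p_con, sep="\t")
                ratio.to_csv(p_rat, sep="\t", header=True)
                record(*mix_paths.values(), p_asn, p_con, p_rat)

        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        logger.info("stage %s done in %.2fs", stage, time.monotonic() - t0)

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": config.stages,
        "files": files,
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest


def demo_report(outdir: str) -> dict:
    """Render the distribution panels and length-bias plots from a
    pipeline output directory and summarize the BIC ranking.

    Needs the fit_dist and length_bias stage outputs; missing inputs are
    named in the error.
    """
    import matplotlib.pyplot as plt

    from . import plots

    required = {
        "summary": os.path.join(outdir, "summary.tsv"),
        "model_comparison": os.path.join(outdir, "model_comparison.json"),
        "gof_qq": os.path.join(outdir, "gof_qq.tsv"),
        "lengthbias_per_gene": os.path.join(outdir, "lengthbias_per_gene.tsv"),
        "lengthbias_per_bin": os.path.join(outdir, "lengthbias_per_bin.tsv"),
    }
    missing = [name for name, p in required.items() if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(
            f"demo_report inputs missing from {outdir}: {missing}"
        )
    summary = pd.read_csv(required["summary"], sep="\t", index_col=0)
    with open(required["model_comparison"]) as fh:
        comparison = json.load(fh)
    qq = pd.read_csv(required["gof_qq"], sep="\t")
    per_gene = pd.read_csv(required["lengthbias_per_gene"], sep="\t", index_col=0)
    per_bin = pd.read_csv(required["lengthbias_per_bin"], sep="\t")

    fig, axes = plt.subplots(1, 4, figsize=(16, 3.6))
    plots.plot_mean_variance(summary, ax=axes[0])
    plots.plot_zero_fraction(summary, ax=axes[1])
    plots.plot_bic(pd.DataFrame(comparison["models"]), ax=axes[2])
    plots.plot_gof_qq(qq, ax=axes[3])
    fig.tight_layout()
    p_dist = os.path.join(outdir, "distribution_panels.png")
    fig.savefig(p_dist, dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    plots.plot_length_bins(per_bin, ax=axes[0])
    plots.plot_polya_trend(per_gene, ax=axes[1])
    fig.tight_layout()
    p_len = os.path.join(outdir, "lengthbias_panels.png")
    fig.savefig(p_len, dpi=120)
    plt.close(fig)

    report = {
        "best_model": comparison["best_model"],
        "bic": {row["model"]: row["bic"] for row in comparison["models"]},
        "figures": [p_dist, p_len],
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
    return report
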