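"""Readers/writers for the on-disk formats: 10x-style MTX triplet
(matrix.mtx + features.tsv + barcodes.tsv), label TSVs, and FASTA."""

from __future__ import annotations

import os
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import UMICountMatrix


def write_mtx_dir(m: UMICountMatrix, outdir: str | os.PathLike) -> Dict[str, str]:
    """Write the 10x triplet dialect: genes x cells matrix.mtx,
    features.tsv (id, name, type), barcodes.tsv; labels.tsv if present."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "matrix.mtx"),
        "features": os.path.join(outdir, "features.tsv"),
        "barcodes": os.path.join(outdir, "barcodes.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], m.counts.tocoo(), field="integer")
    pd.DataFrame(
        {
            "id": m.gene_ids,
            "name": m.gene_ids,
            "type": "Gene Expression",
        }
    ).to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(m.barcodes).to_csv(
        paths["barcodes"], sep="\t", header=False, index=False
    )
    if m.labels is not None:
        paths["labels"] = os.path.join(outdir, "labels.tsv")
        write_labels_tsv(m.labels, paths["labels"])
    return paths


def read_mtx_dir(indir: str | os.PathLike) -> UMICountMatrix:
    """Read a triplet directory written by :func:`write_mtx_dir` (labels
    are picked up from labels.tsv when present)."""
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(indir, "matrix.mtx")))
    features = pd.read_csv(
        os.path.join(indir, "features.tsv"), sep="\t", header=None
    )
    barcodes = pd.read_csv(
        os.path.join(indir, "barcodes.tsv"), sep="\t", header=None
    )
    labels_path = os.path.join(indir, "labels.tsv")
    labels = read_labels_tsv(labels_path) if os.path.exists(labels_path) else None
    return UMICountMatrix(
        counts=counts,
        gene_ids=features[0].to_numpy(dtype=object),
        barcodes=barcodes[0].to_numpy(dtype=object),
        labels=labels,
    )


def write_labels_tsv(labels: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame({"barcode": labels.index, "celltype": labels.values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_labels_tsv(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "celltype"])
    return pd.Series(
        df["celltype"].to_numpy(), index=df["barcode"].to_numpy(), name="celltype"
    )


def write_genome_fasta(
    genome: Mapping[str, str], path: str | os.PathLike
) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | os.PathLike) -> Dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
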