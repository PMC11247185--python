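import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from nucdist.genes import GeneModel, GeneModelSet
from nucdist.matrix import UMICountMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(counts, labels=None, gene_ids=None, barcodes=None):
    counts = np.asarray(counts)
    g, c = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    barcodes = barcodes or [f"c{j}" for j in range(c)]
    if labels is not None:
        labels = pd.Series(list(labels), index=barcodes)
    return UMICountMatrix(sp.csr_matrix(counts), gene_ids, barcodes, labels=labels)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1, 2, 0], [0, 0, 3], [4, 0, 0]])


@pytest.fixture
def labeled_matrix():
    return make_matrix(
        [[5, 1, 0, 2], [0, 4, 3, 1], [2, 2, 2, 2]],
        labels=["A", "A", "B", "A"],
    )


@pytest.fixture
def toy_gene():
    """One plus-strand gene, two exons [0,3) and [6,9) on a 9 bp chromosome."""
    gene = GeneModel(chromosome="chr1", strand="+")
    gene.transcripts["t1"] = [(0, 3), (6, 9)]
    return gene


@pytest.fixture
def toy_models(toy_gene):
    return GeneModelSet({"geneA": toy_gene})


@pytest.fixture
def toy_genome():
    return {"chr1": "ACGTTTGCA"}
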