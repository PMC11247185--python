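"""Intron-aware reference transcriptome construction.

Four reference kinds are supported, differing in how intronic sequence is
incorporated as quantification targets:

``transcripts``
    spliced transcripts only (exon concatenations);
``preandmrna``
    spliced transcripts plus the unspliced (pre-mRNA) span of every
    transcript;
``intronseparate``
    spliced transcripts plus one target per exon gap of every transcript,
    flank-extended (may overlap exons of sibling isoforms);
``introncollapse``
    spliced transcripts plus, per gene, the maximal intervals of the gene
    span that are exonic in no isoform, flank-extended.

Flanks (default 50 bp, one read length) are added to final intron
intervals to capture reads spanning exon/intron junctions, then clipped at
chromosome bounds. Intron targets inherit the gene strand. The bundle also
carries the transcript-to-gene map and the decoy list (all genome
sequences) of the salmon-compatible reference triple; building an index is
out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq

from .genes import GeneModel, GeneModelSet, Interval

REFERENCE_KINDS = ("transcripts", "preandmrna", "introncollapse", "intronseparate")
DEFAULT_FLANK_BP = 50


@dataclass
class TargetSequence:
    target_id: str
    category: str  # spliced | unspliced | intron
    gene_id: str
    transcript_id: str  # empty for collapse introns
    sequence: str
    chromosome: str = ""
    start: int = 0
    end: int = 0


@dataclass
class TargetSequenceSet:
    entries: List[TargetSequence] = field(default_factory=list)
    reference_kind: str = ""
    flank_bp: int = 0

    def __post_init__(self) -> None:
        ids = [e.target_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("target_ids must be unique")
        for e in self.entries:
            if not e.sequence:
                raise ValueError(f"empty sequence for target {e.target_id}")

    def __len__(self) -> int:
        return len(self.entries)

    def by_category(self, category: str) -> List[TargetSequence]:
        return [e for e in self.entries if e.category == category]

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.target_id}\n")
                for i in range(0, len(e.sequence), width):
                    fh.write(e.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _extract(
    genome: Mapping[str, str],
    chromosome: str,
    start: int,
    end: int,
    strand: str,
    who: str,
) -> str:
    if chromosome not in genome:
        raise KeyError(f"unknown chromosome {chromosome!r} for {who}")
    chrom = genome[chromosome]
    if start < 0 or end > len(chrom):
        raise ValueError(
            f"interval [{start},{end}) of {who} outside chromosome "
            f"{chromosome} (length {len(chrom)})"
        )
    seq = chrom[start:end].upper()
    return reverse_complement(seq) if strand == "-" else seq


def _sorted_entries(entries: List[TargetSequence]) -> List[TargetSequence]:
    # stable output order: gene, transcript, genomic start
    return sorted(entries, key=lambda e: (e.gene_id, e.transcript_id, e.start))


def transcript_introns(exons: Sequence[Interval]) -> List[Interval]:
    """Gaps between consecutive exons of one transcript."""
    return [
        (exons[i][1], exons[i + 1][0])
        for i in range(len(exons) - 1)
        if exons[i + 1][0] > exons[i][1]
    ]


def exon_union(gene: GeneModel) -> List[Interval]:
    """Merged union of all exons over all isoforms of a gene."""
    ivals = sorted(ex for exons in gene.transcripts.values() for ex in exons)
    merged: List[Interval] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def spliced_transcript_sequences(
    models: GeneModelSet, genome: Mapping[str, str]
) -> TargetSequenceSet:
    """One target per transcript: exon sequences concatenated in genomic
    order, reverse-complemented for minus-strand genes."""
    entries = []
    for gid, gene in models.genes.items():
        for tid, exons in gene.transcripts.items():
            plus = "".join(
                _extract(genome, gene.chromosome, s, e, "+", tid)
                for s, e in exons
            )
            seq = reverse_complement(plus) if gene.strand == "-" else plus
            entries.append(
                TargetSequence(
                    target_id=tid,
                    category="spliced",
                    gene_id=gid,
                    transcript_id=tid,
                    sequence=seq,
                    chromosome=gene.chromosome,
                    start=exons[0][0],
                    end=exons[-1][1],
                )
            )
    return TargetSequenceSet(_sorted_entries(entries), "transcripts", 0)


def unspliced_transcript_sequences(
    models: GeneModelSet, genome: Mapping[str, str]
) -> TargetSequenceSet:
    """One pre-mRNA target per transcript: the genomic span from first exon
    start to last exon end (introns re-added), strand-adjusted."""
    entries = []
    for gid, gene in models.genes.items():
        for tid, exons in gene.transcripts.items():
            start, end = exons[0][0], exons[-1][1]
            seq = _extract(genome, gene.chromosome, start, end, gene.strand, tid)
            entries.append(
                TargetSequence(
                    target_id=f"{tid}-U",
                    category="unspliced",
                    gene_id=gid,
                    transcript_id=tid,
                    sequence=seq,
                    chromosome=gene.chromosome,
                    start=start,
                    end=end,
                )
            )
    return TargetSequenceSet(_sorted_entries(entries), "preandmrna", 0)


def _flank_clip(
    ivals: Sequence[Interval], flank_bp: int, chrom_len: int
) -> List[Interval]:
    return [
        (max(0, s - flank_bp), min(chrom_len, e + flank_bp)) for s, e in ivals
    ]


def intron_targets_separate(
    models: GeneModelSet,
    genome: Mapping[str, str],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> TargetSequenceSet:
    """Per-transcript intron targets: one per exon gap, flank-extended.

    These may overlap exonic regions of other isoforms of the gene.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    entries = []
    for gid, gene in models.genes.items():
        chrom_len = len(genome[gene.chromosome])
        for tid, exons in gene.transcripts.items():
            gaps = _flank_clip(transcript_introns(exons), flank_bp, chrom_len)
            for i, (s, e) in enumerate(gaps, start=1):
                seq = _extract(genome, gene.chromosome, s, e, gene.strand, tid)
                entries.append(
                    TargetSequence(
                        target_id=f"{tid}-I{i}",
                        category="intron",
                        gene_id=gid,
                        transcript_id=tid,
                        sequence=seq,
                        chromosome=gene.chromosome,
                        start=s,
                        end=e,
                    )
                )
    return TargetSequenceSet(_sorted_entries(entries), "intronseparate", flank_bp)


def intron_targets_collapse(
    models: GeneModelSet,
    genome: Mapping[str, str],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> TargetSequenceSet:
    """Gene-level intron targets: intervals of the gene span exonic in no
    isoform, flank-extended after collapsing."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    entries = []
    for gid, gene in models.genes.items():
        chrom_len = len(genome[gene.chromosome])
        span_start, span_end = gene.span
        union = exon_union(gene)
        introns: List[Interval] = []
        cursor = span_start
        for s, e in union:
            if s > cursor:
                introns.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < span_end:
            introns.append((cursor, span_end))
        introns = _flank_clip(introns, flank_bp, chrom_len)
        for i, (s, e) in enumerate(introns, start=1):
            seq = _extract(genome, gene.chromosome, s, e, gene.strand, gid)
            entries.append(
                TargetSequence(
                    target_id=f"{gid}-I{i}",
                    category="intron",
                    gene_id=gid,
                    transcript_id="",
                    sequence=seq,
                    chromosome=gene.chromosome,
                    start=s,
                    end=e,
                )
            )
    return TargetSequenceSet(_sorted_entries(entries), "introncollapse", flank_bp)


@dataclass
class ReferenceBundle:
    """A complete reference: targets + transcript-to-gene map + decoys."""

    targets: TargetSequenceSet
    t2g: pd.DataFrame  # columns: target_id, gene_id
    decoys: List[str]

    def write(self, outdir: str | os.PathLike) -> Dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "reference.fa"),
            "t2g": os.path.join(outdir, "t2g.tsv"),
            "decoys": os.path.join(outdir, "decoys.txt"),
        }
        self.targets.to_fasta(paths["fasta"])
        self.t2g.to_csv(paths["t2g"], sep="\t", header=False, index=False)
        with open(paths["decoys"], "w") as fh:
            for name in self.decoys:
                fh.write(name + "\n")
        return paths


def build_reference(
    models: GeneModelSet,
    genome: Mapping[str, str],
    kind: str,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> ReferenceBundle:
    """Assemble one of the four reference transcriptomes.

    Every kind includes the spliced transcripts; the other three add
    intronic sequence per their definition. The decoy list names all genome
    sequences so an index built downstream is decoy-aware.
    """
    if kind not in REFERENCE_KINDS:
        raise ValueError(f"unknown reference kind {kind!r}; one of {REFERENCE_KINDS}")
    spliced = spliced_transcript_sequences(models, genome)
    entries = list(spliced.entries)
    if kind == "preandmrna":
        entries += unspliced_transcript_sequences(models, genome).entries
    elif kind == "intronseparate":
        entries += intron_targets_separate(models, genome, flank_bp).entries
    elif kind == "introncollapse":
        entries += intron_targets_collapse(models, genome, flank_bp).entries
    targets = TargetSequenceSet(
        _sorted_entries(entries), kind, 0 if kind in ("transcripts", "preandmrna") else flank_bp
    )
    t2g = pd.DataFrame(
        [(e.target_id, e.gene_id) for e in targets.entries],
        columns=["target_id", "gene_id"],
    )
    return ReferenceBundle(targets=targets, t2g=t2g, decoys=sorted(genome))
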