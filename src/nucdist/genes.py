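"""Gene model containers and GTF round-trip.

Internally every interval is 0-based half-open ``(start, end)``; the GTF
reader/writer converts to and from the format's 1-based closed convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

Interval = Tuple[int, int]


@dataclass
class GeneModel:
    """One gene: its location and the exon chains of its isoforms."""

    chromosome: str
    strand: str
    transcripts: Dict[str, List[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def span(self) -> Interval:
        starts = [ex[0] for exons in self.transcripts.values() for ex in exons]
        ends = [ex[1] for exons in self.transcripts.values() for ex in exons]
        return min(starts), max(ends)


@dataclass
class GeneModelSet:
    """All gene models of an annotation, keyed by gene id."""

    genes: Dict[str, GeneModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, gene in self.genes.items():
            for tid, exons in gene.transcripts.items():
                if not exons:
                    raise ValueError(f"transcript {tid} of {gid} has no exons")
                prev_end = -1
                for start, end in exons:
                    if start >= end:
                        raise ValueError(
                            f"empty/inverted exon ({start},{end}) in {tid}"
                        )
                    if start < prev_end:
                        raise ValueError(
                            f"exons of {tid} overlap or are unsorted"
                        )
                    prev_end = end

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    # -- GTF I/O ---------------------------------------------------------
    @classmethod
    def from_gtf(cls, path: str | os.PathLike) -> "GeneModelSet":
        """Parse a GTF annotation into gene models (via gffutils)."""
        import gffutils

        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        genes: Dict[str, GeneModel] = {}
        for tr in db.features_of_type("transcript"):
            gid = tr.attributes["gene_id"][0]
            tid = tr.attributes["transcript_id"][0]
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(tr, featuretype="exon")
            )
            gene = genes.setdefault(gid, GeneModel(tr.seqid, tr.strand))
            if gene.chromosome != tr.seqid or gene.strand != tr.strand:
                raise ValueError(
                    f"transcript {tid} disagrees with gene {gid} "
                    "on chromosome or strand"
                )
            gene.transcripts[tid] = exons
        return cls(genes)

    def to_gtf(self, path: str | os.PathLike, source: str = "nucdist") -> None:
        """Write gene/transcript/exon lines, 1-based closed coordinates."""
        with open(path, "w") as fh:
            for gid in sorted(self.genes):
                gene = self.genes[gid]
                g0, g1 = gene.span
                attrs = f'gene_id "{gid}";'
                fh.write(
                    f"{gene.chromosome}\t{source}\tgene\t{g0 + 1}\t{g1}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                for tid in sorted(gene.transcripts):
                    exons = gene.transcripts[tid]
                    t0, t1 = exons[0][0], exons[-1][1]
                    tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                    fh.write(
                        f"{gene.chromosome}\t{source}\ttranscript\t{t0 + 1}\t"
                        f"{t1}\t.\t{gene.strand}\t.\t{tattrs}\n"
                    )
                    for i, (s, e) in enumerate(exons, start=1):
                        eattrs = tattrs + f' exon_number "{i}";'
                        fh.write(
                            f"{gene.chromosome}\t{source}\texon\t{s + 1}\t{e}"
                            f"\t.\t{gene.strand}\t.\t{eattrs}\n"
                        )
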