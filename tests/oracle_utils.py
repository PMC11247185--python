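"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval arithmetic and regex
machinery: interval questions are answered base by base, and poly-A runs
are found by a character-by-character scan.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

Interval = Tuple[int, int]


def bases_to_intervals(positions: Sequence[int]) -> List[Interval]:
    """Collapse a sorted iterable of base positions into maximal intervals."""
    intervals: List[Interval] = []
    for p in positions:
        if intervals and p == intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], p + 1)
        else:
            intervals.append((p, p + 1))
    return intervals


def collapse_introns_oracle(gene, flank: int = 0, chrom_len: int = None) -> List[Interval]:
    """Per-base classifier: a base of the gene span is collapse-intronic
    iff it is exonic in no isoform. Flank extension and clipping applied
    interval by interval afterwards."""
    exonic = set()
    for exons in gene.transcripts.values():
        for s, e in exons:
            exonic.update(range(s, e))
    span_start = min(s for exons in gene.transcripts.values() for s, _ in exons)
    span_end = max(e for exons in gene.transcripts.values() for _, e in exons)
    intronic = [p for p in range(span_start, span_end) if p not in exonic]
    ivals = bases_to_intervals(intronic)
    if flank:
        ivals = [
            (max(0, s - flank), min(chrom_len, e + flank)) for s, e in ivals
        ]
    return ivals


def separate_introns_oracle(
    exons: Sequence[Interval], flank: int = 0, chrom_len: int = None
) -> List[Interval]:
    """Per-base classifier for one transcript: a base between the first
    exon start and last exon end is intronic iff it lies in no exon."""
    covered = set()
    for s, e in exons:
        covered.update(range(s, e))
    start, end = exons[0][0], exons[-1][1]
    intronic = [p for p in range(start, end) if p not in covered]
    ivals = bases_to_intervals(intronic)
    if flank:
        ivals = [
            (max(0, s - flank), min(chrom_len, e + flank)) for s, e in ivals
        ]
    return ivals


def polyA_runs_oracle(sequence: str, n: int) -> int:
    """Character-by-character scan for maximal A-runs of length >= n."""
    count = 0
    run = 0
    for ch in sequence.upper() + "$":  # sentinel flushes a trailing run
        if ch == "A":
            run += 1
        else:
            if run >= n:
                count += 1
            run = 0
    return count


def polyA_windows_oracle(sequence: str, n: int) -> int:
    """Brute-force sliding window: count every n-window of all A's."""
    seq = sequence.upper()
    return sum(
        1 for i in range(len(seq) - n + 1) if set(seq[i : i + n]) == {"A"}
    )


def quantile_oracle(values: Sequence[float], q: float) -> float:
    """Order statistic with linear interpolation between closest ranks."""
    v = sorted(values)
    if len(v) == 1:
        return float(v[0])
    h = (len(v) - 1) * q
    lo = int(h)
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))
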