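"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by the most literal possible
method (linear scans, exhaustive enumeration, direct formulas) without
touching the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

from lncwhiten.model import PositionalCategory, TranscriptModel


def overlaps(a1: int, a2: int, b1: int, b2: int) -> bool:
    return a1 < b2 and b1 < a2


def classify_bruteforce(
    t: TranscriptModel, reference: Sequence[TranscriptModel]
) -> PositionalCategory:
    """Literal re-statement of the classification cascade by pairwise scans."""
    ref = [r for r in reference if r.chrom == t.chrom]
    if not any(True for r in reference if r.chrom == t.chrom):
        return PositionalCategory.LINCRNA

    same_exon = False
    anti_exon = False
    for r in ref:
        for re_ in r.exons:
            for te in t.exons:
                if overlaps(te.start, te.end, re_.start, re_.end):
                    if r.strand == t.strand:
                        same_exon = True
                    else:
                        anti_exon = True
    if same_exon:
        chain = t.intron_chain()
        if chain and any(
            r.strand == t.strand and r.intron_chain() == chain for r in ref
        ):
            return PositionalCategory.REJECTED_KNOWN
        return PositionalCategory.SENSE_OVERLAPPING
    if anti_exon:
        return PositionalCategory.ANTISENSE

    span = t.span
    for r in ref:
        for (a, b) in r.intron_chain():
            if a <= span.start and span.end <= b:
                return PositionalCategory.INTRONIC

    # gene body = union span over transcripts of the gene
    bodies: dict[str, list[int]] = {}
    for r in ref:
        s, e = r.span.start, r.span.end
        if r.gene_id in bodies:
            bodies[r.gene_id][0] = min(bodies[r.gene_id][0], s)
            bodies[r.gene_id][1] = max(bodies[r.gene_id][1], e)
        else:
            bodies[r.gene_id] = [s, e]
    if not any(overlaps(span.start, span.end, s, e) for s, e in bodies.values()):
        return PositionalCategory.LINCRNA
    return PositionalCategory.REJECTED_KNOWN


def longest_orf_bruteforce(seq: str) -> int:
    """Scan every (ATG, stop) pair in every forward frame."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for stop in range(start + 3, len(seq) - 2, 3):
            codon = seq[stop : stop + 3]
            if codon in stops:
                best = max(best, (stop - start) // 3)
                break
    return best


def pearson_by_formula(x: Sequence[float], y: Sequence[float]) -> float:
    """Direct product-moment evaluation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def bh_stepup(pvalues: Sequence[float]) -> list[float]:
    """Hand application of the Benjamini-Hochberg step-up procedure."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def hypergeom_by_enumeration(
    universe_size: int, pathway_size: int, query_size: int, overlap: int
) -> float:
    """P(X >= overlap) by exhaustive enumeration of all draws of query_size
    elements from a universe containing pathway_size successes."""
    universe = list(range(universe_size))
    pathway = set(range(pathway_size))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(pathway & set(draw)) >= overlap:
            hits += 1
    return hits / total


def complement_within_span(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set complement of exons inside the transcript span."""
    exons = sorted(exons)
    span = (exons[0][0], exons[-1][1])
    out = []
    cursor = span[0]
    for s, e in exons:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    return out
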