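"""Strand-aware annotation index over reference genes, exons and introns.

Backed by one :class:`intervaltree.IntervalTree` per chromosome and layer
(gene bodies, exons, introns). Gene body = union span of all transcripts of
the gene. The index also keeps the intron chains of all multi-exon reference
transcripts so a query transcript can be checked for an exact structural
match (the signature of an already-annotated isoform).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from intervaltree import IntervalTree

from .model import (
    GenomicInterval,
    TranscriptModel,
    ValidationError,
    derive_introns,
)


@dataclass(frozen=True)
class _ExonHit:
    gene_id: str
    transcript_id: str
    strand: str


@dataclass(frozen=True)
class _IntronHit:
    gene_id: str
    transcript_id: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


class AnnotationIndex:
    """Overlap-query index over a reference annotation."""

    def __init__(self, reference: Iterable[TranscriptModel]) -> None:
        reference = list(reference)
        seen: set[str] = set()
        for t in reference:
            if t.transcript_id in seen:
                raise ValidationError(
                    f"duplicate transcript_id {t.transcript_id!r} in reference"
                )
            seen.add(t.transcript_id)

        self._gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._intron_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.biotype: dict[str, str] = {}
        self._intron_chains: dict[tuple[str, str], set[tuple[tuple[int, int], ...]]]
        self._intron_chains = defaultdict(set)
        self.genes: dict[str, GeneLocus] = {}

        spans: dict[str, list[TranscriptModel]] = defaultdict(list)
        for t in reference:
            spans[t.gene_id].append(t)
        for gene_id, ts in spans.items():
            chroms = {t.chrom for t in ts}
            strands = {t.strand for t in ts}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValidationError(
                    f"gene {gene_id} has transcripts on mixed chromosomes/strands"
                )
            start = min(t.span.start for t in ts)
            end = max(t.span.end for t in ts)
            biotypes = {t.biotype for t in ts}
            biotype = (
                "protein_coding"
                if "protein_coding" in biotypes
                else ("lncRNA" if "lncRNA" in biotypes else "other")
            )
            locus = GeneLocus(gene_id, ts[0].chrom, start, end, ts[0].strand, biotype)
            self.genes[gene_id] = locus
            self.biotype[gene_id] = biotype
            self._gene_trees[locus.chrom].addi(start, end, locus)

        for t in reference:
            for exon in t.exons:
                self._exon_trees[t.chrom].addi(
                    exon.start, exon.end, _ExonHit(t.gene_id, t.transcript_id, t.strand)
                )
            for intron in derive_introns(t):
                self._intron_trees[t.chrom].addi(
                    intron.start,
                    intron.end,
                    _IntronHit(
                        t.gene_id, t.transcript_id, t.strand, intron.start, intron.end
                    ),
                )
            chain = t.intron_chain()
            if chain:
                self._intron_chains[(t.chrom, t.strand)].add(chain)

        self.reference = reference

    # -- queries ---------------------------------------------------------

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._gene_trees

    def genes_overlapping(
        self, chrom: str, start: int, end: int, biotype: str | None = None
    ) -> list[GeneLocus]:
        hits = [iv.data for iv in self._gene_trees.get(chrom, IntervalTree()).overlap(start, end)]
        if biotype is not None:
            hits = [g for g in hits if g.biotype == biotype]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    def exons_overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[_ExonHit]:
        hits = [iv.data for iv in self._exon_trees.get(chrom, IntervalTree()).overlap(start, end)]
        if strand is not None:
            hits = [h for h in hits if h.strand == strand]
        return hits

    def introns_containing(self, chrom: str, start: int, end: int) -> list[_IntronHit]:
        """Reference introns that fully contain ``[start, end)``."""
        hits = [iv.data for iv in self._intron_trees.get(chrom, IntervalTree()).overlap(start, end)]
        return [h for h in hits if h.start <= start and end <= h.end]

    def has_intron_chain(
        self, chrom: str, strand: str, chain: tuple[tuple[int, int], ...]
    ) -> bool:
        """True iff some multi-exon reference transcript has exactly this chain."""
        return bool(chain) and chain in self._intron_chains.get((chrom, strand), set())


def build_annotation_index(reference: Iterable[TranscriptModel]) -> AnnotationIndex:
    """Build the strand-aware overlap index from reference transcripts."""
    return AnnotationIndex(reference)
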