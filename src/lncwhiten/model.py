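"""Core domain types for the lncRNA pipeline.

All genomic coordinates are held internally in the 0-based half-open
convention ``[start, end)``; conversion to/from 1-based inclusive GTF
coordinates happens only at the I/O boundary (:mod:`lncwhiten.gtf`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

PREDICTORS = ("CPC2", "CPAT", "CNCI", "Pfam")

#: Ordered developmental stages of the interscapular adipose tissue time course:
#: infant (classical brown fat), early whitening, puberty, aged (fully whitened).
DEFAULT_STAGES = ("D0", "D15", "D85", "Y2")


class ValidationError(ValueError):
    """An object violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a chromosome.

    ``strand`` may be ``"."`` only for bare query intervals; transcripts
    are always stranded.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between closest boundaries; 0 if the intervals touch
        or overlap. Undefined across chromosomes (raises)."""
        if self.chrom != other.chrom:
            raise ValidationError("gap undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(other.start - self.end, self.start - other.end, 0)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered, non-overlapping exons on one chromosome/strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    source: str = "novel"  # {reference, novel}
    biotype: str = "other"  # {protein_coding, lncRNA, other}

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        if self.source not in ("reference", "novel"):
            raise ValidationError(f"invalid source {self.source!r}")
        prev_end = -1
        for exon in self.exons:
            if exon.chrom != self.chrom or exon.strand not in (self.strand, "."):
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon on different "
                    "chromosome or strand"
                )
            if exon.start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = exon.end

    @property
    def length(self) -> int:
        """Spliced transcript length (sum of exon lengths)."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """The ordered (start, end) pairs of introns; empty for single-exon."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )


def derive_introns(t: TranscriptModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons; empty for a single-exon transcript.

    Exons and introns together tile the transcript span exactly.
    """
    return [
        GenomicInterval(t.chrom, a, b, t.strand) for a, b in t.intron_chain() if b > a
    ]


class PositionalCategory(str, enum.Enum):
    """Positional class of a candidate lncRNA relative to annotated genes."""

    LINCRNA = "lincRNA"
    ANTISENSE = "antisense"
    INTRONIC = "intronic"
    SENSE_OVERLAPPING = "sense_overlapping"
    REJECTED_KNOWN = "rejected_known"


#: The four categories retained as credible lncRNAs.
LNCRNA_CATEGORIES = (
    PositionalCategory.LINCRNA,
    PositionalCategory.ANTISENSE,
    PositionalCategory.INTRONIC,
    PositionalCategory.SENSE_OVERLAPPING,
)


@dataclass(frozen=True)
class CisTarget:
    """A protein-coding gene assigned as potential cis-regulated target."""

    gene_id: str
    relationship: str  # {host, flank}
    distance: int  # bp gap; 0 for host

    def __post_init__(self) -> None:
        if self.relationship not in ("host", "flank"):
            raise ValidationError(f"invalid relationship {self.relationship!r}")
        if self.distance < 0:
            raise ValidationError("distance must be >= 0")


@dataclass
class LncRNARecord:
    """A retained lncRNA with positional category and cis targets."""

    transcript: TranscriptModel
    category: PositionalCategory
    origin: str  # {novel, annotated}
    cis_targets: list[CisTarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.origin not in ("novel", "annotated"):
            raise ValidationError(f"invalid origin {self.origin!r}")
        if self.category == PositionalCategory.REJECTED_KNOWN:
            raise ValidationError("rejected transcripts are not lncRNA records")

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson correlation outcome for one (lncRNA, cis-target) pair."""

    lncrna_id: str
    gene_id: str
    r: float
    p: float
    klass: str  # {pos, neg, ns}
    category: PositionalCategory | None = None

    def __post_init__(self) -> None:
        if self.klass not in ("pos", "neg", "ns"):
            raise ValidationError(f"invalid class {self.klass!r}")


@dataclass(frozen=True)
class DEResult:
    """Differential-expression outcome for one feature in one comparison."""

    feature_id: str
    comparison: str  # "B_vs_A"
    log2fc: float
    p: float
    fdr: float
    status: str  # {up, down, ns}


class ExpressionMatrix:
    """Features x samples expression table (raw counts or TPM) plus metadata.

    Wraps a :class:`pandas.DataFrame` (rows = features, columns = samples)
    and a sample metadata frame with ``stage`` and ``replicate`` columns.
    Counts must be non-negative integers; TPM any non-negative real.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        kind: str,
        metadata: pd.DataFrame,
    ) -> None:
        if kind not in ("counts", "TPM"):
            raise ValidationError(f"kind must be counts or TPM, got {kind!r}")
        if (values.to_numpy() < 0).any():
            raise ValidationError(f"{kind} matrix contains negative values")
        if kind == "counts":
            arr = values.to_numpy()
            if not np.allclose(arr, np.round(arr), atol=0, rtol=0):
                raise ValidationError("count matrix contains non-integral values")
            values = values.round().astype(np.int64)
        missing = [s for s in values.columns if s not in metadata.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        if "stage" not in metadata.columns:
            raise ValidationError("metadata must have a 'stage' column")
        self.values = values
        self.kind = kind
        self.metadata = metadata.loc[list(values.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stages in order of first appearance in the metadata."""
        seen: list[str] = []
        for s in self.metadata["stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_for_stage(self, stage: str) -> list[str]:
        return list(self.metadata.index[self.metadata["stage"] == stage])

    def stage_means(self) -> pd.DataFrame:
        """Replicate-mean expression per stage (features x stages)."""
        out = {}
        for stage in self.stages:
            cols = self.samples_for_stage(stage)
            if not cols:
                raise ValidationError(f"stage {stage} has no samples")
            out[stage] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out, index=self.values.index)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.values.index


class CodingPotentialCalls:
    """Merged coding-potential calls from the four predictors.

    ``calls[transcript_id][predictor]`` is one of ``coding``, ``noncoding``
    or ``missing``; predictors are fixed to CPC2, CPAT, CNCI and Pfam.
    """

    def __init__(self, calls: Mapping[str, Mapping[str, str]]) -> None:
        self.calls: dict[str, dict[str, str]] = {}
        for tid, per_pred in calls.items():
            row = {}
            for pred, call in per_pred.items():
                if pred not in PREDICTORS:
                    raise ValidationError(f"unknown predictor {pred!r}")
                if call not in ("coding", "noncoding", "missing"):
                    raise ValidationError(f"invalid call {call!r}")
                row[pred] = call
            for pred in PREDICTORS:
                row.setdefault(pred, "missing")
            self.calls[tid] = row

    def __contains__(self, tid: str) -> bool:
        return tid in self.calls

    def __getitem__(self, tid: str) -> dict[str, str]:
        return self.calls[tid]

    def transcript_ids(self) -> list[str]:
        return list(self.calls)


def category_breakdown(
    records: Sequence[LncRNARecord],
) -> dict[str, int]:
    """Counts per positional category plus ``total``; the per-category counts
    always sum to the total (partition invariant)."""
    counts = {c.value: 0 for c in LNCRNA_CATEGORIES}
    for rec in records:
        counts[rec.category.value] += 1
    counts["total"] = len(records)
    return counts
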