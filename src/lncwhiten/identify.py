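"""Candidate lncRNA filtering, positional classification and the
four-predictor non-coding consensus.

A novel lncRNA must be >= 200 nt spliced, multi-exonic, expressed above
TPM 0.1 in at least one sample, fall into one of four positional
categories relative to the reference annotation (intergenic, antisense,
intronic, sense-overlapping), and be called non-coding by all four of
CPC2, CPAT, CNCI and Pfam.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .index import AnnotationIndex, build_annotation_index
from .model import (
    CodingPotentialCalls,
    ExpressionMatrix,
    LncRNARecord,
    LNCRNA_CATEGORIES,
    PositionalCategory,
    TranscriptModel,
    ValidationError,
    category_breakdown,
)

logger = logging.getLogger(__name__)

MIN_LENGTH = 200
MIN_EXONS = 2
MIN_TPM = 0.1

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def max_tpm(tpm: ExpressionMatrix, feature_id: str) -> float | None:
    """Max TPM across samples for a feature; None if absent from the matrix."""
    if feature_id in tpm:
        return float(tpm.row(feature_id).max())
    return None


def filter_structural(
    transcripts: Iterable[TranscriptModel],
    tpm: ExpressionMatrix,
    min_length: int = MIN_LENGTH,
    min_exons: int = MIN_EXONS,
    min_tpm: float = MIN_TPM,
    on_missing: str = "warn",
) -> list[TranscriptModel]:
    """Keep transcripts with spliced length >= min_length, >= min_exons exons
    and TPM strictly above min_tpm in at least one sample.

    Transcripts absent from the TPM matrix are dropped with a warning
    (``on_missing="warn"``) or raise (``on_missing="error"``).
    """
    retained = []
    for t in transcripts:
        value = max_tpm(tpm, t.transcript_id)
        if value is None and t.gene_id in tpm:
            value = float(tpm.row(t.gene_id).max())
        if value is None:
            if on_missing == "error":
                raise ValidationError(
                    f"transcript {t.transcript_id} absent from TPM matrix"
                )
            logger.warning(
                "transcript %s absent from TPM matrix; dropped", t.transcript_id
            )
            continue
        if t.length >= min_length and t.n_exons >= min_exons and value > min_tpm:
            retained.append(t)
    return retained


def classify_position(
    t: TranscriptModel, index: AnnotationIndex, strict: bool = False
) -> PositionalCategory:
    """Positional category of a candidate relative to the reference.

    Decision cascade (fixed precedence, mirroring gffcompare class codes
    =/o/x/i/u):

    1. same-strand exonic overlap AND the candidate's intron chain exactly
       matches a reference transcript -> rejected_known (an annotated isoform);
    2. same-strand exonic overlap otherwise -> sense_overlapping;
    3. opposite-strand exonic overlap -> antisense;
    4. entirely contained in a single intron of one reference transcript
       (either strand) -> intronic;
    5. no overlap with any gene body -> lincRNA;
    6. residual (touches a gene body but none of the above) -> rejected_known.

    A single-exon candidate has an empty intron chain, which never matches a
    reference chain, so step 1 cannot fire for it.
    """
    if not index.has_chrom(t.chrom):
        if strict:
            raise ValidationError(f"chromosome {t.chrom} absent from reference index")
        logger.warning(
            "chromosome %s absent from reference; %s classified lincRNA",
            t.chrom,
            t.transcript_id,
        )
        return PositionalCategory.LINCRNA

    opposite = "-" if t.strand == "+" else "+"
    same_hits = []
    anti_hits = []
    for exon in t.exons:
        same_hits.extend(index.exons_overlapping(t.chrom, exon.start, exon.end, t.strand))
        anti_hits.extend(index.exons_overlapping(t.chrom, exon.start, exon.end, opposite))

    if same_hits:
        if index.has_intron_chain(t.chrom, t.strand, t.intron_chain()):
            return PositionalCategory.REJECTED_KNOWN
        return PositionalCategory.SENSE_OVERLAPPING
    if anti_hits:
        return PositionalCategory.ANTISENSE

    span = t.span
    if index.introns_containing(t.chrom, span.start, span.end):
        return PositionalCategory.INTRONIC
    if not index.genes_overlapping(t.chrom, span.start, span.end):
        return PositionalCategory.LINCRNA
    return PositionalCategory.REJECTED_KNOWN


def consensus_noncoding(calls: CodingPotentialCalls, transcript_id: str) -> bool:
    """True iff all four predictors call the transcript non-coding.

    A ``missing`` call is conservatively treated as not-confirmed (False);
    the four-way intersection semantics mean one coding call suffices to
    reject.
    """
    if transcript_id not in calls:
        raise KeyError(f"transcript {transcript_id} absent from coding calls")
    per = calls[transcript_id]
    missing = [p for p, c in per.items() if c == "missing"]
    if missing:
        logger.warning(
            "transcript %s missing calls from %s; not confirmed noncoding",
            transcript_id,
            ",".join(missing),
        )
    return all(c == "noncoding" for c in per.values())


def longest_orf(sequence: str) -> int:
    """Length in codons (excluding the stop) of the longest forward-strand ORF.

    Scans the three forward frames for ATG...stop. Used as a deterministic
    stand-in predictor (non-coding iff < 100 codons) in end-to-end tests; it
    is NOT a replacement for the four external predictors.
    """
    seq = sequence.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValidationError(f"invalid nucleotide(s): {sorted(invalid)}")
    best = 0
    for frame in range(3):
        open_starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                open_starts.append(i)
            elif codon in _STOP_CODONS:
                if open_starts:
                    best = max(best, (i - open_starts[0]) // 3)
                open_starts = []
    return best


def identify_lncrnas(
    novel: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    tpm: ExpressionMatrix,
    calls: CodingPotentialCalls,
    min_length: int = MIN_LENGTH,
    min_exons: int = MIN_EXONS,
    min_tpm: float = MIN_TPM,
) -> tuple[list[LncRNARecord], dict[str, int]]:
    """End-to-end identification: structural filter -> positional
    classification -> non-coding consensus, then merge of reference-annotated
    lncRNAs.

    Annotated lncRNAs (reference biotype ``lncRNA``) bypass classification
    and join as category lincRNA with ``origin="annotated"``, subject only to
    the expression filter. Returns the records and a summary with per-category
    counts of novel lncRNAs, the annotated count and the grand total.
    """
    index = build_annotation_index(reference)
    records: list[LncRNARecord] = []

    structural = filter_structural(novel, tpm, min_length, min_exons, min_tpm)
    for t in structural:
        category = classify_position(t, index)
        if category not in LNCRNA_CATEGORIES:
            continue
        if t.transcript_id not in calls:
            logger.warning(
                "no coding-potential calls for %s; excluded", t.transcript_id
            )
            continue
        if not consensus_noncoding(calls, t.transcript_id):
            continue
        records.append(LncRNARecord(transcript=t, category=category, origin="novel"))

    summary = category_breakdown(records)
    summary["novel_total"] = summary.pop("total")

    n_annotated = 0
    for t in reference:
        if t.biotype != "lncRNA":
            continue
        value = max_tpm(tpm, t.transcript_id)
        if value is None and t.gene_id in tpm:
            value = float(tpm.row(t.gene_id).max())
        if value is None or value <= min_tpm:
            continue
        records.append(
            LncRNARecord(
                transcript=t, category=PositionalCategory.LINCRNA, origin="annotated"
            )
        )
        n_annotated += 1

    summary["annotated_total"] = n_annotated
    summary["grand_total"] = summary["novel_total"] + n_annotated
    return records, summary
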