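"""Cis-target assignment and lncRNA-target expression correlation.

Genic lncRNAs (antisense, intronic, sense-overlapping) take the
protein-coding gene(s) at their locus as potential cis targets; lincRNAs
take every protein-coding gene within a 100-kb flank. Association is
screened by Pearson correlation of TPM across all samples at raw p < 0.05
(no multiple-testing correction — the screen is a candidate filter, not an
inference), partitioned into positive / negative / non-significant.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .index import AnnotationIndex
from .model import (
    CisTarget,
    CorrelationRecord,
    ExpressionMatrix,
    LncRNARecord,
    LNCRNA_CATEGORIES,
    PositionalCategory,
    ValidationError,
)

logger = logging.getLogger(__name__)

CIS_WINDOW = 100_000
ALPHA = 0.05


def assign_cis_targets(
    record: LncRNARecord, index: AnnotationIndex, window: int = CIS_WINDOW
) -> LncRNARecord:
    """Attach potential cis-regulated protein-coding targets to a record.

    Genic categories: all protein-coding genes whose locus overlaps the
    lncRNA span (relationship ``host``, distance 0). lincRNA: all
    protein-coding genes whose body lies within ``window`` bp of the span
    (boundary inclusive), relationship ``flank`` with the gap distance.
    """
    if record.category not in LNCRNA_CATEGORIES:
        raise ValidationError(f"record {record.transcript_id} is unclassified")
    span = record.transcript.span
    targets: list[CisTarget] = []
    if record.category == PositionalCategory.LINCRNA:
        lo = max(0, span.start - window)
        hi = span.end + window
        for gene in index.genes_overlapping(span.chrom, lo, hi + 1, biotype="protein_coding"):
            # a lincRNA never overlaps a gene body, so gap 0 means adjacency
            gap = span.gap_to(gene.interval)
            if gap <= window:
                targets.append(CisTarget(gene.gene_id, "flank", gap))
    else:
        for gene in index.genes_overlapping(
            span.chrom, span.start, span.end, biotype="protein_coding"
        ):
            targets.append(CisTarget(gene.gene_id, "host", 0))
    record.cis_targets = targets
    return record


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p (t approximation on n-2 df).

    Zero variance in either vector gives ``(nan, nan)`` with a warning —
    the pair is untestable and should be reported non-significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError(f"need n >= 3 samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance vector; correlation undefined")
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_screen(
    records: Iterable[LncRNARecord],
    expr: ExpressionMatrix,
    alpha: float = ALPHA,
    log2p1: bool = False,
) -> list[CorrelationRecord]:
    """Pearson screen of every (lncRNA, cis-target) pair across all samples.

    ``log2p1`` switches the working scale to log2(TPM + 1). Pairs whose
    target gene is absent from the matrix are skipped with a warning;
    untestable pairs (zero variance) are reported ``ns``.
    """
    out: list[CorrelationRecord] = []
    for rec in records:
        lnc_id = rec.transcript_id
        if lnc_id in expr:
            x = expr.row(lnc_id)
        elif rec.transcript.gene_id in expr:
            x = expr.row(rec.transcript.gene_id)
        else:
            logger.warning("lncRNA %s absent from expression matrix; skipped", lnc_id)
            continue
        for target in rec.cis_targets:
            if target.gene_id not in expr:
                logger.warning(
                    "target %s of %s absent from expression matrix; pair skipped",
                    target.gene_id,
                    lnc_id,
                )
                continue
            y = expr.row(target.gene_id)
            xv, yv = (np.log2(x + 1), np.log2(y + 1)) if log2p1 else (x, y)
            r, p = pearson_with_p(xv, yv)
            if math.isnan(r) or math.isnan(p):
                klass = "ns"
            elif p < alpha:
                klass = "pos" if r > 0 else ("neg" if r < 0 else "ns")
            else:
                klass = "ns"
            out.append(
                CorrelationRecord(
                    lncrna_id=lnc_id,
                    gene_id=target.gene_id,
                    r=r,
                    p=p,
                    klass=klass,
                    category=rec.category,
                )
            )
    return out


def summarize_correlation(
    records: Iterable[CorrelationRecord],
    total_expressed: int | None = None,
) -> dict:
    """Per-category counts of lncRNAs with >=1 positive / >=1 negative
    significant partner, plus the overall significantly-correlated fraction.

    Counting is per lncRNA, not per pair: an lncRNA with several significant
    partners of a sign counts once for that sign. The overall fraction is
    (lncRNAs with any significant partner) / ``total_expressed``; when
    ``total_expressed`` is None the number of distinct screened lncRNAs is
    used as the denominator.
    """
    per_cat_pos: dict[str, set[str]] = {}
    per_cat_neg: dict[str, set[str]] = {}
    all_lnc: set[str] = set()
    sig_lnc: set[str] = set()
    for rec in records:
        cat = rec.category.value if rec.category is not None else "unknown"
        all_lnc.add(rec.lncrna_id)
        if rec.klass == "pos":
            per_cat_pos.setdefault(cat, set()).add(rec.lncrna_id)
            sig_lnc.add(rec.lncrna_id)
        elif rec.klass == "neg":
            per_cat_neg.setdefault(cat, set()).add(rec.lncrna_id)
            sig_lnc.add(rec.lncrna_id)
    denom = total_expressed if total_expressed is not None else len(all_lnc)
    categories = sorted(set(per_cat_pos) | set(per_cat_neg))
    return {
        "per_category": {
            cat: {
                "pos": len(per_cat_pos.get(cat, set())),
                "neg": len(per_cat_neg.get(cat, set())),
            }
            for cat in categories
        },
        "n_significant": len(sig_lnc),
        "total_expressed": denom,
        "significant_fraction": (len(sig_lnc) / denom) if denom else 0.0,
    }


def pooled_significant_fraction(
    per_category_counts: dict[str, tuple[int, int]], total_expressed: int
) -> float:
    """Pooled significantly-correlated fraction from per-category
    (positive, negative) lncRNA counts over the expressed total.

    This is the arithmetic used for headline summary fractions: the
    per-category positive and negative counts are summed and divided by the
    total number of expressed lncRNAs.
    """
    if total_expressed <= 0:
        raise ValidationError("total_expressed must be positive")
    n_sig = sum(pos + neg for pos, neg in per_category_counts.values())
    return n_sig / total_expressed
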