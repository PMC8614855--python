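"""GTF reading/writing.

GTF stores 1-based inclusive coordinates; everything downstream of this
module uses 0-based half-open. Attribute parsing is delegated to
gffutils; exon grouping, validation and the coordinate conversion are
done here so that malformed input is reported with its line number.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable

from gffutils.feature import feature_from_line

from .model import GenomicInterval, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)


class GTFParseError(ValueError):
    """A GTF line could not be parsed; message names the line number."""


def read_gtf(path: str | Path, source: str = "novel") -> list[TranscriptModel]:
    """Read exon features of a GTF into :class:`TranscriptModel` objects.

    Parameters
    ----------
    path
        Tab-delimited GTF; only ``exon`` features are used, each must carry
        ``transcript_id`` and ``gene_id`` attributes. A ``gene_biotype`` or
        ``transcript_biotype`` attribute, when present, sets the biotype
        (``protein_coding`` / ``lncRNA`` / anything else -> ``other``).
    source
        Recorded on every transcript: ``"reference"`` or ``"novel"``.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    meta: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{path}:{lineno}: expected 9 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise GTFParseError(
                    f"{path}:{lineno}: non-numeric coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GTFParseError(f"{path}:{lineno}: malformed GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except (KeyError, IndexError):
                raise GTFParseError(
                    f"{path}:{lineno}: exon missing transcript_id/gene_id"
                )
            if feat.end < feat.start:
                raise ValidationError(
                    f"{path}:{lineno}: exon end {feat.end} < start {feat.start}"
                )
            if feat.strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}:{lineno}: exon strand must be + or -, got {feat.strand!r}"
                )
            # 1-based inclusive -> 0-based half-open
            exons[tid].append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
            biotype = "other"
            for key in ("gene_biotype", "transcript_biotype", "biotype"):
                if key in feat.attributes:
                    raw = feat.attributes[key][0]
                    biotype = raw if raw in ("protein_coding", "lncRNA") else "other"
                    break
            meta.setdefault(
                tid,
                {
                    "gene_id": gid,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "biotype": biotype,
                },
            )
            if meta[tid]["chrom"] != feat.seqid or meta[tid]["strand"] != feat.strand:
                raise ValidationError(
                    f"{path}:{lineno}: transcript {tid} has exons on mixed "
                    "chromosomes or strands"
                )

    transcripts = []
    for tid, exon_list in exons.items():
        m = meta[tid]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(sorted(exon_list, key=lambda e: e.start)),
                source=source,
                biotype=m["biotype"],
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF (transcript + exon features, 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gtf produced by lncwhiten\n")
        ordered = sorted(
            transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id)
        )
        for t in ordered:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{t.biotype}";'
            )
            span = t.span
            fh.write(
                f"{t.chrom}\tlncwhiten\ttranscript\t{span.start + 1}\t{span.end}\t"
                f".\t{t.strand}\t.\t{attrs}\n"
            )
            for exon in t.exons:
                fh.write(
                    f"{t.chrom}\tlncwhiten\texon\t{exon.start + 1}\t{exon.end}\t"
                    f".\t{t.strand}\t.\t{attrs}\n"
                )
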