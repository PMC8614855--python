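"""Self-contained synthetic dataset generator with a ground-truth ledger.

Emulates the study design the pipeline targets: a 4-stage x 3-replicate
adipose-tissue time course (D0 infant / classical brown fat, D15, D85, Y2
aged / whitened), a reference annotation with protein-coding and annotated
lncRNA genes, novel transcripts planted to satisfy each positional
category's defining predicate, four-predictor coding calls, NB count and
TPM matrices with planted stage-pattern archetypes, planted lncRNA-gene
correlations, and planted top-10 expression dominance at the classical-BAT
stage. Every planted fact is recorded in a :class:`TruthLedger` so tests
can compare pipeline output against construction truth.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cis import assign_cis_targets
from .index import build_annotation_index
from .model import (
    CodingPotentialCalls,
    DEFAULT_STAGES,
    ExpressionMatrix,
    GenomicInterval,
    LncRNARecord,
    PositionalCategory,
    PREDICTORS,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Eight temporal archetypes (multiplicative stage profiles over
#: D0, D15, D85, Y2) mirroring the recurring whitening-course patterns:
#: early-down, transient mid-course peaks, ramps to puberty, and the
#: aged-stage switch-on.
ARCHETYPES: dict[str, tuple[float, float, float, float]] = {
    "down_at_D15": (8.0, 1.0, 1.0, 1.0),
    "down_gradual": (6.0, 2.0, 1.0, 1.0),
    "peak_D15": (1.0, 8.0, 1.0, 1.0),
    "peak_D15_slow_decay": (1.0, 6.0, 1.0, 2.0),
    "peak_D15_broad": (2.0, 8.0, 2.0, 1.0),
    "up_to_D85_plateau": (1.0, 2.0, 6.0, 6.0),
    "up_to_D85_high": (1.0, 3.0, 8.0, 8.0),
    "flat_then_up_Y2": (1.0, 1.0, 1.0, 8.0),
}

FLAT = (1.0, 1.0, 1.0, 1.0)
#: Dominant classical-BAT lncRNAs: high at D0, decaying with whitening.
DOMINANT_PROFILE = (1.0, 0.25, 0.25, 0.25)

ENRICHED_PATHWAY_ID = "PW_Y2_SWITCH"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study. Defaults are the package's fixed
    desk-scale study conditions (2 chromosomes, 200 protein-coding genes,
    120 planted novel transcripts, 4 x 3 design)."""

    n_chromosomes: int = 2
    n_genes: int = 200
    n_annotated_lncrnas: int = 30
    exon_count_range: tuple[int, int] = (2, 5)
    exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (800, 3000)
    intergenic_gap_range: tuple[int, int] = (2000, 60000)
    planted: Mapping[str, int] = field(
        default_factory=lambda: {
            "lincRNA": 50,
            "antisense": 25,
            "intronic": 20,
            "sense_overlapping": 15,
            "rejected_known": 10,
        }
    )
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_replicates: int = 3
    dispersion: float = 0.01
    n_del_per_archetype: int = 5
    n_pos_pairs: int = 15
    n_neg_pairs: int = 8
    dominance: float = 0.80
    n_dominant: int = 10
    coding_flip_fraction: float = 0.0
    gene_base_mean_range: tuple[float, float] = (100.0, 1000.0)
    lnc_base_mean_range: tuple[float, float] = (50.0, 400.0)
    tpm_total: float = 1.0e6
    n_pathways: int = 10
    pathway_size: int = 25

    def validate(self) -> None:
        if any(v < 0 for v in self.planted.values()):
            raise ValidationError("planted counts must be >= 0")
        if not 0 < self.dominance < 1:
            raise ValidationError("dominance must lie in (0, 1)")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.n_replicates < 1 or len(self.stages) < 2:
            raise ValidationError("need >= 2 stages and >= 1 replicate")
        if not 0 <= self.coding_flip_fraction <= 1:
            raise ValidationError("coding_flip_fraction must lie in [0, 1]")


@dataclass
class TruthLedger:
    """Ground truth for every generated feature."""

    categories: dict[str, PositionalCategory] = field(default_factory=dict)
    partner_gene: dict[str, str | None] = field(default_factory=dict)
    annotated_lncrna_genes: list[str] = field(default_factory=list)
    patterns: dict[str, str] = field(default_factory=dict)
    true_lfc: dict[str, dict[str, float]] = field(default_factory=dict)
    correlations: dict[tuple[str, str], str] = field(default_factory=dict)
    dominant: list[str] = field(default_factory=list)
    dominance_share: dict[str, float] = field(default_factory=dict)
    flipped_coding: set[str] = field(default_factory=set)
    enriched_pathway: str | None = None
    enriched_cluster_pattern: str | None = None

    def planted_category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cat in self.categories.values():
            counts[cat.value] = counts.get(cat.value, 0) + 1
        return counts

    def expected_retained_novel(self) -> set[str]:
        """Novel transcripts that should survive identification: planted in
        one of the four categories and not flipped to coding."""
        keep = {
            PositionalCategory.LINCRNA,
            PositionalCategory.ANTISENSE,
            PositionalCategory.INTRONIC,
            PositionalCategory.SENSE_OVERLAPPING,
        }
        return {
            tid
            for tid, cat in self.categories.items()
            if cat in keep and tid not in self.flipped_coding
        }

    def strong_del_features(self, min_abs_lfc: float = 2.5) -> set[str]:
        """Features planted with at least one comparison |log2FC| >= min_abs_lfc."""
        return {
            fid
            for fid, per in self.true_lfc.items()
            if any(abs(v) >= min_abs_lfc for v in per.values())
        }


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    spec: SyntheticSpec, seed: int
) -> list[TranscriptModel]:
    """Non-overlapping multi-exon genes with alternating strands, protein-
    coding interleaved with annotated lncRNA genes; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    total_genes = spec.n_genes + spec.n_annotated_lncrnas
    transcripts: list[TranscriptModel] = []
    if total_genes == 0:
        return transcripts
    # interleave annotated lncRNA genes roughly evenly
    lnc_every = (
        max(2, total_genes // spec.n_annotated_lncrnas)
        if spec.n_annotated_lncrnas
        else total_genes + 1
    )
    per_chrom = math.ceil(total_genes / spec.n_chromosomes)
    idx = 0
    n_pcg = 0
    n_lnc = 0
    for c in range(spec.n_chromosomes):
        pos = int(rng.integers(*spec.intergenic_gap_range))
        for _ in range(per_chrom):
            if idx >= total_genes:
                break
            is_lnc = (
                n_lnc < spec.n_annotated_lncrnas
                and (idx % lnc_every == lnc_every - 1 or n_pcg >= spec.n_genes)
            )
            strand = "+" if idx % 2 == 0 else "-"
            chrom = f"chr{c + 1}"
            if is_lnc:
                gene_id = f"ALNC{idx:04d}"
                tid = f"{gene_id}.T1"
                biotype = "lncRNA"
                n_exons = 2
            else:
                gene_id = f"PCG{idx:04d}"
                tid = f"{gene_id}.T1"
                biotype = "protein_coding"
                n_exons = int(rng.integers(spec.exon_count_range[0],
                                           spec.exon_count_range[1] + 1))
            exons = []
            cursor = pos
            for e in range(n_exons):
                elen = int(rng.integers(*spec.exon_length_range))
                exons.append(GenomicInterval(chrom, cursor, cursor + elen, strand))
                cursor += elen
                if e < n_exons - 1:
                    cursor += int(rng.integers(*spec.intron_length_range))
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    source="reference",
                    biotype=biotype,
                )
            )
            pos = cursor + int(rng.integers(*spec.intergenic_gap_range))
            idx += 1
            if is_lnc:
                n_lnc += 1
            else:
                n_pcg += 1
    return transcripts


# ---------------------------------------------------------------------------
# novel transcript planting


def _plant_lincrna(
    rng: np.random.Generator,
    gap: tuple[str, int, int],
    tid: str,
    gid: str,
) -> TranscriptModel:
    chrom, lo, hi = gap
    e1 = int(rng.integers(130, 250))
    e2 = int(rng.integers(130, 250))
    intron = int(rng.integers(100, 400))
    span = e1 + intron + e2
    start = lo + 1 + int(rng.integers(0, hi - lo - span - 2))
    strand = "+" if rng.integers(2) else "-"
    exons = (
        GenomicInterval(chrom, start, start + e1, strand),
        GenomicInterval(chrom, start + e1 + intron, start + span, strand),
    )
    return TranscriptModel(tid, gid, chrom, strand, exons, "novel", "other")


def plant_novel_transcripts(
    reference: Sequence[TranscriptModel], spec: SyntheticSpec, seed: int
) -> tuple[list[TranscriptModel], dict[str, PositionalCategory], dict[str, str | None]]:
    """Plant novel transcripts satisfying each category's defining predicate
    under the classifier's precedence rules.

    Returns the transcripts, transcript -> planted category, and
    transcript -> planting partner gene (host for genic categories, the
    nearest flanking protein-coding gene for lincRNAs; None if none).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    pcg = [t for t in reference if t.biotype == "protein_coding"]
    host_order = list(rng.permutation(len(pcg)))
    novel: list[TranscriptModel] = []
    categories: dict[str, PositionalCategory] = {}
    partner: dict[str, str | None] = {}
    counter = 1

    def next_ids() -> tuple[str, str]:
        nonlocal counter
        tid, gid = f"MSTRG.{counter}.1", f"MSTRG.{counter}"
        counter += 1
        return tid, gid

    def take_host(need_intron: int = 0) -> TranscriptModel:
        while host_order:
            t = pcg[host_order.pop()]
            if need_intron == 0:
                return t
            if any(b - a >= need_intron for a, b in t.intron_chain()):
                return t
        raise ValidationError("annotation geometry cannot host more planted transcripts")

    n = dict(spec.planted)

    for _ in range(n.get("antisense", 0)):
        host = take_host()
        e1 = host.exons[0]
        strand = "-" if host.strand == "+" else "+"
        a = e1.start + min(30, len(e1) // 4)
        b = min(e1.end, a + 160)
        intron_start, intron_end = host.intron_chain()[0]
        x = intron_start + 50
        exons = (
            GenomicInterval(host.chrom, a, b, strand),
            GenomicInterval(host.chrom, x, x + 160, strand),
        )
        tid, gid = next_ids()
        novel.append(TranscriptModel(tid, gid, host.chrom, strand, exons, "novel", "other"))
        categories[tid] = PositionalCategory.ANTISENSE
        partner[tid] = host.gene_id

    for _ in range(n.get("intronic", 0)):
        host = take_host(need_intron=700)
        intron = next(
            (a, b) for a, b in host.intron_chain() if b - a >= 700
        )
        strand = "-" if host.strand == "+" else "+"
        start = intron[0] + 50
        exons = (
            GenomicInterval(host.chrom, start, start + 160, strand),
            GenomicInterval(host.chrom, start + 300, start + 460, strand),
        )
        tid, gid = next_ids()
        novel.append(TranscriptModel(tid, gid, host.chrom, strand, exons, "novel", "other"))
        categories[tid] = PositionalCategory.INTRONIC
        partner[tid] = host.gene_id

    for _ in range(n.get("sense_overlapping", 0)):
        host = take_host()
        e1 = host.exons[0]
        intron_start, intron_end = host.intron_chain()[0]
        exon1 = GenomicInterval(
            host.chrom, max(0, e1.start - 80), e1.start + min(60, len(e1) - 1), host.strand
        )
        x = intron_start + 100
        exon2 = GenomicInterval(host.chrom, x, x + 160, host.strand)
        tid, gid = next_ids()
        novel.append(
            TranscriptModel(tid, gid, host.chrom, host.strand, (exon1, exon2), "novel", "other")
        )
        categories[tid] = PositionalCategory.SENSE_OVERLAPPING
        partner[tid] = host.gene_id

    for _ in range(n.get("rejected_known", 0)):
        host = take_host()
        tid, gid = next_ids()
        novel.append(
            TranscriptModel(tid, gid, host.chrom, host.strand, host.exons, "novel", "other")
        )
        categories[tid] = PositionalCategory.REJECTED_KNOWN
        partner[tid] = host.gene_id

    # lincRNAs go into unused intergenic gaps between consecutive gene bodies
    n_linc = n.get("lincRNA", 0)
    if n_linc:
        by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in reference:
            by_chrom.setdefault(t.chrom, []).append(t)
        gaps: list[tuple[str, int, int, str | None, str | None]] = []
        for chrom, ts in by_chrom.items():
            ts = sorted(ts, key=lambda t: t.span.start)
            for left, right in zip(ts, ts[1:]):
                lo, hi = left.span.end, right.span.start
                if hi - lo >= 1200:
                    lgene = left.gene_id if left.biotype == "protein_coding" else None
                    rgene = right.gene_id if right.biotype == "protein_coding" else None
                    gaps.append((chrom, lo, hi, lgene, rgene))
        if len(gaps) < n_linc:
            raise ValidationError(
                f"annotation has only {len(gaps)} usable intergenic gaps for "
                f"{n_linc} lincRNAs"
            )
        chosen = rng.choice(len(gaps), size=n_linc, replace=False)
        for gi in chosen:
            chrom, lo, hi, lgene, rgene = gaps[gi]
            tid, gid = next_ids()
            t = _plant_lincrna(rng, (chrom, lo, hi), tid, gid)
            novel.append(t)
            categories[tid] = PositionalCategory.LINCRNA
            # nearest flanking protein-coding gene
            dl = t.span.start - lo
            dr = hi - t.span.end
            if lgene is not None and (rgene is None or dl <= dr):
                partner[tid] = lgene
            else:
                partner[tid] = rgene
    return novel, categories, partner


# ---------------------------------------------------------------------------
# expression simulation


def _spliced_length(t: TranscriptModel) -> int:
    return t.length


def simulate_counts(
    spec: SyntheticSpec,
    reference: Sequence[TranscriptModel],
    novel: Sequence[TranscriptModel],
    categories: Mapping[str, PositionalCategory],
    partner: Mapping[str, str | None],
    seed: int,
    flipped: frozenset[str] = frozenset(),
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, TruthLedger]:
    """Simulate NB counts and derived TPM for all features.

    Features are the novel transcripts (by transcript id) plus the reference
    genes (by gene id). Planted archetypes set stage-mean profiles; planted
    correlation pairs share (positive) or mirror (negative) the lncRNA's
    stage profile; the classical-BAT stage's lncRNA expression is
    redistributed so the designated dominant lincRNAs carry the configured
    top-10 share. TPM is length-normalized counts scaled to a fixed total
    per sample.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    stages = list(spec.stages)
    ledger = TruthLedger()
    ledger.categories.update(categories)
    ledger.partner_gene.update(partner)
    ledger.flipped_coding = set(flipped)

    feature_ids: list[str] = []
    lengths: dict[str, int] = {}
    for t in novel:
        feature_ids.append(t.transcript_id)
        lengths[t.transcript_id] = _spliced_length(t)
    gene_lengths: dict[str, int] = {}
    gene_biotype: dict[str, str] = {}
    for t in reference:
        gene_lengths.setdefault(t.gene_id, 0)
        gene_lengths[t.gene_id] += _spliced_length(t)
        gene_biotype[t.gene_id] = t.biotype
    for gid, glen in gene_lengths.items():
        feature_ids.append(gid)
        lengths[gid] = glen
    ledger.annotated_lncrna_genes = sorted(
        g for g, b in gene_biotype.items() if b == "lncRNA"
    )

    retained = sorted(
        tid
        for tid, cat in categories.items()
        if cat != PositionalCategory.REJECTED_KNOWN and tid not in flipped
    )
    retained_lincs = [
        t for t in retained if categories[t] == PositionalCategory.LINCRNA
    ]

    # 1. dominant classical-BAT lincRNAs
    n_dom = min(spec.n_dominant, len(retained_lincs))
    dominant = list(rng.choice(retained_lincs, size=n_dom, replace=False)) if n_dom else []
    ledger.dominant = [str(d) for d in dominant]

    # 2. archetype assignment over the remaining retained lncRNAs
    pool = [t for t in retained if t not in set(dominant)]
    pool = list(rng.permutation(pool))
    archetype_of: dict[str, str] = {}
    names = list(ARCHETYPES)
    for i, name in enumerate(names):
        for tid in pool[i * spec.n_del_per_archetype : (i + 1) * spec.n_del_per_archetype]:
            archetype_of[str(tid)] = name

    # 3. correlation pairs among archetyped lncRNAs with a partner gene
    used_genes: set[str] = set()
    pair_candidates = [
        t for t in archetype_of if partner.get(t) not in (None,) and partner[t] not in used_genes
    ]
    pos_pairs: list[tuple[str, str]] = []
    neg_pairs: list[tuple[str, str]] = []
    for tid in pair_candidates:
        gene = partner[tid]
        if gene in used_genes:
            continue
        if len(pos_pairs) < spec.n_pos_pairs:
            pos_pairs.append((tid, gene))
            used_genes.add(gene)
        elif len(neg_pairs) < spec.n_neg_pairs:
            neg_pairs.append((tid, gene))
            used_genes.add(gene)
        else:
            break
    for lnc, gene in pos_pairs:
        ledger.correlations[(lnc, gene)] = "pos"
    for lnc, gene in neg_pairs:
        ledger.correlations[(lnc, gene)] = "neg"

    # 4. stage-profile and base-mean assembly
    profiles: dict[str, tuple[float, ...]] = {}
    base: dict[str, float] = {}
    lo_g, hi_g = spec.gene_base_mean_range
    lo_l, hi_l = spec.lnc_base_mean_range

    def draw_base(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for fid in feature_ids:
        is_gene = fid in gene_lengths
        base[fid] = draw_base(lo_g, hi_g) if is_gene and gene_biotype[fid] == "protein_coding" \
            else draw_base(lo_l, hi_l)
        profiles[fid] = FLAT
    for tid, name in archetype_of.items():
        profiles[tid] = ARCHETYPES[name]
        ledger.patterns[tid] = name
    for lnc, gene in pos_pairs:
        profiles[gene] = profiles[lnc]
    for lnc, gene in neg_pairs:
        p = profiles[lnc]
        m = max(p) + min(p)
        profiles[gene] = tuple(m - v for v in p)
    for tid in dominant:
        profiles[str(tid)] = DOMINANT_PROFILE
        ledger.patterns[str(tid)] = "dominant_classical_bat"

    # 5. dominance calibration at the first (classical-BAT) stage:
    # set dominant D0 means so their expression-rate share among retained
    # lncRNAs equals the configured dominance.
    lnc_denominator = set(retained) | set(ledger.annotated_lncrna_genes)
    rest_rate = sum(
        base[f] * profiles[f][0] / (lengths[f] / 1000.0)
        for f in lnc_denominator
        if f not in set(map(str, dominant))
    )
    if dominant:
        each_rate = rest_rate * spec.dominance / (1 - spec.dominance) / len(dominant)
        for tid in map(str, dominant):
            base[tid] = each_rate * (lengths[tid] / 1000.0)
        ledger.dominance_share[stages[0]] = spec.dominance

    # 6. planted true log2 fold-changes
    comparisons = [
        (a, b) for i, a in enumerate(stages) for b in stages[i + 1 :]
    ]
    for fid, prof in profiles.items():
        if prof == FLAT:
            continue
        ledger.true_lfc[fid] = {
            f"{b}_vs_{a}": math.log2(prof[stages.index(b)] / prof[stages.index(a)])
            for a, b in comparisons
        }
        ledger.patterns.setdefault(fid, "correlation_partner")

    # 7. draw counts
    sample_ids = [f"{s}_r{r + 1}" for s in stages for r in range(spec.n_replicates)]
    sample_stage = {f"{s}_r{r + 1}": s for s in stages for r in range(spec.n_replicates)}
    size_factor = np.exp(rng.normal(0.0, 0.15, size=len(sample_ids)))
    count_mat = np.zeros((len(feature_ids), len(sample_ids)), dtype=np.int64)
    alpha = spec.dispersion
    for i, fid in enumerate(feature_ids):
        prof = profiles[fid]
        for j, sid in enumerate(sample_ids):
            mu = base[fid] * prof[stages.index(sample_stage[sid])] * size_factor[j]
            if mu <= 0:
                continue
            if alpha == 0:
                count_mat[i, j] = rng.poisson(mu)
            else:
                r_param = 1.0 / alpha
                p_param = r_param / (r_param + mu)
                count_mat[i, j] = rng.negative_binomial(r_param, p_param)

    counts_df = pd.DataFrame(count_mat, index=feature_ids, columns=sample_ids)
    rate = counts_df.div(pd.Series(lengths) / 1000.0, axis=0)
    tpm_df = rate.div(rate.sum(axis=0), axis=1) * spec.tpm_total

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "stage": [sample_stage[s] for s in sample_ids],
            "replicate": [int(s.split("_r")[1]) for s in sample_ids],
        }
    ).set_index("sample_id")

    counts = ExpressionMatrix(counts_df, "counts", metadata)
    tpm = ExpressionMatrix(tpm_df, "TPM", metadata)
    return counts, tpm, metadata.reset_index(), ledger


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class Bundle:
    """One-call synthetic dataset: everything the pipeline consumes."""

    spec: SyntheticSpec
    reference: list[TranscriptModel]
    novel: list[TranscriptModel]
    calls: CodingPotentialCalls
    counts: ExpressionMatrix
    tpm: ExpressionMatrix
    metadata: pd.DataFrame
    pathways: dict[str, set[str]]
    ledger: TruthLedger

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle in standard formats (GTF, TSV, GMT) plus ledger TSVs."""
        from .gtf import write_gtf
        from .tables import (
            write_coding_calls,
            write_expression_matrix,
            write_gmt,
            write_metadata,
        )

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["reference_gtf"] = out / "reference.gtf"
        write_gtf(self.reference, paths["reference_gtf"])
        paths["novel_gtf"] = out / "novel.gtf"
        write_gtf(self.novel, paths["novel_gtf"])
        paths["counts"] = out / "counts.tsv"
        write_expression_matrix(self.counts, paths["counts"])
        paths["tpm"] = out / "tpm.tsv"
        write_expression_matrix(self.tpm, paths["tpm"])
        paths["metadata"] = out / "metadata.tsv"
        write_metadata(self.metadata.set_index("sample_id"), paths["metadata"])
        for pred, p in write_coding_calls(self.calls, out).items():
            paths[f"calls_{pred}"] = p
        paths["gmt"] = out / "pathways.gmt"
        write_gmt(self.pathways, paths["gmt"])
        # ledger tables
        led = pd.DataFrame(
            {
                "transcript_id": list(self.ledger.categories),
                "category": [c.value for c in self.ledger.categories.values()],
                "partner_gene": [
                    self.ledger.partner_gene.get(t) or ""
                    for t in self.ledger.categories
                ],
            }
        )
        paths["ledger_categories"] = out / "ledger_categories.tsv"
        led.to_csv(paths["ledger_categories"], sep="\t", index=False)
        pat = pd.DataFrame(
            {
                "feature_id": list(self.ledger.patterns),
                "pattern": list(self.ledger.patterns.values()),
            }
        )
        paths["ledger_patterns"] = out / "ledger_patterns.tsv"
        pat.to_csv(paths["ledger_patterns"], sep="\t", index=False)
        corr = pd.DataFrame(
            [(l, g, s) for (l, g), s in self.ledger.correlations.items()],
            columns=["lncrna_id", "gene_id", "sign"],
        )
        paths["ledger_correlations"] = out / "ledger_correlations.tsv"
        corr.to_csv(paths["ledger_correlations"], sep="\t", index=False)
        return paths


def generate_dataset(spec: SyntheticSpec, seed: int) -> Bundle:
    """Generate the full synthetic bundle; pure function of (spec, seed)."""
    spec.validate()
    root = np.random.SeedSequence(seed)
    s_ann, s_plant, s_counts, s_misc = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )
    rng = np.random.default_rng(s_misc)

    reference = generate_annotation(spec, s_ann)
    novel, categories, partner = plant_novel_transcripts(reference, spec, s_plant)

    # coding calls: all planted transcripts noncoding by all four predictors,
    # with a configurable fraction flipped to coding on one random predictor
    tids = sorted(categories)
    n_flip = int(round(spec.coding_flip_fraction * len(tids)))
    flipped = (
        set(map(str, rng.choice(tids, size=n_flip, replace=False))) if n_flip else set()
    )
    calls_map: dict[str, dict[str, str]] = {}
    for tid in tids:
        calls_map[tid] = {p: "noncoding" for p in PREDICTORS}
        if tid in flipped:
            pred = PREDICTORS[int(rng.integers(len(PREDICTORS)))]
            calls_map[tid][pred] = "coding"
    calls = CodingPotentialCalls(calls_map)

    counts, tpm, metadata, ledger = simulate_counts(
        spec, reference, novel, categories, partner, s_counts, frozenset(flipped)
    )

    # pathway map over protein-coding genes, with one pathway packed with the
    # cis targets of the aged-stage switch-on archetype so that cluster's
    # query is enriched by construction
    pcg_genes = sorted(
        {t.gene_id for t in reference if t.biotype == "protein_coding"}
    )
    pathways: dict[str, set[str]] = {}
    for i in range(spec.n_pathways):
        members = rng.choice(pcg_genes, size=min(spec.pathway_size, len(pcg_genes)),
                             replace=False)
        pathways[f"PW{i + 1:02d}"] = set(map(str, members))
    index = build_annotation_index(reference)
    novel_by_id = {t.transcript_id: t for t in novel}
    up_targets: set[str] = set()
    for tid, name in ledger.patterns.items():
        if name != "flat_then_up_Y2" or tid not in novel_by_id:
            continue
        rec = LncRNARecord(
            transcript=novel_by_id[tid],
            category=categories[tid],
            origin="novel",
        )
        assign_cis_targets(rec, index)
        up_targets.update(t.gene_id for t in rec.cis_targets)
    if up_targets:
        fill = [g for g in pcg_genes if g not in up_targets]
        extra = rng.choice(fill, size=max(0, spec.pathway_size - len(up_targets)),
                           replace=False)
        pathways[ENRICHED_PATHWAY_ID] = up_targets | set(map(str, extra))
        ledger.enriched_pathway = ENRICHED_PATHWAY_ID
        ledger.enriched_cluster_pattern = "flat_then_up_Y2"

    return Bundle(
        spec=spec,
        reference=reference,
        novel=novel,
        calls=calls,
        counts=counts,
        tpm=tpm,
        metadata=metadata,
        pathways=pathways,
        ledger=ledger,
    )
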