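"""End-to-end orchestration: identify -> targets -> correlate -> complexity
-> differential expression -> cluster -> enrich -> rank.

Every stage writes its TSV outputs under the configured output directory
and contributes counts to a JSON run report; the report always satisfies
the partition identities (category counts sum to totals, DEL-union
breakdown sums to the union size).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cis import (
    ALPHA,
    CIS_WINDOW,
    assign_cis_targets,
    correlation_screen,
    summarize_correlation,
)
from .complexity import complexity_by_group
from .diffexpr import (
    FDR_THRESHOLD,
    LFC_THRESHOLD,
    del_union,
    run_all_comparisons,
)
from .gtf import read_gtf
from .identify import MIN_EXONS, MIN_LENGTH, MIN_TPM, identify_lncrnas
from .index import build_annotation_index
from .model import (
    CorrelationRecord,
    DEResult,
    ExpressionMatrix,
    LncRNARecord,
    PositionalCategory,
)
from .patterns import (
    ENRICH_ALPHA,
    N_CLUSTERS,
    hypergeom_enrich,
    kmeans_cluster,
    stage_means,
    zscore_rows,
)
from .tables import read_coding_calls, read_expression_matrix, read_gmt

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class PipelineConfig:
    """Paths to all inputs plus every tunable threshold."""

    reference_gtf: str
    novel_gtf: str
    counts: str
    tpm: str
    metadata: str
    calls: dict[str, str]  # predictor -> path
    gmt: str | None = None
    out_dir: str = "lncwhiten_out"
    min_length: int = MIN_LENGTH
    min_exons: int = MIN_EXONS
    min_tpm: float = MIN_TPM
    window: int = CIS_WINDOW
    alpha: float = ALPHA
    log2p1: bool = False
    lfc: float = LFC_THRESHOLD
    fdr: float = FDR_THRESHOLD
    k: int = N_CLUSTERS
    n_init: int = 25
    complexity_k: int = 10
    top_n: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def input_paths(self) -> list[str]:
        paths = [self.reference_gtf, self.novel_gtf, self.counts, self.tpm, self.metadata]
        paths.extend(self.calls.values())
        if self.gmt:
            paths.append(self.gmt)
        return paths


def expression_feature_id(record: LncRNARecord, expr: ExpressionMatrix) -> str | None:
    """The id under which a lncRNA appears in an expression matrix: the
    transcript id, else its gene id, else None."""
    if record.transcript_id in expr:
        return record.transcript_id
    if record.transcript.gene_id in expr:
        return record.transcript.gene_id
    return None


def rank_candidates(
    records: Sequence[LncRNARecord],
    union: set[str],
    correlations: Iterable[CorrelationRecord],
    stage_mean_tpm: pd.DataFrame,
    top_n: int = 10,
) -> pd.DataFrame:
    """Candidate ranking: DELs with >= 1 significant cis correlation,
    ordered by maximum stage-mean TPM (descending; ties by id).

    The filter-then-sort rule is this package's fixed, reproducible reading
    of "abundance + differential expression + correlation" candidate
    selection.
    """
    significant = {r.lncrna_id for r in correlations if r.klass != "ns"}
    rows = []
    for rec in records:
        fid = rec.transcript_id if rec.transcript_id in stage_mean_tpm.index \
            else rec.transcript.gene_id
        if fid not in union or fid not in significant:
            continue
        if fid not in stage_mean_tpm.index:
            continue
        row = stage_mean_tpm.loc[fid]
        rows.append(
            {
                "lncrna_id": fid,
                "category": rec.category.value,
                "origin": rec.origin,
                "max_stage_tpm": float(row.max()),
                "peak_stage": str(row.idxmax()),
            }
        )
    df = pd.DataFrame(rows, columns=["lncrna_id", "category", "origin",
                                     "max_stage_tpm", "peak_stage"])
    df = df.sort_values(
        ["max_stage_tpm", "lncrna_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df.head(top_n)


def _records_table(records: Sequence[LncRNARecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        t = rec.transcript
        targets = ";".join(
            f"{c.gene_id}:{c.relationship}:{c.distance}" for c in rec.cis_targets
        )
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "start": t.span.start,
                "end": t.span.end,
                "strand": t.strand,
                "n_exons": t.n_exons,
                "length": t.length,
                "category": rec.category.value,
                "origin": rec.origin,
                "cis_targets": targets,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run report (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input path(s): {missing}")

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "warnings": [],
    }

    class _ReportHandler(logging.Handler):
        def emit(self, record: logging.LogRecord) -> None:
            if record.levelno >= logging.WARNING:
                report["warnings"].append(record.getMessage())

    handler = _ReportHandler()
    logging.getLogger("lncwhiten").addHandler(handler)

    stage = "load_inputs"
    try:
        reference = read_gtf(config.reference_gtf, source="reference")
        novel = read_gtf(config.novel_gtf, source="novel")
        tpm = read_expression_matrix(config.tpm, "TPM", config.metadata)
        counts = read_expression_matrix(config.counts, "counts", config.metadata)
        calls = read_coding_calls(config.calls)

        stage = "identify"
        records, summary = identify_lncrnas(
            novel, reference, tpm, calls,
            config.min_length, config.min_exons, config.min_tpm,
        )
        report["identification"] = summary

        stage = "targets"
        index = build_annotation_index(reference)
        for rec in records:
            assign_cis_targets(rec, index, config.window)
        _records_table(records).to_csv(out_dir / "lncrnas.tsv", sep="\t", index=False)

        stage = "correlate"
        corr = correlation_screen(records, tpm, config.alpha, config.log2p1)
        pd.DataFrame(
            [
                {
                    "lncrna_id": r.lncrna_id,
                    "gene_id": r.gene_id,
                    "r": r.r,
                    "p": r.p,
                    "class": r.klass,
                    "category": r.category.value if r.category else "",
                }
                for r in corr
            ]
        ).to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
        report["correlation"] = summarize_correlation(
            corr, total_expressed=summary["grand_total"]
        )

        stage = "complexity"
        lnc_ids = [
            fid
            for fid in (expression_feature_id(r, tpm) for r in records)
            if fid is not None
        ]
        curves, complexity_summary = complexity_by_group(
            tpm, feature_ids=lnc_ids, by="stage", k=config.complexity_k
        )
        complexity_summary.to_csv(out_dir / "complexity.tsv", sep="\t", index=False)
        pd.concat(
            [
                pd.DataFrame(
                    {
                        "group": g,
                        "rank": range(1, len(c.fractions) + 1),
                        "fraction": c.fractions,
                    }
                )
                for g, c in curves.items()
            ]
        ).to_csv(out_dir / "complexity_curves.tsv", sep="\t", index=False)
        report["complexity"] = {
            row["group"]: row[f"top{config.complexity_k}_fraction"]
            for _, row in complexity_summary.iterrows()
        }

        stage = "de"
        categories: dict[str, PositionalCategory] = {}
        for rec in records:
            fid = expression_feature_id(rec, counts)
            if fid is not None:
                categories[fid] = rec.category
        per_comp = run_all_comparisons(
            counts, config.lfc, config.fdr, feature_ids=list(categories)
        )
        de_rows = [
            {
                "feature_id": r.feature_id,
                "comparison": r.comparison,
                "log2fc": r.log2fc,
                "p": r.p,
                "fdr": r.fdr,
                "status": r.status,
            }
            for results in per_comp.values()
            for r in results
        ]
        pd.DataFrame(de_rows).to_csv(out_dir / "de_results.tsv", sep="\t", index=False)
        union, breakdown = del_union(per_comp, categories)
        report["de"] = {
            "per_comparison": {
                comp: {
                    "up": sum(1 for r in results if r.status == "up"),
                    "down": sum(1 for r in results if r.status == "down"),
                }
                for comp, results in per_comp.items()
            },
            "union_breakdown": breakdown,
        }

        stage = "cluster"
        cluster_labels: pd.Series | None = None
        sm = stage_means(tpm, feature_ids=list(categories))
        if len(union) >= config.k:
            z = zscore_rows(sm.loc[sorted(union & set(sm.index))])
            assignment = kmeans_cluster(
                z, k=config.k, seed=config.seed, n_init=config.n_init
            )
            cluster_labels = assignment.labels
            assignment.labels.rename("cluster").to_frame().to_csv(
                out_dir / "clusters.tsv", sep="\t", index_label="feature_id"
            )
            report["clusters"] = {
                "k": assignment.k,
                "sizes": assignment.sizes(),
                "inertia": assignment.inertia,
            }
        else:
            logger.warning(
                "only %d DELs for k=%d clusters; clustering skipped",
                len(union), config.k,
            )
            report["clusters"] = {"k": 0, "sizes": {}, "skipped": True}

        stage = "enrich"
        enrichment_rows = []
        if config.gmt and cluster_labels is not None:
            pathways = read_gmt(config.gmt)
            universe = set().union(*pathways.values())
            target_map: dict[str, set[str]] = {}
            for rec in records:
                fid = expression_feature_id(rec, tpm)
                if fid is not None:
                    target_map[fid] = {c.gene_id for c in rec.cis_targets}
            for label in sorted(cluster_labels.unique()):
                members = cluster_labels.index[cluster_labels == label]
                query = set().union(*(target_map.get(m, set()) for m in members))
                query &= universe
                if not query:
                    continue
                for res in hypergeom_enrich(query, pathways, universe, ENRICH_ALPHA):
                    enrichment_rows.append(
                        {
                            "cluster": int(label),
                            "pathway_id": res.pathway_id,
                            "pathway_size": res.pathway_size,
                            "overlap": res.overlap,
                            "p": res.p,
                            "significant": res.significant,
                        }
                    )
            pd.DataFrame(enrichment_rows).to_csv(
                out_dir / "enrichment.tsv", sep="\t", index=False
            )
        report["enrichment"] = {
            "n_tests": len(enrichment_rows),
            "n_significant": sum(1 for r in enrichment_rows if r["significant"]),
        }

        stage = "rank"
        ranked = rank_candidates(records, union, corr, sm, config.top_n)
        ranked.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
        report["candidates"] = list(ranked["lncrna_id"])

    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("lncwhiten").removeHandler(handler)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
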