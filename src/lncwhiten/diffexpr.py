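"""Simplified negative-binomial differential expression for the stage
time course.

The test is a deliberately transparent NB Wald test: median-of-ratios
normalization, pooled method-of-moments dispersion, delta-method standard
error on the log2 ratio of pseudocounted normalized group means, and a
Student-t reference with n_A + n_B - 2 degrees of freedom for the Wald
statistic (a normal reference is badly anticonservative at 3 replicates
per group; the t reference restores near-nominal type-I error); p-values
are BH-adjusted per comparison. A lncRNA is a DEL (differentially expressed lncRNA) when
|log2FC| > 1.5 and FDR < 0.01 (strict inequalities). This is not a DESeq2
reimplementation — no shrinkage, Cook's filtering or independent
filtering — and its guarantees are calibration properties (type-I error,
planted-effect recovery), not numeric agreement with DESeq2.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import DEResult, ExpressionMatrix, PositionalCategory, ValidationError

logger = logging.getLogger(__name__)

LFC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.01
PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each feature with a positive geometric mean across samples, the
    ratio count_ij / geomean_i is formed; factor_j is the median ratio over
    those features.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    finite = np.isfinite(log_arr).all(axis=1)
    if not finite.any():
        raise ValidationError(
            "no feature has nonzero counts in all samples; median-of-ratios "
            "undefined (consider a pseudo-reference fallback)"
        )
    log_geomean = log_arr[finite].mean(axis=1)
    ratios = np.exp(log_arr[finite] - log_geomean[:, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def estimate_dispersion(
    normalized: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.Series:
    """Pooled method-of-moments NB dispersion per feature.

    Within each group the sample mean and variance are computed; the two
    groups' moments are averaged and alpha = max(0, (s2 - mu) / mu^2)
    (0 when under-dispersed or unexpressed). Requires >= 2 replicates per
    group.
    """
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValidationError(f"group {name} needs >= 2 replicates")
    a = normalized[list(group_a)].to_numpy(dtype=float)
    b = normalized[list(group_b)].to_numpy(dtype=float)
    mu = (a.mean(axis=1) + b.mean(axis=1)) / 2
    s2 = (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    return pd.Series(np.maximum(alpha, 0.0), index=normalized.index)


def nb_wald(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudo: float = PSEUDOCOUNT,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald test of group B over group A for every feature.

    Counts are normalized by :func:`size_factors` computed on the samples of
    the two groups. log2FC = log2((m_B + pseudo) / (m_A + pseudo)) on the
    normalized group means; the SE comes from the delta method with
    Var(m_g) = (m_g + alpha m_g^2) / n_g; two-sided p from a t reference
    with n_A + n_B - 2 df. Features with both group means zero get log2fc 0
    and p 1.
    """
    cols = list(group_a) + list(group_b)
    if len(set(cols)) != len(cols):
        raise ValidationError("groups must be disjoint")
    sub = counts[cols]
    sf = size_factors(sub)
    normalized = sub / sf
    if dispersion is None:
        dispersion = estimate_dispersion(normalized, group_a, group_b)
    alpha = dispersion.to_numpy(dtype=float)

    a = normalized[list(group_a)].to_numpy(dtype=float)
    b = normalized[list(group_b)].to_numpy(dtype=float)
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    n_a, n_b = a.shape[1], b.shape[1]

    log2fc = np.log2((m_b + pseudo) / (m_a + pseudo))
    var_a = (m_a + alpha * m_a**2) / n_a
    var_b = (m_b + alpha * m_b**2) / n_b
    se2 = (1 / np.log(2)) ** 2 * (
        var_a / (m_a + pseudo) ** 2 + var_b / (m_b + pseudo) ** 2
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    df_t = n_a + n_b - 2
    p = 2 * stats.t.sf(np.abs(z), df_t)
    both_zero = (m_a == 0) & (m_b == 0)
    log2fc = np.where(both_zero, 0.0, log2fc)
    p = np.where(both_zero | (se == 0), 1.0, p)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": np.clip(p, 0.0, 1.0), "dispersion": alpha},
        index=counts.index,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_status(log2fc: float, fdr: float, lfc: float = LFC_THRESHOLD,
                fdr_threshold: float = FDR_THRESHOLD) -> str:
    if fdr < fdr_threshold and log2fc > lfc:
        return "up"
    if fdr < fdr_threshold and log2fc < -lfc:
        return "down"
    return "ns"


def de_test(
    counts: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    lfc: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    feature_ids: Sequence[str] | None = None,
) -> list[DEResult]:
    """Full pairwise test of stage_b vs stage_a with BH-FDR and DEL calling."""
    group_a = counts.samples_for_stage(stage_a)
    group_b = counts.samples_for_stage(stage_b)
    if not group_a or not group_b:
        raise ValidationError(f"no samples for stage {stage_a!r} or {stage_b!r}")
    values = counts.values
    if feature_ids is not None:
        values = values.loc[[f for f in feature_ids if f in values.index]]
    table = nb_wald(values, group_a, group_b)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    comparison = f"{stage_b}_vs_{stage_a}"
    return [
        DEResult(
            feature_id=fid,
            comparison=comparison,
            log2fc=float(row.log2fc),
            p=float(row.p),
            fdr=float(row.fdr),
            status=call_status(row.log2fc, row.fdr, lfc, fdr_threshold),
        )
        for fid, row in table.iterrows()
    ]


def call_dels(
    results: Iterable[DEResult],
    lfc: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> list[DEResult]:
    """Re-call DEL status at the given thresholds (strict inequalities)."""
    return [
        DEResult(
            feature_id=r.feature_id,
            comparison=r.comparison,
            log2fc=r.log2fc,
            p=r.p,
            fdr=r.fdr,
            status=call_status(r.log2fc, r.fdr, lfc, fdr_threshold),
        )
        for r in results
    ]


def pairwise_comparisons(stages: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered stage pairs (later vs earlier), e.g. six for four stages."""
    return [(a, b) for a, b in itertools.combinations(stages, 2)]


def run_all_comparisons(
    counts: ExpressionMatrix,
    lfc: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    feature_ids: Sequence[str] | None = None,
) -> dict[str, list[DEResult]]:
    """Run every pairwise stage comparison; keys are "B_vs_A" labels."""
    out = {}
    for stage_a, stage_b in pairwise_comparisons(counts.stages):
        results = de_test(counts, stage_a, stage_b, lfc, fdr_threshold, feature_ids)
        out[f"{stage_b}_vs_{stage_a}"] = results
    return out


def del_union(
    per_comparison: Mapping[str, Iterable[DEResult]],
    categories: Mapping[str, PositionalCategory] | None = None,
) -> tuple[set[str], dict[str, int]]:
    """Union of DEL feature ids over all comparisons with per-category
    breakdown; breakdown counts always sum to the union size."""
    union: set[str] = set()
    for results in per_comparison.values():
        union.update(r.feature_id for r in results if r.status != "ns")
    breakdown: dict[str, int] = {}
    if categories is not None:
        for fid in union:
            cat = categories.get(fid)
            key = cat.value if cat is not None else "unknown"
            breakdown[key] = breakdown.get(key, 0) + 1
    breakdown["union_total"] = len(union)
    return union, breakdown
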