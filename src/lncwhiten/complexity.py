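"""Transcriptional-complexity profiling.

Complexity is summarized by the cumulative share of total lncRNA
expression contributed by the k most-expressed lncRNAs: a tissue where the
top 10 lncRNAs carry ~80% of all lncRNA expression (classical brown fat)
is "low complexity"; a flatter curve is "high complexity".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class ComplexityCurve:
    """Cumulative expression-share curve for one sample or stage."""

    group: str
    fractions: np.ndarray  # fractions[i] = share of the (i+1) top features

    def at_rank(self, k: int) -> float:
        if k < 1:
            raise ValidationError("rank must be >= 1")
        return float(self.fractions[min(k, len(self.fractions)) - 1])


def complexity_curve(values, group: str = "") -> ComplexityCurve:
    """Sort descending, cumulate, normalize by the total.

    The curve is invariant to permutation and to positive rescaling of the
    input; an all-zero vector has no defined curve and raises.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("expression vector must be non-empty 1-D")
    if (arr < 0).any():
        raise ValidationError("expression values must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValidationError("all-zero expression vector: curve undefined")
    fractions = np.cumsum(np.sort(arr)[::-1]) / total
    return ComplexityCurve(group=group, fractions=fractions)


def top_k_fraction(values, k: int = 10) -> float:
    """Share of total expression carried by the k most-expressed features
    (k capped at the number of features)."""
    return complexity_curve(values).at_rank(k)


def complexity_by_group(
    expr: ExpressionMatrix,
    feature_ids=None,
    by: str = "stage",
    k: int = 10,
) -> tuple[dict[str, ComplexityCurve], pd.DataFrame]:
    """Complexity curves per stage (replicate-mean TPM) or per sample.

    Returns the curves and a tidy summary frame (group, top-k share).
    """
    if by not in ("stage", "sample"):
        raise ValidationError("by must be 'stage' or 'sample'")
    values = expr.values
    if feature_ids is not None:
        values = values.loc[[f for f in feature_ids if f in values.index]]
    if by == "stage":
        groups = {
            stage: values[expr.samples_for_stage(stage)].mean(axis=1).to_numpy()
            for stage in expr.stages
        }
    else:
        groups = {s: values[s].to_numpy(dtype=float) for s in expr.sample_ids}
    curves = {g: complexity_curve(v, group=g) for g, v in groups.items()}
    summary = pd.DataFrame(
        {
            "group": list(curves),
            f"top{k}_fraction": [c.at_rank(k) for c in curves.values()],
        }
    )
    return curves, summary
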