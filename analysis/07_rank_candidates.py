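"""Rank candidate regulator lncRNAs.

Filters the identified lncRNAs to DELs with at least one significant cis
correlation and ranks them by maximum stage-mean TPM — abundance,
differential expression and cis association combined into a fixed,
reproducible selection rule. Writes results/candidates.tsv.
"""

from pathlib import Path

import pandas as pd

from lncwhiten import (
    identify_lncrnas,
    read_coding_calls,
    read_expression_matrix,
    read_gtf,
)
from lncwhiten.model import CorrelationRecord, PositionalCategory
from lncwhiten.patterns import stage_means
from lncwhiten.pipeline import rank_candidates

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def main() -> None:
    novel = read_gtf(DATA / "novel.gtf", source="novel")
    reference = read_gtf(DATA / "reference.gtf", source="reference")
    tpm = read_expression_matrix(DATA / "tpm.tsv", "TPM", DATA / "metadata.tsv")
    calls = read_coding_calls(
        {p: DATA / f"calls_{p.lower()}.tsv" for p in ("CPC2", "CPAT", "CNCI", "Pfam")}
    )
    records, _ = identify_lncrnas(novel, reference, tpm, calls)

    union = set(pd.read_csv(ROOT / "del_union.tsv", sep="\t")["feature_id"])
    corr = [
        CorrelationRecord(
            row["lncrna_id"], row["gene_id"], row["r"], row["p"], row["class"],
            PositionalCategory(row["category"]) if row["category"] else None,
        )
        for _, row in pd.read_csv(ROOT / "correlations.tsv", sep="\t").iterrows()
    ]
    sm = stage_means(tpm)
    ranked = rank_candidates(records, union, corr, sm, top_n=10)
    ranked.to_csv(ROOT / "candidates.tsv", sep="\t", index=False)
    print("top candidate lncRNAs (DEL + significant cis correlation, "
          "by peak stage-mean TPM):")
    print(ranked.to_string(index=False))


if __name__ == "__main__":
    main()
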