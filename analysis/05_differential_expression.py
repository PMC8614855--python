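"""Call differentially expressed lncRNAs (DELs) across the time course.

Runs the NB Wald test on raw counts for all six pairwise stage
comparisons, BH-adjusts per comparison, and calls DELs at |log2FC| > 1.5
and FDR < 0.01. Reports per-comparison up/down counts and the DEL union
with its per-category breakdown. Writes results/de_results.tsv and
results/del_union.tsv.
"""

from pathlib import Path

import pandas as pd

from lncwhiten import (
    del_union,
    identify_lncrnas,
    read_coding_calls,
    read_expression_matrix,
    read_gtf,
    run_all_comparisons,
)
from lncwhiten.pipeline import expression_feature_id

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def main() -> None:
    novel = read_gtf(DATA / "novel.gtf", source="novel")
    reference = read_gtf(DATA / "reference.gtf", source="reference")
    tpm = read_expression_matrix(DATA / "tpm.tsv", "TPM", DATA / "metadata.tsv")
    counts = read_expression_matrix(DATA / "counts.tsv", "counts",
                                    DATA / "metadata.tsv")
    calls = read_coding_calls(
        {p: DATA / f"calls_{p.lower()}.tsv" for p in ("CPC2", "CPAT", "CNCI", "Pfam")}
    )
    records, _ = identify_lncrnas(novel, reference, tpm, calls)
    categories = {}
    for rec in records:
        fid = expression_feature_id(rec, counts)
        if fid is not None:
            categories[fid] = rec.category

    per_comp = run_all_comparisons(counts, feature_ids=list(categories))
    rows = [
        {"feature_id": r.feature_id, "comparison": r.comparison, "log2fc": r.log2fc,
         "p": r.p, "fdr": r.fdr, "status": r.status}
        for results in per_comp.values() for r in results
    ]
    pd.DataFrame(rows).to_csv(ROOT / "de_results.tsv", sep="\t", index=False)

    print("per-comparison DEL counts (up / down):")
    for comp, results in per_comp.items():
        up = sum(1 for r in results if r.status == "up")
        down = sum(1 for r in results if r.status == "down")
        print(f"  {comp}: {up} up, {down} down")
    union, breakdown = del_union(per_comp, categories)
    pd.Series(sorted(union), name="feature_id").to_frame().to_csv(
        ROOT / "del_union.tsv", sep="\t", index=False
    )
    print(f"DEL union across all comparisons: {breakdown['union_total']}")
    print("breakdown: " + ", ".join(
        f"{k}={v}" for k, v in breakdown.items() if k != "union_total"
    ))
    assert sum(v for k, v in breakdown.items() if k != "union_total") \
        == breakdown["union_total"]


if __name__ == "__main__":
    main()
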