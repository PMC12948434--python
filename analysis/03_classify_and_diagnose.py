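"""Classify variants and assign per-individual diagnosis categories.

Combines ACMG evidence into 5-tier classes, resolves (presumed)
compound-heterozygous genotypes, assigns one category per individual,
and applies the strong-risk reclassification.  Writes the category
table, the per-gene bar view, and the solve rates.
"""

import argparse
from pathlib import Path

import pandas as pd

from ksdcohort.diagnosis import (
    cohort_counts,
    gene_bar_counts,
    solve_rate,
    write_results_jsonl,
)
from ksdcohort.pipeline import read_bundle, run_diagnosis_pipeline
from ksdcohort.stats import chi_square_2x2

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path,
                    default=ROOT / "scratch" / "bundle")
    args = ap.parse_args()

    results, _ = run_diagnosis_pipeline(read_bundle(args.bundle))
    results_dir = ROOT / "results"
    results_dir.mkdir(exist_ok=True)

    tables = []
    for group in ("KSF", "NKSF"):
        t = cohort_counts(results, group)
        t.insert(0, "group", group)
        tables.append(t)
        print(f"\n{group} category partition:")
        print(t.to_string(index=False))
    pd.concat(tables).to_csv(results_dir / "03_category_counts.tsv",
                             sep="\t", index=False)
    gene_bar_counts(results, "KSF").to_csv(
        results_dir / "03_gene_bar_counts_ksf.tsv", sep="\t", index=False
    )
    # full per-individual records are large and regenerable -> scratch
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    write_results_jsonl(results, scratch / "diagnoses.jsonl")

    pre = solve_rate(results, "pre_reclassification")
    post = solve_rate(results, "post_reclassification")
    print(f"\nsolve rate: {pre}% before reclassification, "
          f"{post}% after demoting monoallelic genotypes without a "
          f"biochemical phenotype")

    # carrier enrichment: LP/P-bearing individuals per group
    n_lp_ksf = sum(
        1 for r in results
        if r.group == "KSF" and (r.monogenic_ksd or r.category.value ==
                                 "carrier_AR")
    )
    n_lp_nksf = sum(
        1 for r in results
        if r.group == "NKSF" and (r.monogenic_ksd or r.category.value ==
                                  "carrier_AR")
    )
    n_ksf = sum(r.group == "KSF" for r in results)
    n_nksf = sum(r.group == "NKSF" for r in results)
    chi = chi_square_2x2(n_lp_ksf, n_ksf - n_lp_ksf,
                         n_lp_nksf, n_nksf - n_lp_nksf)
    print(f"LP/P carriers: {n_lp_ksf}/{n_ksf} KSF vs {n_lp_nksf}/{n_nksf} "
          f"NKSF (chi-square {chi.statistic:.3f}, p = {chi.p_value:.4f})")


if __name__ == "__main__":
    main()
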