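"""Genotype–phenotype correlation on derived biochemistry.

Computes TmP/GFR, urinary ratios and the simplified supersaturation
indices at the baseline biochemistry visit (V2 for stone formers, the
single enrollment visit for controls), then compares genotype groups
with nonparametric tests: phosphate handling for monoallelic SLC34A3
carriers, urinary cystine for the cystinuria genotypes.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ksdcohort.biochem import cystinuria_profile
from ksdcohort.pipeline import derive_biochem_frame, read_bundle, select_visit
from ksdcohort.stats import kruskal_wallis, mann_whitney, shapiro_gate

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path,
                    default=ROOT / "scratch" / "bundle")
    args = ap.parse_args()

    bundle = read_bundle(args.bundle)
    manifest = json.loads((args.bundle / "manifest.json").read_text())
    truth = pd.DataFrame(manifest["ground_truth"]).set_index("individual_id")

    derived = select_visit(derive_biochem_frame(bundle.biochem))
    derived = derived.join(truth[["effect_class"]], on="individual_id")
    controls = derived[derived.effect_class == "null"]

    rows = []
    comparisons = [
        ("slc34a3_mono", "tmp_gfr"),
        ("slc34a3_mono", "ca_crea_ratio"),
        ("slc34a3_mono", "ss_brushite"),
        ("cystinuria_biallelic_slc3a1", "cystine_crea_ratio"),
        ("cystinuria_biallelic_slc7a9", "cystine_crea_ratio"),
        ("slc7a9_mono", "cystine_crea_ratio"),
    ]
    for eclass, index in comparisons:
        carriers = derived[derived.effect_class == eclass]
        r = mann_whitney(carriers[index], controls[index])
        rows.append(
            {
                "genotype_group": eclass,
                "index": index,
                "n_carriers": len(carriers),
                "carrier_median": carriers[index].median(),
                "control_median": controls[index].median(),
                "mann_whitney_p": r.p_value,
            }
        )
        print(f"{eclass:>30} {index:<20} median {rows[-1]['carrier_median']:8.3f} "
              f"vs control {rows[-1]['control_median']:8.3f}  p={r.p_value:.2e}")

    # k-group comparison across all cystine genotype classes
    cystine_groups = [
        derived[derived.effect_class == ec]["cystine_crea_ratio"]
        for ec in ("null", "slc7a9_mono", "cystinuria_biallelic_slc7a9",
                   "cystinuria_biallelic_slc3a1")
    ]
    kw = kruskal_wallis(cystine_groups)
    print(f"\nKruskal-Wallis across cystine genotype classes: "
          f"H={kw.statistic:.1f}, p={kw.p_value:.2e}")
    gate = shapiro_gate(controls["cystine_crea_ratio"])
    print(f"control cystine distribution reported as {gate['summary_type']}")

    # cystinuria amino-acid profiles for the biallelic genotypes
    biallelic_ids = truth[
        truth.effect_class.str.startswith("cystinuria_biallelic")
    ].index
    v2 = bundle.biochem[
        (bundle.biochem.visit == "V2")
        & bundle.biochem.individual_id.isin(biallelic_ids)
    ]
    n_marked = sum(
        cystinuria_profile(
            {
                "cystine": r.ua_cystine,
                "ornithine": r.ua_ornithine,
                "lysine": r.ua_lysine,
                "arginine": r.ua_arginine,
            }
        ).marked
        for r in v2.itertuples(index=False)
    )
    print(f"marked cystinuria profile in {n_marked}/{len(v2)} biallelic "
          f"carriers at V2")

    results_dir = ROOT / "results"
    results_dir.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(
        results_dir / "04_biochem_comparisons.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
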