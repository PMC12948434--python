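"""Run the variant filter cascade on the simulated bundle.

Applies the quality, cohort-frequency, population-frequency and
consequence filters in order and reports per-stage removal counts.
Requires analysis/01_simulate_cohort.py to have been run first.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from ksdcohort.pipeline import read_bundle
from ksdcohort.variants import FilterConfig, run_filter_cascade

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path,
                    default=ROOT / "scratch" / "bundle")
    args = ap.parse_args()

    bundle = read_bundle(args.bundle)
    n = len(bundle.demographics)
    filtered, report = run_filter_cascade(bundle.variants, FilterConfig(), n)
    print(f"{report.n_input} calls in, {report.n_output} retained")
    print(f"removed: quality={report.removed_quality}, "
          f"cohort-frequency={report.removed_cohort_frequency}, "
          f"gnomAD={report.removed_population_frequency}, "
          f"consequence={report.removed_consequence}")

    results_dir = ROOT / "results"
    results_dir.mkdir(exist_ok=True)
    (results_dir / "02_filter_report.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
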