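#!/usr/bin/env python
"""Test-retest reliability of every metric across the four runs.

Computes ICC(3,1) per density and scope, the density-averaged overall ICC
with its SD, and the four-level qualitative class. Writes results/icc.tsv
and prints the global-scope summary.
"""

from pathlib import Path

from temponet.io_core import read_cohort, read_metric_table
from temponet.reliability import icc_results_frame, icc_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    metrics = read_metric_table(ROOT / "metrics.tsv")
    cohort = read_cohort(ROOT / "data" / "cohort.csv")
    results = icc_table(metrics, cohort)
    frame = icc_results_frame(results)
    out = ROOT / "icc.tsv"
    frame.to_csv(out, sep="\t", index=False, float_format="%.17g")
    print(f"{len(frame)} scope/metric ICC rows -> {out}")
    for res in results:
        if res.scope == "global":
            print(f"global {res.metric_name}: overall ICC "
                  f"{res.overall_icc:.3f} +/- {res.overall_sd:.3f} "
                  f"({res.reliability_class})")


if __name__ == "__main__":
    main()
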