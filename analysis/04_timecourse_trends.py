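#!/usr/bin/env python
"""Time-course trend analysis: per-miRNA secretion trends, intracellular
cross-reference and total-signal trajectories.

Classifies every detected miRNA's normalized-fraction and raw-intensity
trend against time over the 15-240 min course, cross-references secretory
and intracellular categories, and reports the total secreted signal per
time point.
"""

from pathlib import Path

import pandas as pd

import endomir as em
from endomir.io import dump_json

SIM = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    matrix = em.read_intensity_matrix(SIM / "matrix.tsv")
    sheet = em.read_sample_sheet(SIM / "samples.tsv")
    flags = pd.read_csv(SIM / "flags.tsv", sep="\t", index_col=0).astype(bool)
    results = em.run_all(matrix, sheet, flags=flags)
    tc = results.timecourse

    summary = {
        "trend_counts": {
            "sec_normalized": tc.sec_normalized.counts(),
            "sec_intensity": tc.sec_intensity.counts(),
            "int_normalized": tc.int_normalized.counts(),
            "int_intensity": tc.int_intensity.counts(),
        },
        "sec_total_intensity_by_time": {
            f"{r.time_min:g}min": round(float(r.total_intensity), 1)
            for r in tc.sec_trajectory.itertuples()
        },
        "int_total_intensity_by_time": {
            f"{r.time_min:g}min": round(float(r.total_intensity), 1)
            for r in tc.int_trajectory.itertuples()
        },
        "sec_vs_int_category_contingency": {
            str(k): {str(kk): int(vv) for kk, vv in row.items()}
            for k, row in tc.contingency.to_dict(orient="index").items()
        },
    }
    dump_json(summary, RESULTS / "04_timecourse_trends.json")
    tc.sec_intensity.table.round(6).to_csv(Path("scratch") / "sec_trends_intensity.tsv", sep="\t")
    tc.sec_normalized.table.round(6).to_csv(Path("scratch") / "sec_trends_normalized.tsv", sep="\t")

    si = summary["trend_counts"]["sec_intensity"]
    print(f"secretory intensity trends over {si['total']} detected sec-miRs: "
          f"{si['increasing']} increasing, {si['decreasing']} decreasing, "
          f"{si['unchanged']} unchanged")
    ii = summary["trend_counts"]["int_intensity"]
    print(f"intracellular intensity trends over {ii['total']} detected int-miRs: "
          f"{ii['unchanged']}/{ii['total']} unchanged")
    print("total secreted signal by time:",
          ", ".join(f"{k}={v}" for k, v in summary["sec_total_intensity_by_time"].items()))


if __name__ == "__main__":
    main()
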