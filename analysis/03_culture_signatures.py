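#!/usr/bin/env python
"""Endothelial signatures from the culture grid: detected counts, the
intracellular/secretory partition, condition-vs-donor correlation blocks
and PCA clustering.

Runs the full pipeline on the simulated study (scratch/sim) and reports
the analyses of the 4-donor x 4-medium grid: how many miRNAs each
compartment expresses, the three-way origin partition, whether culture
medium or genetic background drives clustering, and how distinct the
averaged intracellular and secretory signatures are.
"""

from pathlib import Path

import numpy as np
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

    counts = results.data.detection.counts
    cells = counts[[s for s in counts.index if s.startswith("cell-")]]
    media = counts[[s for s in counts.index if s.startswith("cm-")]]
    sig = results.signatures
    comp = results.compare

    summary = {
        "detected_per_cell_sample": {"mean": float(cells.mean()), "sd": float(cells.std(ddof=0))},
        "detected_per_medium_sample": {"mean": float(media.mean()), "sd": float(media.std(ddof=0))},
        "partition": sig.partition.counts(),
        "int_vs_sec_signature": {
            "rho": round(sig.int_vs_sec.rho, 4),
            "p": sig.int_vs_sec.p_value,
            "n": sig.int_vs_sec.n,
        },
        "shared_mirnas_int_vs_sec": {
            "rho": round(sig.both_subset_rho.rho, 4),
            "p": sig.both_subset_rho.p_value,
        },
        "condition_blocks_cells": {
            "same_donor_cross_media": {
                "mean": round(float(np.mean(comp.cell_groups["same_donor_diff_medium"])), 4),
                "sd": round(float(np.std(comp.cell_groups["same_donor_diff_medium"])), 4),
            },
            "same_medium_cross_donors": {
                "mean": round(float(np.mean(comp.cell_groups["same_medium_diff_donor"])), 4),
                "sd": round(float(np.std(comp.cell_groups["same_medium_diff_donor"])), 4),
            },
            "tests_p": {k: v.p_value for k, v in comp.cell_condition_tests.items()},
        },
        "cell_pca_variance_ratio_pc1_pc2": [
            round(float(v), 4) for v in comp.cell_pca.explained_ratio[:2]
        ],
    }
    dump_json(summary, RESULTS / "03_culture_signatures.json")
    comp.cell_matrix.rho.round(4).to_csv(RESULTS / "03_cell_correlation_matrix.tsv", sep="\t")
    comp.cell_pca.scores.round(6).to_csv(Path("scratch") / "cell_pca_scores.tsv", sep="\t")

    print(f"detected per cell sample: {cells.mean():.0f} (+/- {cells.std(ddof=0):.0f}); "
          f"per conditioned medium: {media.mean():.0f} (+/- {media.std(ddof=0):.0f})")
    p = summary["partition"]
    print(f"partition of {p['total']} detected miRNAs: {p['int_only']} intracellular-only, "
          f"{p['sec_only']} secreted-only, {p['both']} both")
    print(f"averaged int vs sec signature: rho = {summary['int_vs_sec_signature']['rho']} "
          f"(p = {summary['int_vs_sec_signature']['p']:.2g})")
    cb = summary["condition_blocks_cells"]
    print(f"same donor across media: rho = {cb['same_donor_cross_media']['mean']} "
          f"(+/- {cb['same_donor_cross_media']['sd']}); "
          f"same medium across donors: rho = {cb['same_medium_cross_donors']['mean']} "
          f"(+/- {cb['same_medium_cross_donors']['sd']}); "
          f"Welch p = {cb['tests_p']['welch_t']:.2g}")


if __name__ == "__main__":
    main()
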