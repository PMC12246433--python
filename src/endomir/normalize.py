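"""Background handling, detection calls and fraction-of-total normalization.

The pipeline's core transform expresses each sample as the fraction of its
total signal intensity carried by each miRNA.  Fractions are invariant to
per-sample rescaling of intensities, which is what lets the method tolerate
substantial variation in RNA input without spike-ins or external standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import ProbeIntensityMatrix, SampleSheet
from .qc import DetectionThreshold


@dataclass
class DetectionMatrix:
    """Boolean probe x sample detection calls against a threshold."""

    table: pd.DataFrame  # bool
    threshold: float

    @property
    def counts(self) -> pd.Series:
        """Number of detected miRNAs per sample."""
        return self.table.sum(axis=0)

    def detected_union(self, samples, min_detect_samples: int = 1) -> set[str]:
        """miRNAs detected in at least ``min_detect_samples`` of ``samples``."""
        samples = list(samples)
        missing = [s for s in samples if s not in self.table.columns]
        if missing:
            raise ContractError(f"samples not in detection matrix: {missing}")
        if not samples:
            return set()
        hits = self.table[samples].sum(axis=1) >= min_detect_samples
        return set(self.table.index[hits])


@dataclass
class FractionMatrix:
    """Probe x sample fractions of total intensity; columns sum to 1."""

    table: pd.DataFrame
    masked: bool  # whether undetected entries were zeroed before totalling

    @property
    def column_sums(self) -> pd.Series:
        return self.table.sum(axis=0)


def subtract_background(
    matrix: ProbeIntensityMatrix,
    sheet: SampleSheet,
    blank_compartment: str = "blank_medium",
    target_compartments: tuple[str, ...] = ("conditioned_medium",),
) -> ProbeIntensityMatrix:
    """Subtract mean blank-medium intensity from conditioned-medium samples.

    Blanks are matched by culture medium, falling back to the pooled mean of
    all blanks when a medium has none of its own; results are floored at 0
    and blank columns are dropped.  Compartments without a measured blank
    (cells, blood, WBC) pass through unchanged.
    """
    blanks = sheet.of(blank_compartment)
    blank_ids = [s for s in blanks["sample_id"] if s in matrix.values.columns]
    by_medium: dict[str, pd.Series] = {}
    for medium, grp in blanks.groupby("culture_medium"):
        ids = [s for s in grp["sample_id"] if s in matrix.values.columns]
        if ids:
            by_medium[medium] = matrix.values[ids].mean(axis=1)
    pooled = matrix.values[blank_ids].mean(axis=1) if blank_ids else None

    out = matrix.values.copy()
    for _, row in sheet.table.iterrows():
        if row["compartment"] not in target_compartments:
            continue
        sid = row["sample_id"]
        if sid not in out.columns:
            continue
        medium = row["culture_medium"]
        if medium in by_medium:
            bg = by_medium[medium]
        elif pooled is not None:
            warnings.warn(
                f"no blank for medium {medium!r}; using pooled mean of all blanks"
            )
            bg = pooled
        else:
            raise ContractError(
                f"conditioned-medium sample {sid!r} has no matching blank "
                f"for medium {medium!r} and no blanks exist"
            )
        out[sid] = np.maximum(out[sid] - bg, 0.0)
    keep = [c for c in out.columns if c not in set(blank_ids)]
    return ProbeIntensityMatrix(out[keep], matrix.scale_tag)


def call_detection(
    matrix: ProbeIntensityMatrix, threshold: DetectionThreshold | float
) -> DetectionMatrix:
    """Strictly-greater-than detection calls (a probe exactly at the
    threshold is undetected)."""
    if isinstance(threshold, DetectionThreshold):
        if threshold.scale_tag != matrix.scale_tag:
            raise ContractError(
                f"threshold scale {threshold.scale_tag!r} != matrix scale {matrix.scale_tag!r}"
            )
        value = threshold.value
    else:
        value = float(threshold)
    if not value > 0:
        raise ContractError("detection threshold must be > 0")
    return DetectionMatrix(table=matrix.values > value, threshold=value)


def normalize_total(
    matrix: ProbeIntensityMatrix,
    qc_pass: list[str] | None = None,
    mask: DetectionMatrix | None = None,
) -> FractionMatrix:
    """Fraction-of-total-intensity normalization over QC-passing probes.

    With ``mask`` given, undetected entries are zeroed before totalling so
    that signatures range over detected miRNAs only.
    """
    values = matrix.values
    if qc_pass is not None:
        missing = [p for p in qc_pass if p not in values.index]
        if missing:
            raise ContractError(f"qc_pass probes not in matrix: {missing[:5]}")
        values = values.loc[list(qc_pass)]
    if mask is not None:
        m = mask.table.reindex(index=values.index, columns=values.columns).fillna(False)
        values = values.where(m, 0.0)
    totals = values.sum(axis=0)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise ContractError(f"zero total intensity in samples: {list(zero.index)}")
    return FractionMatrix(table=values / totals, masked=mask is not None)
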