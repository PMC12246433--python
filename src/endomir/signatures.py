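"""Averaged compartment signatures, origin partition and blood attribution.

A signature is a miRNA profile on the simplex: fractions of total signal
summing to 1 over the detected support.  The origin partition splits the
detected endothelial universe into intracellular-only, secreted-only and
shared miRNAs; blood samples are then classified miRNA-by-miRNA as
endothelial-origin candidates (present in the endothelial reference) or
non-endothelial (absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .normalize import DetectionMatrix, FractionMatrix


@dataclass
class Signature:
    """Normalized fraction vector for one sample or an averaged group."""

    label: str
    fractions: pd.Series  # over the support, sums to 1
    n_samples: int
    provenance: list[str]

    @property
    def support(self) -> set[str]:
        return set(self.fractions.index[self.fractions > 0])

    def as_series(self, universe=None) -> pd.Series:
        """Fractions over a wider miRNA universe, zero-filled."""
        if universe is None:
            return self.fractions
        return self.fractions.reindex(universe, fill_value=0.0)


@dataclass
class OriginPartition:
    int_only: set[str]
    sec_only: set[str]
    both: set[str]

    def __post_init__(self) -> None:
        if self.int_only & self.sec_only or self.int_only & self.both or self.sec_only & self.both:
            raise ContractError("origin partition sets must be pairwise disjoint")

    @property
    def universe(self) -> set[str]:
        return self.int_only | self.sec_only | self.both

    def counts(self) -> dict[str, int]:
        return {
            "int_only": len(self.int_only),
            "sec_only": len(self.sec_only),
            "both": len(self.both),
            "total": len(self.universe),
        }


@dataclass
class BloodOriginLabels:
    """Per blood sample: endothelial-origin (E) vs non-endothelial (N) sets."""

    endothelial: dict[str, set[str]]
    non_endothelial: dict[str, set[str]]
    reference_used: str

    def counts(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s,
                "n_endothelial": len(self.endothelial[s]),
                "n_non_endothelial": len(self.non_endothelial[s]),
            }
            for s in self.endothelial
        ]
        return pd.DataFrame(rows)


def average_signature(
    fractions: FractionMatrix,
    detection: DetectionMatrix,
    samples,
    min_detect_samples: int = 1,
    label: str = "signature",
) -> Signature:
    """Average a group of samples into one signature.

    miRNAs detected in at least ``min_detect_samples`` of the group enter
    the support; per-miRNA fractions (undetected entries counted as 0) are
    averaged arithmetically and then renormalized to sum 1, which keeps the
    result on the simplex regardless of differing supports.
    """
    samples = list(samples)
    if not samples:
        raise ContractError("average_signature needs a nonempty sample set")
    if min_detect_samples > len(samples):
        raise ContractError("min_detect_samples exceeds the number of samples")
    missing = [s for s in samples if s not in fractions.table.columns]
    if missing:
        raise ContractError(f"samples not in fraction matrix: {missing}")
    F = fractions.table[samples]
    det = detection.table.reindex(index=F.index)[samples].fillna(False)
    support = det.sum(axis=1) >= min_detect_samples
    if not support.any():
        raise ContractError("averaged signature has empty support")
    mean = F.where(det, 0.0).mean(axis=1)[support]
    total = mean.sum()
    if total <= 0:
        raise ContractError("averaged signature sums to zero")
    return Signature(
        label=label, fractions=mean / total, n_samples=len(samples), provenance=samples
    )


def partition_origin(cell_detected: set[str], media_detected: set[str]) -> OriginPartition:
    """Three-way split of the detected universe by compartment membership."""
    cells, media = set(cell_detected), set(media_detected)
    return OriginPartition(
        int_only=cells - media, sec_only=media - cells, both=cells & media
    )


def classify_blood(
    blood_detection: DetectionMatrix,
    reference: set[str],
    samples=None,
    reference_used: str = "cells",
) -> BloodOriginLabels:
    """Split each blood sample's detected set by presence in the endothelial
    reference (E = detected & reference, N = detected - reference)."""
    if not reference:
        raise ContractError("endothelial reference set is empty")
    ids = list(samples) if samples is not None else list(blood_detection.table.columns)
    endo: dict[str, set[str]] = {}
    non: dict[str, set[str]] = {}
    for s in ids:
        detected = blood_detection.detected_union([s])
        endo[s] = detected & reference
        non[s] = detected - reference
    return BloodOriginLabels(endothelial=endo, non_endothelial=non, reference_used=reference_used)
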