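"""Serial-dilution probe QC and detection-threshold derivation.

A pooled RNA extract measured across a serial dilution lets every probe be
tested for dose-response linearity: probes whose intensity does not
correlate significantly (Pearson, two-sided) with input amount are not
quantitative and are disregarded downstream.  The same series yields a
detection threshold: the mean intensity of probes that newly appear with
each increase of input material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .io import ProbeIntensityMatrix, SampleSheet
from . import correlate


@dataclass
class DetectionThreshold:
    """Intensity threshold derived from newly detected probes.

    ``value`` is the arithmetic mean, pooled over all consecutive dilution
    steps, of the intensities (at first appearance) of probes present at the
    larger input but absent at the smaller.  Per-step sets and means are
    kept for transparency.
    """

    value: float
    n_contributing_probes: int
    per_step_new_probe_ids: dict[str, list[str]]
    per_step_means: dict[str, float]
    scale_tag: str = "linear"


@dataclass
class ProbeQCReport:
    """Per-probe dose-response statistics and the derived pass/fail set."""

    table: pd.DataFrame  # columns: r, p, n, passed; index: probe_id
    alpha: float
    filtered_fraction: float
    threshold: DetectionThreshold | None = None

    @property
    def passing_probes(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    @property
    def failing_probes(self) -> list[str]:
        return list(self.table.index[~self.table["passed"]])

    def summary(self) -> dict:
        out = {
            "n_probes": int(len(self.table)),
            "n_failed": int((~self.table["passed"]).sum()),
            "filtered_fraction": float(self.filtered_fraction),
            "alpha": self.alpha,
        }
        if self.threshold is not None:
            out["detection_threshold"] = self.threshold.value
            out["per_step_new_probe_counts"] = {
                k: len(v) for k, v in self.threshold.per_step_new_probe_ids.items()
            }
        return out


def _dilution_columns(matrix: ProbeIntensityMatrix, sheet: SampleSheet) -> tuple[pd.DataFrame, np.ndarray]:
    dil = sheet.dilution_samples()
    if dil.empty:
        raise ContractError("dilution series required: no dilution_member samples in sheet")
    missing = [s for s in dil["sample_id"] if s not in matrix.values.columns]
    if missing:
        raise ContractError(f"dilution samples absent from matrix: {missing}")
    X = matrix.values[list(dil["sample_id"])]
    ng = dil["input_ng"].to_numpy(dtype=float)
    return X, ng


def probe_dose_response(
    matrix: ProbeIntensityMatrix, sheet: SampleSheet, alpha: float = 0.05
) -> ProbeQCReport:
    """Pearson dose-response test for every probe across the dilution series.

    A probe passes when its two-sided p-value is below ``alpha`` and its
    correlation is finite; zero-variance probes have undefined r and fail.
    Requires at least three distinct input amounts.
    """
    X, ng = _dilution_columns(matrix, sheet)
    if np.unique(ng).size < 3:
        raise ContractError(
            "probe dose-response needs >= 3 distinct input_ng values "
            f"(got {np.unique(ng).size})"
        )
    V = X.to_numpy(dtype=float)
    n = ng.size
    xd = ng - ng.mean()
    yd = V - V.mean(axis=1, keepdims=True)
    sxy = yd @ xd
    sxx = float(xd @ xd)
    syy = np.einsum("ij,ij->i", yd, yd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    r = np.where(syy > 0, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.isnan(r), np.nan, 2.0 * stats.t.sf(np.abs(t), n - 2))
    p = np.where(np.isfinite(t) | np.isnan(r), p, 0.0)  # |r| == 1 -> p = 0
    passed = np.isfinite(r) & (p < alpha)
    table = pd.DataFrame(
        {"r": r, "p": p, "n": n, "passed": passed}, index=X.index.rename("probe_id")
    )
    filtered_fraction = float((~passed).mean()) if len(table) else 0.0
    return ProbeQCReport(table=table, alpha=alpha, filtered_fraction=filtered_fraction)


def _present_matrix(X: pd.DataFrame, present_call) -> pd.DataFrame:
    """Boolean present/absent calls for the dilution columns.

    ``present_call`` is either the string ``"positive"`` (signal > 0 after
    background handling — the fallback when no detection-flag matrix exists),
    a boolean DataFrame aligned like the intensity matrix (e.g. scanner
    flags), or a callable mapping the intensity frame to booleans.
    """
    if isinstance(present_call, str):
        if present_call != "positive":
            raise ContractError(f"unknown present_call rule {present_call!r}")
        return X > 0
    if isinstance(present_call, pd.DataFrame):
        missing = [c for c in X.columns if c not in present_call.columns]
        if missing:
            raise ContractError(f"flag matrix lacks dilution samples: {missing}")
        return present_call.reindex(index=X.index)[X.columns].fillna(False).astype(bool)
    if callable(present_call):
        return present_call(X).astype(bool)
    raise ContractError("present_call must be 'positive', a flag DataFrame or a callable")


def derive_detection_threshold(
    matrix: ProbeIntensityMatrix,
    sheet: SampleSheet,
    present_call="positive",
) -> DetectionThreshold:
    """Mean intensity of probes newly detected along the dilution series.

    For each consecutive pair of inputs, probes present at the larger but
    absent at the smaller input contribute their intensity at first
    detection; the threshold is the mean pooled over all steps (a probe that
    flickers contributes once per appearance).
    """
    X, ng = _dilution_columns(matrix, sheet)
    if np.unique(ng).size != ng.size:
        raise ContractError("dilution inputs must be strictly increasing and distinct")
    present = _present_matrix(X, present_call)
    per_step_ids: dict[str, list[str]] = {}
    per_step_means: dict[str, float] = {}
    pooled: list[float] = []
    cols = list(X.columns)
    for i in range(len(cols) - 1):
        lo, hi = cols[i], cols[i + 1]
        new = present[hi] & ~present[lo]
        ids = list(X.index[new])
        step = f"{ng[i]:g}->{ng[i + 1]:g}"
        per_step_ids[step] = ids
        vals = X.loc[ids, hi].to_numpy(dtype=float)
        per_step_means[step] = float(vals.mean()) if len(vals) else float("nan")
        pooled.extend(vals.tolist())
    if not pooled:
        raise ContractError(
            "no newly detected probes at any dilution step; "
            "supply a manual detection threshold instead"
        )
    return DetectionThreshold(
        value=float(np.mean(pooled)),
        n_contributing_probes=len(pooled),
        per_step_new_probe_ids=per_step_ids,
        per_step_means=per_step_means,
        scale_tag=matrix.scale_tag,
    )


def pattern_robustness(
    matrix: ProbeIntensityMatrix,
    sheet: SampleSheet,
    reference_input: float,
    probes: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each dilution sample's normalized pattern
    against the reference input's, quantifying how far fraction-of-total
    normalization tolerates variable RNA input.
    """
    X, ng = _dilution_columns(matrix, sheet)
    if probes is not None:
        X = X.loc[probes]
    hits = np.flatnonzero(np.isclose(ng, reference_input))
    if hits.size == 0:
        raise ContractError(f"reference_input {reference_input} not in the dilution series")
    totals = X.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ContractError(f"zero total intensity in dilution samples: {bad}")
    fr = X / totals
    ref = fr.iloc[:, hits[0]]
    rows = []
    for j, col in enumerate(fr.columns):
        res = correlate.spearman(fr[col], ref, policy="union", p_method="approx")
        rows.append({"input_ng": ng[j], "sample_id": col, "rho": res.rho, "p": res.p_value})
    return pd.DataFrame(rows)
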