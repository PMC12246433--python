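"""End-to-end orchestration of the analysis stages.

``run_all`` chains dilution QC -> background subtraction -> detection ->
fraction normalization -> signatures/partition -> correlation blocks (+
blood attribution when blood samples are present, + time-course trends when
time points are present) on one matrix + sample sheet, dispatching on what
the sheet contains.  Each stage is also callable on its own; the
command-line layer and the analysis scripts are thin wrappers over these
functions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correlate, normalize, qc, signatures, timecourse
from .errors import ContractError
from .io import AnalysisConfig, ProbeIntensityMatrix, SampleSheet


def _grid_cells(sheet: SampleSheet) -> pd.DataFrame:
    """Cell-pellet rows of the culture grid (no dilution, no time course)."""
    rows = sheet.of("cell")
    return rows[~rows["dilution_member"] & rows["time_min"].isna()]


def _grid_media(sheet: SampleSheet) -> pd.DataFrame:
    rows = sheet.of("conditioned_medium")
    return rows[rows["time_min"].isna()]


def run_qc_stage(
    matrix: ProbeIntensityMatrix,
    sheet: SampleSheet,
    config: AnalysisConfig,
    flags: pd.DataFrame | None = None,
) -> qc.ProbeQCReport:
    """Dose-response QC and (when configured) threshold derivation.

    ``flags`` is an optional scanner present/absent matrix used for the
    newly-detected calls; without it the signal > 0 fallback applies.
    """
    report = qc.probe_dose_response(matrix, sheet, alpha=config.alpha)
    if config.detection_threshold == "derive":
        present_call = flags if flags is not None else "positive"
        report.threshold = qc.derive_detection_threshold(matrix, sheet, present_call)
    return report


@dataclass
class NormalizedData:
    matrix: ProbeIntensityMatrix  # background-subtracted, blanks dropped
    detection: normalize.DetectionMatrix
    fractions: normalize.FractionMatrix
    qc_pass: list[str]
    threshold: float


def run_normalize_stage(
    matrix: ProbeIntensityMatrix,
    sheet: SampleSheet,
    config: AnalysisConfig,
    qc_report: qc.ProbeQCReport | None = None,
) -> NormalizedData:
    """Background subtraction, detection calls and fraction normalization."""
    if config.detection_threshold == "derive":
        if qc_report is None or qc_report.threshold is None:
            qc_report = run_qc_stage(matrix, sheet, config)
        threshold = qc_report.threshold.value
    else:
        threshold = float(config.detection_threshold)
    qc_pass = qc_report.passing_probes if qc_report is not None else matrix.probe_ids

    has_blanks = not sheet.of("blank_medium").empty
    sub = normalize.subtract_background(matrix, sheet) if has_blanks else matrix
    detection = normalize.call_detection(sub, threshold)
    mask = detection if config.mask_undetected else None
    fractions = normalize.normalize_total(sub, qc_pass=qc_pass, mask=mask)
    return NormalizedData(
        matrix=sub, detection=detection, fractions=fractions, qc_pass=qc_pass, threshold=threshold
    )


@dataclass
class SignatureStage:
    cell_union: set[str]
    media_union: set[str]
    partition: signatures.OriginPartition
    int_signature: signatures.Signature
    sec_signature: signatures.Signature
    int_vs_sec: correlate.CorrelationResult
    both_subset_rho: correlate.CorrelationResult


def run_signature_stage(
    data: NormalizedData, sheet: SampleSheet, config: AnalysisConfig
) -> SignatureStage:
    cells = list(_grid_cells(sheet)["sample_id"])
    media = list(_grid_media(sheet)["sample_id"])
    if not cells or not media:
        raise ContractError("signature stage needs both cell and conditioned-medium samples")
    cell_union = data.detection.detected_union(cells, config.min_detect_samples)
    media_union = data.detection.detected_union(media, config.min_detect_samples)
    part = signatures.partition_origin(cell_union, media_union)
    int_sig = signatures.average_signature(
        data.fractions, data.detection, cells, config.min_detect_samples, label="endothelial_int"
    )
    sec_sig = signatures.average_signature(
        data.fractions, data.detection, media, config.min_detect_samples, label="endothelial_sec"
    )
    universe = sorted(part.universe)
    policy = config.correlation_subset_policy
    int_vs_sec = correlate.spearman(
        int_sig.as_series(universe), sec_sig.as_series(universe), policy=policy
    )
    both = sorted(part.both) if len(part.both) >= 3 else universe
    both_rho = correlate.spearman(
        int_sig.as_series(both), sec_sig.as_series(both), policy="intersection"
        if len(part.both) >= 3
        else policy,
    )
    return SignatureStage(
        cell_union=cell_union,
        media_union=media_union,
        partition=part,
        int_signature=int_sig,
        sec_signature=sec_sig,
        int_vs_sec=int_vs_sec,
        both_subset_rho=both_rho,
    )


def donor_medium_coefficient_groups(
    summary: correlate.BlockSummary, rows: pd.DataFrame
) -> dict[str, list[float]]:
    """Split pairwise coefficients into the two contrasts of the culture
    grid: same donor across media vs same medium across donors."""
    meta = rows.set_index("sample_id")
    groups: dict[str, list[float]] = {"same_donor_diff_medium": [], "same_medium_diff_donor": []}
    ids = [s for s in summary.rho.index if s in meta.index]
    for a, b in itertools.combinations(ids, 2):
        da, db = meta.loc[a, "donor"], meta.loc[b, "donor"]
        ma, mb = meta.loc[a, "culture_medium"], meta.loc[b, "culture_medium"]
        rho = float(summary.rho.loc[a, b])
        if da == db and ma != mb:
            groups["same_donor_diff_medium"].append(rho)
        elif ma == mb and da != db:
            groups["same_medium_diff_donor"].append(rho)
    return groups


@dataclass
class CompareStage:
    cell_matrix: correlate.BlockSummary
    media_matrix: correlate.BlockSummary
    cell_groups: dict[str, list[float]]
    media_groups: dict[str, list[float]]
    cell_condition_tests: dict[str, correlate.ComparisonResult]
    media_condition_tests: dict[str, correlate.ComparisonResult]
    cell_pca: correlate.PCAResult
    media_pca: correlate.PCAResult


def run_compare_stage(
    data: NormalizedData, sheet: SampleSheet, config: AnalysisConfig
) -> CompareStage:
    cells = _grid_cells(sheet)
    media = _grid_media(sheet)
    policy = config.correlation_subset_policy
    F = data.fractions.table
    cell_m = correlate.correlation_matrix(F[list(cells["sample_id"])], policy)
    media_m = correlate.correlation_matrix(F[list(media["sample_id"])], policy)
    cell_groups = donor_medium_coefficient_groups(cell_m, cells)
    media_groups = donor_medium_coefficient_groups(media_m, media)

    def _tests(groups):
        out = {}
        a, b = groups["same_donor_diff_medium"], groups["same_medium_diff_donor"]
        if len(a) >= 2 and len(b) >= 2:
            for test in ("student_t", "welch_t", "mann_whitney"):
                out[test] = correlate.compare_coefficient_groups(a, b, test=test)
        return out

    return CompareStage(
        cell_matrix=cell_m,
        media_matrix=media_m,
        cell_groups=cell_groups,
        media_groups=media_groups,
        cell_condition_tests=_tests(cell_groups),
        media_condition_tests=_tests(media_groups),
        cell_pca=correlate.pca(F[list(cells["sample_id"])]),
        media_pca=correlate.pca(F[list(media["sample_id"])]),
    )


@dataclass
class BloodStage:
    matrix: correlate.BlockSummary  # blood + endothelial sample columns
    labels: signatures.BloodOriginLabels
    tests: dict[str, correlate.ComparisonResult]
    pca: correlate.PCAResult


_BLOOD_GROUP = {
    "serum": "serum",
    "plasma": "plasma",
    "cell": "endo_int",
    "conditioned_medium": "endo_sec",
    "wbc": "wbc_int",
    "wbc_medium": "wbc_sec",
}


def run_blood_stage(
    data: NormalizedData,
    sheet: SampleSheet,
    config: AnalysisConfig,
    sig_stage: SignatureStage,
) -> BloodStage:
    blood = sheet.table[sheet.table["compartment"].isin(["serum", "plasma"])]
    if blood.empty:
        raise ContractError("blood stage needs serum or plasma samples")
    wbc = sheet.table[sheet.table["compartment"].isin(["wbc", "wbc_medium"])]
    cells = _grid_cells(sheet)
    media = _grid_media(sheet)
    ids = (
        list(blood["sample_id"])
        + list(wbc["sample_id"])
        + list(media["sample_id"])
        + list(cells["sample_id"])
    )
    summary = correlate.correlation_matrix(
        data.fractions.table[ids], config.correlation_subset_policy
    )
    meta = sheet.table.set_index("sample_id")
    grouping = {s: _BLOOD_GROUP[meta.loc[s, "compartment"]] for s in ids}
    pairs = [("serum", "endo_sec"), ("plasma", "endo_sec"), ("serum", "endo_int"), ("plasma", "endo_int")]
    if len(blood["compartment"].unique()) == 2:
        pairs.append(("serum", "plasma"))
    if not wbc.empty:
        pairs += [("serum", "wbc_sec"), ("plasma", "wbc_sec")]
    summary = correlate.block_stats(summary, grouping, pairs)

    tests = {}
    sb = summary.blocks.get(("serum", "endo_sec"))
    pb = summary.blocks.get(("plasma", "endo_sec"))
    if sb is not None and pb is not None and sb.n_pairs >= 2 and pb.n_pairs >= 2:
        for test in ("student_t", "welch_t", "mann_whitney"):
            tests[test] = correlate.compare_coefficient_groups(sb.values, pb.values, test=test)

    reference = {
        "cells": sig_stage.cell_union,
        "media": sig_stage.media_union,
        "both": sig_stage.cell_union | sig_stage.media_union,
    }[config.endothelial_reference]
    labels = signatures.classify_blood(
        data.detection,
        reference,
        samples=list(blood["sample_id"]),
        reference_used=config.endothelial_reference,
    )
    return BloodStage(
        matrix=summary,
        labels=labels,
        tests=tests,
        pca=correlate.pca(data.fractions.table[ids]),
    )


@dataclass
class TimecourseStage:
    sec_normalized: timecourse.TrendTable
    int_normalized: timecourse.TrendTable
    sec_intensity: timecourse.TrendTable
    int_intensity: timecourse.TrendTable
    cross: pd.DataFrame
    contingency: pd.DataFrame
    sec_trajectory: pd.DataFrame
    int_trajectory: pd.DataFrame


def run_timecourse_stage(
    data: NormalizedData, sheet: SampleSheet, config: AnalysisConfig
) -> TimecourseStage:
    kw = dict(sheet=sheet, alpha=config.alpha, detection=data.detection)
    sec_n = timecourse.trend_classify(data.fractions, fraction="sec", mode="normalized", **kw)
    int_n = timecourse.trend_classify(data.fractions, fraction="int", mode="normalized", **kw)
    sec_i = timecourse.trend_classify(data.matrix, fraction="sec", mode="intensity", **kw)
    int_i = timecourse.trend_classify(data.matrix, fraction="int", mode="intensity", **kw)
    cross, contingency = timecourse.cross_reference(sec_n, int_n)
    return TimecourseStage(
        sec_normalized=sec_n,
        int_normalized=int_n,
        sec_intensity=sec_i,
        int_intensity=int_i,
        cross=cross,
        contingency=contingency,
        sec_trajectory=timecourse.total_signal_trajectory(data.matrix, sheet, "sec", data.qc_pass),
        int_trajectory=timecourse.total_signal_trajectory(data.matrix, sheet, "int", data.qc_pass),
    )


@dataclass
class StudyResults:
    qc: qc.ProbeQCReport | None
    data: NormalizedData
    signatures: SignatureStage | None
    compare: CompareStage | None
    blood: BloodStage | None
    timecourse: TimecourseStage | None

    def summary(self) -> dict:
        """Scalar summary of every stage that ran, JSON-serializable."""
        out: dict = {"detection_threshold": self.data.threshold}
        counts = self.data.detection.counts
        meta = None
        if self.qc is not None:
            out["qc"] = self.qc.summary()
        out["detected_counts"] = {k: int(v) for k, v in counts.items()}
        if self.signatures is not None:
            s = self.signatures
            out["partition"] = s.partition.counts()
            out["int_vs_sec"] = {
                "rho": s.int_vs_sec.rho,
                "p": s.int_vs_sec.p_value,
                "n": s.int_vs_sec.n,
            }
            out["both_subset"] = {"rho": s.both_subset_rho.rho, "p": s.both_subset_rho.p_value}
        if self.compare is not None:
            c = self.compare
            out["condition_effect"] = {
                "cell_same_donor_diff_medium_mean": float(np.mean(c.cell_groups["same_donor_diff_medium"])),
                "cell_same_medium_diff_donor_mean": float(np.mean(c.cell_groups["same_medium_diff_donor"])),
                "cell_tests": {k: v.p_value for k, v in c.cell_condition_tests.items()},
                "media_tests": {k: v.p_value for k, v in c.media_condition_tests.items()},
            }
        if self.blood is not None:
            b = self.blood
            out["blood_blocks"] = {
                f"{a}~{bb}": {"mean": st.mean, "sd": st.sd, "n_pairs": st.n_pairs}
                for (a, bb), st in (b.matrix.blocks or {}).items()
            }
            out["blood_tests"] = {k: v.p_value for k, v in b.tests.items()}
            out["blood_origin_counts"] = b.labels.counts().to_dict(orient="records")
        if self.timecourse is not None:
            t = self.timecourse
            out["trend_counts"] = {
                "sec_normalized": t.sec_normalized.counts(),
                "int_normalized": t.int_normalized.counts(),
                "sec_intensity": t.sec_intensity.counts(),
                "int_intensity": t.int_intensity.counts(),
            }
            out["sec_total_trajectory"] = t.sec_trajectory.to_dict(orient="records")
        return out


def run_all(
    matrix: ProbeIntensityMatrix,
    sheet: SampleSheet,
    config: AnalysisConfig | None = None,
    flags: pd.DataFrame | None = None,
) -> StudyResults:
    """Run every stage the sheet supports."""
    config = config or AnalysisConfig()
    has_dilution = not sheet.dilution_samples().empty
    qc_report = run_qc_stage(matrix, sheet, config, flags) if has_dilution else None
    if qc_report is None and config.detection_threshold == "derive":
        raise ContractError(
            "dilution series required to derive the detection threshold; "
            "set a numeric detection_threshold or include dilution samples"
        )
    data = run_normalize_stage(matrix, sheet, config, qc_report)

    sig_stage = comp_stage = blood_stage = tc_stage = None
    has_grid = not _grid_cells(sheet).empty and not _grid_media(sheet).empty
    if has_grid:
        sig_stage = run_signature_stage(data, sheet, config)
        if len(_grid_cells(sheet)) >= 2 and len(_grid_media(sheet)) >= 2:
            comp_stage = run_compare_stage(data, sheet, config)
        if not sheet.table[sheet.table["compartment"].isin(["serum", "plasma"])].empty:
            blood_stage = run_blood_stage(data, sheet, config, sig_stage)
    tc_rows = sheet.table[sheet.table["time_min"].notna()]
    if not tc_rows.empty and tc_rows["time_min"].nunique() >= 3:
        tc_stage = run_timecourse_stage(data, sheet, config)
    return StudyResults(
        qc=qc_report,
        data=data,
        signatures=sig_stage,
        compare=comp_stage,
        blood=blood_stage,
        timecourse=tc_stage,
    )
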