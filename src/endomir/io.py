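"""Reading and writing of intensity matrices, sample sheets and configuration.

The on-disk formats are deliberately plain: tab-separated UTF-8 text with a
``.`` decimal point and no quoting, which keeps round trips bit-exact and
matches common array-export conventions.  A simplified reader for Agilent
Feature Extraction text exports is included: it consumes only the probe-name
column, one chosen signal column and an optional detection-flag column from
a tab-delimited file whose header line names its columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError

#: Allowed sample compartments, in the order they appear in the study design.
COMPARTMENTS = (
    "cell",
    "conditioned_medium",
    "blank_medium",
    "serum",
    "plasma",
    "wbc",
    "wbc_medium",
)

#: Culture media used for the endothelial cultures; "none" marks samples
#: (blood, dilution pools) that never saw a culture medium.
MEDIA = ("MCDB", "MCDB-S", "HIM-V", "EGM-2MV", "none")

SHEET_COLUMNS = (
    "sample_id",
    "compartment",
    "donor",
    "culture_medium",
    "time_min",
    "input_ng",
    "replicate",
    "dilution_member",
)


def _find_duplicates(labels: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen and lab not in dups:
            dups.append(lab)
        seen.add(lab)
    return dups


@dataclass
class ProbeIntensityMatrix:
    """A probe x sample table of fluorescence intensities.

    ``values`` has unique probe identifiers as its index and unique sample
    identifiers as its columns.  ``scale_tag`` records the intensity scale;
    the pipeline operates on ``linear`` signals, where every finite value is
    nonnegative.  Missing cells (e.g. probes absent from one of several
    assembled export files) are NaN, never silently zero: a zero is a
    meaningful intensity under fraction-of-total normalization.
    """

    values: pd.DataFrame
    scale_tag: str = "linear"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("linear", "log2"):
            raise ContractError(f"unknown scale_tag {self.scale_tag!r}")
        dup_p = _find_duplicates(self.values.index)
        if dup_p:
            raise ContractError(f"duplicate probe identifiers: {dup_p}")
        dup_s = _find_duplicates(self.values.columns)
        if dup_s:
            raise ContractError(f"duplicate sample identifiers: {dup_s}")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ContractError(f"non-numeric intensity value: {exc}") from exc
        if self.scale_tag == "linear":
            neg = self.values.values < 0
            if np.any(neg):
                i, j = np.argwhere(neg)[0]
                raise ContractError(
                    "negative intensity on linear scale at probe "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ProbeIntensityMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ContractError(f"samples not in matrix: {missing}")
        return ProbeIntensityMatrix(self.values[list(sample_ids)].copy(), self.scale_tag)


@dataclass
class SampleSheet:
    """Per-sample experimental metadata driving every grouping.

    One row per sample with the columns of :data:`SHEET_COLUMNS`.  Optional
    fields (``donor``, ``culture_medium``, ``time_min``, ``input_ng``) are NA
    when absent; ``culture_medium`` defaults to ``"none"``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "sample_id" not in df.columns or "compartment" not in df.columns:
            raise ContractError("sample sheet requires columns sample_id and compartment")
        for col in SHEET_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[list(SHEET_COLUMNS)]
        dup = _find_duplicates(df["sample_id"])
        if dup:
            raise ContractError(f"duplicate sample_id: {dup}")
        bad = sorted(set(df["compartment"]) - set(COMPARTMENTS))
        if bad:
            raise ContractError(
                f"unknown compartment {bad}; allowed: {list(COMPARTMENTS)}"
            )
        df["culture_medium"] = df["culture_medium"].fillna("none")
        unknown_media = sorted(set(df["culture_medium"]) - set(MEDIA))
        if unknown_media:
            warnings.warn(f"non-standard culture_medium labels: {unknown_media}")
        df["donor"] = df["donor"].astype("string")
        df["time_min"] = pd.to_numeric(df["time_min"], errors="raise")
        df["input_ng"] = pd.to_numeric(df["input_ng"], errors="raise")
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").fillna(1).astype(int)
        if (df["replicate"] < 1).any():
            raise ContractError("replicate must be >= 1")
        df["dilution_member"] = (
            df["dilution_member"]
            .map(lambda v: _parse_bool(v), na_action=None)
            .astype(bool)
        )
        if (df["time_min"].dropna() < 0).any():
            raise ContractError("time_min must be >= 0")
        missing_ng = df["dilution_member"] & df["input_ng"].isna()
        if missing_ng.any():
            bad_ids = list(df.loc[missing_ng, "sample_id"])
            raise ContractError(f"dilution_member samples lack input_ng: {bad_ids}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def of(self, compartment: str) -> pd.DataFrame:
        """Rows for one compartment, in sheet order."""
        if compartment not in COMPARTMENTS:
            raise ContractError(f"unknown compartment {compartment!r}")
        return self.table[self.table["compartment"] == compartment]

    def dilution_samples(self) -> pd.DataFrame:
        """Dilution-series rows sorted by strictly increasing input_ng."""
        d = self.table[self.table["dilution_member"]]
        return d.sort_values("input_ng", kind="stable")

    def row(self, sample_id: str) -> pd.Series:
        hit = self.table[self.table["sample_id"] == sample_id]
        if hit.empty:
            raise ContractError(f"sample {sample_id!r} not in sheet")
        return hit.iloc[0]


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
        return False
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ContractError(f"cannot parse boolean {v!r}")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    alpha
        Two-sided significance level used for probe QC, trend classification
        and group comparisons.
    detection_threshold
        Either a positive intensity on the matrix scale or the string
        ``"derive"``, in which case the threshold is computed from the
        dilution series (mean intensity of newly detected probes).
    min_detect_samples
        Minimum number of samples a miRNA must be detected in to enter an
        averaged signature or detected-union set.
    correlation_subset_policy
        ``"union"`` compares two signatures over the union of their supports
        with zero-fill; ``"intersection"`` restricts to shared support.
    endothelial_reference
        Which endothelial detected-union serves as the blood E/N reference:
        ``"cells"``, ``"media"`` or ``"both"``.
    """

    alpha: float = 0.05
    detection_threshold: float | str = "derive"
    min_detect_samples: int = 1
    correlation_subset_policy: str = "union"
    endothelial_reference: str = "cells"
    mask_undetected: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ContractError("alpha must lie strictly between 0 and 1")
        if isinstance(self.detection_threshold, str):
            if self.detection_threshold != "derive":
                raise ContractError("detection_threshold must be numeric or 'derive'")
        elif not self.detection_threshold > 0:
            raise ContractError("numeric detection_threshold must be > 0")
        if self.min_detect_samples < 1:
            raise ContractError("min_detect_samples must be >= 1")
        if self.correlation_subset_policy not in ("union", "intersection"):
            raise ContractError("correlation_subset_policy must be union|intersection")
        if self.endothelial_reference not in ("cells", "media", "both"):
            raise ContractError("endothelial_reference must be cells|media|both")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ContractError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# intensity matrices

def read_intensity_matrix(path: str | Path, scale_tag: str = "linear") -> ProbeIntensityMatrix:
    """Read a probe x sample TSV (first column probe_id, header sample ids).

    A ``log2`` input is exponentiated on load (with a warning) so the rest of
    the pipeline always sees linear-scale signal, on which the detection
    threshold and fraction normalization are defined.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ContractError(f"non-numeric cell in {path}: {exc}") from exc
    mat = ProbeIntensityMatrix(df, scale_tag=scale_tag)
    if scale_tag == "log2":
        warnings.warn("log2-scale input exponentiated to linear scale on load")
        mat = ProbeIntensityMatrix(np.power(2.0, mat.values), scale_tag="linear")
    return mat


def write_intensity_matrix(matrix: ProbeIntensityMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.table.copy()
    out["dilution_member"] = out["dilution_member"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simplified Agilent Feature Extraction text export

def read_agilent_fe(
    paths: Sequence[str | Path],
    signal_column: str,
    flag_column: str | None = None,
    probe_column: str = "ProbeName",
) -> tuple[ProbeIntensityMatrix, pd.DataFrame | None]:
    """Assemble one matrix column per Feature Extraction export file.

    Probes are the union across files; cells absent from a file are NaN
    (missing, distinct from 0).  Duplicate spots for a probe within one file
    are averaged (flags combined with "any").  When ``flag_column`` is given,
    a parallel boolean present/absent frame is returned as well.
    """
    if not paths:
        raise ContractError("no Feature Extraction files given")
    cols: dict[str, pd.Series] = {}
    flag_cols: dict[str, pd.Series] = {}
    for p in paths:
        p = Path(p)
        df = pd.read_csv(p, sep="\t")
        for needed in filter(None, (probe_column, signal_column, flag_column)):
            if needed not in df.columns:
                raise ContractError(
                    f"column {needed!r} absent from {p.name}; available: {list(df.columns)}"
                )
        grouped = df.groupby(probe_column, sort=False)
        sig = grouped[signal_column].mean()
        sample_id = p.stem
        if sample_id in cols:
            raise ContractError(f"duplicate sample id from file stem {sample_id!r}")
        cols[sample_id] = sig
        if flag_column is not None:
            flag_cols[sample_id] = grouped[flag_column].apply(
                lambda v: bool(np.any(np.asarray(v, dtype=float) != 0))
            )
    values = pd.DataFrame(cols)
    matrix = ProbeIntensityMatrix(values)
    flags = None
    if flag_column is not None:
        flags = pd.DataFrame(flag_cols).reindex(values.index).fillna(False).astype(bool)
    return matrix, flags


# ---------------------------------------------------------------------------
# small JSON helper shared by result writers


def dump_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
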