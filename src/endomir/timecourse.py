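"""Per-miRNA temporal trend classification over the time-course design.

Each detected miRNA is correlated (Pearson) against time in minutes, after
averaging technical replicates within each time point.  A miRNA is
"increasing" when p < alpha and r > 0, "decreasing" when p < alpha and
r < 0, otherwise "unchanged"; a zero-variance series has undefined r and is
never significant.  The same rule is applied either to normalized fractions
("normalized" mode) or to raw intensities ("intensity" mode).  Raw p-values
drive the categories; Benjamini-Hochberg q-values are reported alongside as
a supplementary column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError
from .io import ProbeIntensityMatrix, SampleSheet
from .normalize import DetectionMatrix, FractionMatrix

_FRACTION_COMPARTMENT = {"sec": "conditioned_medium", "int": "cell"}


@dataclass
class TrendTable:
    """Trend records for all detected miRNAs of one fraction and mode."""

    table: pd.DataFrame  # index mirna; columns r, p, q, category, n_timepoints
    fraction: str  # "sec" | "int"
    mode: str  # "normalized" | "intensity"
    alpha: float

    def counts(self) -> dict[str, int]:
        c = self.table["category"].value_counts().to_dict()
        return {
            "increasing": int(c.get("increasing", 0)),
            "decreasing": int(c.get("decreasing", 0)),
            "unchanged": int(c.get("unchanged", 0)),
            "total": int(len(self.table)),
        }


def _timecourse_layout(sheet: SampleSheet, fraction: str) -> pd.DataFrame:
    if fraction not in _FRACTION_COMPARTMENT:
        raise ContractError("fraction must be 'sec' or 'int'")
    rows = sheet.of(_FRACTION_COMPARTMENT[fraction])
    rows = rows[rows["time_min"].notna()]
    if rows.empty:
        raise ContractError(f"no time-course samples for fraction {fraction!r}")
    return rows


def _replicate_means(values: pd.DataFrame, rows: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Average replicate columns per time point; columns ordered by time."""
    groups = rows.groupby("time_min")["sample_id"].apply(list).sort_index()
    means = pd.DataFrame(
        {t: values[ids].mean(axis=1) for t, ids in groups.items()}
    )
    return means, groups.index.to_numpy(dtype=float)


def trend_classify(
    matrix: FractionMatrix | ProbeIntensityMatrix | pd.DataFrame,
    sheet: SampleSheet,
    fraction: str = "sec",
    mode: str = "normalized",
    alpha: float = 0.05,
    detection: DetectionMatrix | None = None,
    average_replicates: bool = True,
) -> TrendTable:
    """Classify each detected miRNA's trend against time.

    ``matrix`` should hold fractions for ``mode="normalized"`` and raw (or
    background-subtracted) intensities for ``mode="intensity"``.  Detected
    miRNAs are those flagged in ``detection`` for at least one time-course
    sample of the fraction, or (fallback) with nonzero signal in one.
    """
    if mode not in ("normalized", "intensity"):
        raise ContractError("mode must be 'normalized' or 'intensity'")
    values = matrix.table if isinstance(matrix, FractionMatrix) else (
        matrix.values if isinstance(matrix, ProbeIntensityMatrix) else matrix
    )
    rows = _timecourse_layout(sheet, fraction)
    ids = [s for s in rows["sample_id"] if s in values.columns]
    if len(ids) < len(rows):
        missing = sorted(set(rows["sample_id"]) - set(ids))
        raise ContractError(f"time-course samples absent from matrix: {missing}")
    if rows["time_min"].nunique() < 3:
        raise ContractError("trend classification needs >= 3 distinct time points")

    if detection is not None:
        detected = detection.table.reindex(index=values.index)[ids].fillna(False).any(axis=1)
    else:
        detected = (values[ids] != 0).any(axis=1)
    V = values.loc[detected, ids]

    if average_replicates:
        Y, t = _replicate_means(V, rows)
    else:
        order = rows.sort_values(["time_min", "replicate"])["sample_id"]
        Y = V[list(order)]
        t = rows.set_index("sample_id").loc[list(order), "time_min"].to_numpy(dtype=float)

    n = t.size
    td = t - t.mean()
    yd = Y.to_numpy(dtype=float) - Y.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yd, yd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yd @ td) / np.sqrt((td @ td) * syy)
    r = np.where(syy > 0, np.clip(r, -1, 1), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.isnan(r), np.nan, 2.0 * stats.t.sf(np.abs(tstat), n - 2))
    p = np.where(np.isfinite(tstat) | np.isnan(r), p, 0.0)

    significant = np.isfinite(r) & (p < alpha)
    category = np.where(
        significant & (r > 0), "increasing", np.where(significant & (r < 0), "decreasing", "unchanged")
    )
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    table = pd.DataFrame(
        {"r": r, "p": p, "q": q, "category": category, "n_timepoints": n},
        index=Y.index.rename("mirna"),
    )
    return TrendTable(table=table, fraction=fraction, mode=mode, alpha=alpha)


def cross_reference(sec: TrendTable, int_: TrendTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join secretory and intracellular trends on miRNA id.

    Returns the joined per-miRNA table and a contingency table of
    (sec category x int category) counts.  A disjoint join yields an empty
    frame (with a warning via the empty contingency).
    """
    joined = sec.table[["category"]].join(
        int_.table[["category"]], how="inner", lsuffix="_sec", rsuffix="_int"
    )
    joined = joined.rename(columns={"category_sec": "sec_category", "category_int": "int_category"})
    if joined.empty:
        import warnings

        warnings.warn("secretory and intracellular trend tables share no miRNAs")
        contingency = pd.DataFrame()
    else:
        contingency = pd.crosstab(joined["sec_category"], joined["int_category"])
    return joined.reset_index(), contingency


def total_signal_trajectory(
    matrix: ProbeIntensityMatrix | pd.DataFrame,
    sheet: SampleSheet,
    fraction: str = "sec",
    probes: list[str] | None = None,
) -> pd.DataFrame:
    """Replicate-averaged total intensity (over QC-passing probes) per time
    point — the summary behind "total secreted signal increases with time"."""
    values = matrix.values if isinstance(matrix, ProbeIntensityMatrix) else matrix
    if probes is not None:
        values = values.loc[[p for p in probes if p in values.index]]
    rows = _timecourse_layout(sheet, fraction)
    means, t = _replicate_means(values[list(rows["sample_id"])], rows)
    totals = means.sum(axis=0)
    return pd.DataFrame({"time_min": t, "total_intensity": totals.to_numpy(dtype=float)})
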