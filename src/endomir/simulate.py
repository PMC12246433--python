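"""Synthetic microarray generator with known ground truth.

The generator emulates the structure of an endothelial secretome microarray
study: per-probe linear dose-response with probe-specific slopes and a small
minority of saturating (QC-filterable) probes; compartment abundance
profiles for the endothelial intracellular and secretory pools with a
controlled overlap; white-blood-cell intracellular/secretory pools and an
"other tissues" pool; donor and culture-medium log-normal effects (the
medium effect larger by default); serum and plasma as convex mixtures over
the pools with a tunable endothelial-secretory weight; blank-medium
background; and monotone per-miRNA secretion time trends.

Signal model for probe p in sample s (linear probes)::

    intensity = slope_p * input_ng_s * abundance_p(s) * donor_mult * medium_mult
                [* trend_mult(t)] + intercept_p + background + N(0, noise_sd),

floored at 0.  Blank-medium samples carry intercept + background only.
Non-linear probes replace the linear term by a Michaelis-Menten saturation
that plateaus near the signal of the lowest dilution input, which makes
their dose-response correlation insignificant by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import ProbeIntensityMatrix, SampleSheet, dump_json

POOLS = ("endothelial_secretory", "wbc_secretory", "wbc_intracellular", "other")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic world; defaults encode the study design."""

    # miRNA universe and endothelial overlap design
    n_mirnas: int = 900
    n_int_only: int = 155
    n_sec_only: int = 166
    n_shared: int = 253

    # study layout
    huvec_donors: tuple[str, ...] = ("1302", "1308", "1309", "1314")
    timecourse_donor: str = "1332"
    media: tuple[str, ...] = ("MCDB", "MCDB-S", "HIM-V", "EGM-2MV")
    n_blood_donors: int = 4
    n_wbc_donors: int = 3
    dilution_grid: tuple[float, ...] = (12.5, 25.0, 50.0, 75.0, 100.0, 150.0)
    time_grid: tuple[float, ...] = (15.0, 30.0, 60.0, 120.0, 240.0)
    replicates: int = 3
    standard_input_ng: float = 100.0

    # abundance and probe model
    dirichlet_concentration: float = 1.0
    slope_median: float = 40.0
    slope_log_sd: float = 0.5
    intercept: float = 0.0
    background_level: float = 0.5
    noise_sd: float = 0.01
    nonlinear_probe_fraction: float = 0.027
    saturation_kappa: float = 0.02
    # scanner-style detection: a probe is flagged present when its
    # deterministic signal exceeds the detection floor, emulating
    # feature-extraction present/absent calls.  The default floor sits at
    # the detect_floor_quantile of the lowest-input pooled-dilution signals
    # (never below detection_snr * noise_sd), so the detection limit lies
    # inside the assay's dynamic range and probes appear progressively
    # along the dilution series; detect_floor overrides it outright.
    detection_snr: float = 3.0
    detect_floor: float | None = None
    detect_floor_quantile: float = 0.25
    # small abundance mass spread over the whole probe repertoire in the
    # pooled dilution extract (carrier RNA / cross-hybridization floor), so
    # every probe has a dose-response to evaluate
    pool_trace_fraction: float = 0.05

    # biological effect sizes
    donor_effect_sd: float = 0.25
    medium_effect_sd: float = 0.5
    secretion_yield: float = 0.35
    wbc_support_fraction: float = 0.85
    other_support_fraction: float = 0.5

    # blood mixtures: weights over POOLS
    serum_weights: tuple[float, ...] = (0.75, 0.10, 0.05, 0.10)
    plasma_weights: tuple[float, ...] = (0.40, 0.25, 0.10, 0.25)

    # secretion time trends over the secretory support
    trend_counts: tuple[int, int] | None = None  # (n_up, n_down); rest flat
    trend_fractions: tuple[float, float] = (0.39, 0.07)
    trend_up_rate: float = 1.0
    trend_down_rate: float = 0.5

    # which pool the serial-dilution pooled extract represents
    dilution_pool: str = "endothelial_union"  # or "cells"

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_int_only, self.n_sec_only, self.n_shared) < 0:
            raise ContractError("counts must be >= 0")
        if self.n_int_only + self.n_sec_only + self.n_shared > self.n_mirnas:
            raise ContractError(
                "overlap design exceeds n_mirnas: "
                f"{self.n_int_only}+{self.n_sec_only}+{self.n_shared} > {self.n_mirnas}"
            )
        grid = np.asarray(self.dilution_grid, dtype=float)
        if len(grid) and np.any(np.diff(grid) <= 0):
            raise ContractError("dilution_grid must be strictly increasing")
        if not 0 <= self.nonlinear_probe_fraction <= 1:
            raise ContractError("nonlinear_probe_fraction must lie in [0, 1]")
        if self.n_wbc_donors > self.n_blood_donors:
            raise ContractError("n_wbc_donors cannot exceed n_blood_donors")
        for w in (self.serum_weights, self.plasma_weights):
            w = np.asarray(w, dtype=float)
            if len(w) != len(POOLS) or np.any(w < 0) or abs(w.sum() - 1) > 1e-9:
                raise ContractError(f"mixture weights must be a length-{len(POOLS)} simplex vector")
        if self.trend_counts is not None:
            up, down = self.trend_counts
            if up < 0 or down < 0 or up + down > self.n_sec_only + self.n_shared:
                raise ContractError("trend_counts exceed the secretory support")
        if self.dilution_pool not in ("endothelial_union", "cells"):
            raise ContractError("dilution_pool must be endothelial_union|cells")
        if not 0 <= self.pool_trace_fraction < 1:
            raise ContractError("pool_trace_fraction must lie in [0, 1)")
        if not 0 < self.detect_floor_quantile < 1:
            raise ContractError("detect_floor_quantile must lie in (0, 1)")

    @property
    def blood_donors(self) -> tuple[str, ...]:
        return tuple(f"bd{i + 1}" for i in range(self.n_blood_donors))

    @property
    def wbc_donors(self) -> tuple[str, ...]:
        return self.blood_donors[: self.n_wbc_donors]

    @property
    def n_sec_support(self) -> int:
        return self.n_sec_only + self.n_shared


@dataclass
class SyntheticWorld:
    """Ground truth realized from a :class:`GeneratorConfig`."""

    config: GeneratorConfig
    mirna_ids: list[str]
    profiles: dict[str, np.ndarray]  # relative abundance vectors, each sums to 1
    donor_effects: dict[str, np.ndarray]  # multiplicative, per miRNA
    medium_effects: dict[str, np.ndarray]
    mixture_weights: dict[str, np.ndarray]  # "<donor>/<serum|plasma>" -> weights over POOLS
    trend_direction: np.ndarray  # +1 up, -1 down, 0 flat, per miRNA
    slopes: np.ndarray
    intercepts: np.ndarray
    linear: np.ndarray  # bool per probe
    sat_vmax: np.ndarray  # plateau signal of non-linear probes
    sat_k: np.ndarray  # half-saturation constant (signal-model units)
    background_level: float
    detect_floor: float = 0.0  # deterministic-signal level of the present flag

    # -- ground-truth accessors -------------------------------------------
    def support(self, profile: str) -> set[str]:
        return {m for m, a in zip(self.mirna_ids, self.profiles[profile]) if a > 0}

    @property
    def int_support(self) -> set[str]:
        return self.support("endothelial_intracellular")

    @property
    def sec_support(self) -> set[str]:
        return self.support("endothelial_secretory")

    def trend_truth(self) -> pd.Series:
        labels = np.array(["unchanged", "increasing", "decreasing"])
        return pd.Series(labels[self.trend_direction], index=self.mirna_ids, name="category")

    def nonlinear_probe_ids(self) -> set[str]:
        return {m for m, ok in zip(self.mirna_ids, self.linear) if not ok}

    def truth_dict(self) -> dict:
        """JSON-serializable ground truth for recovery tests."""
        return {
            "config": dataclasses.asdict(self.config),
            "mirna_ids": self.mirna_ids,
            "int_support": sorted(self.int_support),
            "sec_support": sorted(self.sec_support),
            "nonlinear_probes": sorted(self.nonlinear_probe_ids()),
            "trend_direction": {
                m: int(d) for m, d in zip(self.mirna_ids, self.trend_direction) if d != 0
            },
            "mixture_weights": {k: v.tolist() for k, v in self.mixture_weights.items()},
            "background_level": self.background_level,
            "detect_floor": self.detect_floor,
        }

    def save_truth(self, path: str | Path) -> None:
        dump_json(self.truth_dict(), path)


def _dirichlet_profile(rng: np.random.Generator, n: int, support: np.ndarray, conc: float) -> np.ndarray:
    prof = np.zeros(n)
    k = support.size
    if k:
        prof[support] = rng.dirichlet(np.full(k, conc))
    return prof


def generate_world(config: GeneratorConfig) -> SyntheticWorld:
    """Realize abundance profiles, effects, probe model and trends."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_mirnas
    mirna_ids = [f"syn-miR-{i + 1:04d}" for i in range(n)]

    perm = rng.permutation(n)
    int_only = perm[: cfg.n_int_only]
    sec_only = perm[cfg.n_int_only : cfg.n_int_only + cfg.n_sec_only]
    shared = perm[cfg.n_int_only + cfg.n_sec_only : cfg.n_int_only + cfg.n_sec_only + cfg.n_shared]
    int_sup = np.sort(np.concatenate([int_only, shared]))
    sec_sup = np.sort(np.concatenate([sec_only, shared]))

    conc = cfg.dirichlet_concentration
    profiles = {
        "endothelial_intracellular": _dirichlet_profile(rng, n, int_sup, conc),
        "endothelial_secretory": _dirichlet_profile(rng, n, sec_sup, conc),
    }
    n_wbc = int(round(cfg.wbc_support_fraction * n))
    n_other = int(round(cfg.other_support_fraction * n))
    profiles["wbc_intracellular"] = _dirichlet_profile(
        rng, n, np.sort(rng.choice(n, size=n_wbc, replace=False)), conc
    )
    profiles["wbc_secretory"] = _dirichlet_profile(
        rng, n, np.sort(rng.choice(n, size=max(1, int(round(0.9 * n_wbc))), replace=False)), conc
    )
    profiles["other"] = _dirichlet_profile(
        rng, n, np.sort(rng.choice(n, size=n_other, replace=False)), conc
    )
    if cfg.dilution_pool == "cells":
        pool = profiles["endothelial_intracellular"].copy()
    else:
        pool = profiles["endothelial_intracellular"] + profiles["endothelial_secretory"]
        pool = pool / pool.sum()
    f = cfg.pool_trace_fraction
    profiles["dilution_pool"] = (1.0 - f) * pool + f / n

    donor_effects: dict[str, np.ndarray] = {"pooled": np.ones(n)}
    for d in (*cfg.huvec_donors, cfg.timecourse_donor, *cfg.blood_donors):
        donor_effects.setdefault(d, np.exp(rng.normal(0.0, cfg.donor_effect_sd, n)))
    medium_effects: dict[str, np.ndarray] = {"none": np.ones(n)}
    for m in cfg.media:
        medium_effects[m] = np.exp(rng.normal(0.0, cfg.medium_effect_sd, n))

    mixture_weights = {}
    for d in cfg.blood_donors:
        mixture_weights[f"{d}/serum"] = np.asarray(cfg.serum_weights, dtype=float)
        mixture_weights[f"{d}/plasma"] = np.asarray(cfg.plasma_weights, dtype=float)

    # monotone secretion trends over the secretory support
    trend_direction = np.zeros(n, dtype=np.int8)
    if cfg.trend_counts is not None:
        n_up, n_down = cfg.trend_counts
    else:
        n_up = int(round(cfg.trend_fractions[0] * sec_sup.size))
        n_down = int(round(cfg.trend_fractions[1] * sec_sup.size))
    order = rng.permutation(sec_sup)
    trend_direction[order[:n_up]] = 1
    trend_direction[order[n_up : n_up + n_down]] = -1

    slopes = cfg.slope_median * np.exp(rng.normal(0.0, cfg.slope_log_sd, n))
    intercepts = np.full(n, float(cfg.intercept))
    linear = np.ones(n, dtype=bool)
    k_nl = int(round(cfg.nonlinear_probe_fraction * n))
    if k_nl:
        linear[rng.choice(n, size=k_nl, replace=False)] = False

    # non-linear probes plateau near their signal at the lowest dilution
    # input, so the dose-response stays essentially flat across the series
    ref_abund = profiles["dilution_pool"].copy()
    ref_abund[ref_abund == 0] = 1.0 / n
    low_ng = cfg.dilution_grid[0] if cfg.dilution_grid else cfg.standard_input_ng
    u_ref = slopes * low_ng * ref_abund
    sat_vmax = u_ref
    sat_k = cfg.saturation_kappa * u_ref

    if cfg.detect_floor is not None:
        floor = float(cfg.detect_floor)
    else:
        floor = max(
            cfg.detection_snr * cfg.noise_sd,
            float(np.quantile(u_ref, cfg.detect_floor_quantile)),
        )

    return SyntheticWorld(
        config=cfg,
        mirna_ids=mirna_ids,
        profiles=profiles,
        donor_effects=donor_effects,
        medium_effects=medium_effects,
        mixture_weights=mixture_weights,
        trend_direction=trend_direction,
        slopes=slopes,
        intercepts=intercepts,
        linear=linear,
        sat_vmax=sat_vmax,
        sat_k=sat_k,
        background_level=cfg.background_level,
        detect_floor=floor,
    )


# ---------------------------------------------------------------------------
# array simulation

# compartments carrying the blank-medium background signal (culture media
# contain carrier RNA, e.g. from bovine serum supplements); the WBC medium
# is serum-free and blood has no measured blank
_BACKGROUND_COMPARTMENTS = {"conditioned_medium", "blank_medium"}


def _abundance(world: SyntheticWorld, row: pd.Series) -> np.ndarray:
    """Deterministic relative-abundance vector for one sheet row."""
    cfg = world.config
    comp = row["compartment"]
    donor = row["donor"] if pd.notna(row["donor"]) else "pooled"
    medium = row["culture_medium"]
    if donor not in world.donor_effects:
        raise ContractError(f"donor {donor!r} absent from world")
    if medium not in world.medium_effects:
        raise ContractError(f"culture medium {medium!r} absent from world")
    d_eff = world.donor_effects[donor]
    m_eff = world.medium_effects[medium]

    if comp == "blank_medium":
        return np.zeros(cfg.n_mirnas)
    if comp == "cell":
        if row["dilution_member"]:
            return world.profiles["dilution_pool"].copy()
        return world.profiles["endothelial_intracellular"] * d_eff * m_eff
    if comp == "conditioned_medium":
        a = world.profiles["endothelial_secretory"] * d_eff * m_eff * cfg.secretion_yield
        t = row["time_min"]
        if pd.notna(t):
            tmax = max(cfg.time_grid) if cfg.time_grid else 1.0
            frac = float(t) / tmax
            mult = np.ones(cfg.n_mirnas)
            mult[world.trend_direction == 1] += cfg.trend_up_rate * frac
            mult[world.trend_direction == -1] -= cfg.trend_down_rate * frac
            a = a * np.maximum(mult, 0.0)
        return a
    if comp in ("serum", "plasma"):
        key = f"{donor}/{comp}"
        if key not in world.mixture_weights:
            raise ContractError(f"no mixture weights for {key!r}")
        w = world.mixture_weights[key]
        pools = np.stack([world.profiles[p] for p in POOLS])
        return (w @ pools) * d_eff
    if comp == "wbc":
        return world.profiles["wbc_intracellular"] * d_eff
    if comp == "wbc_medium":
        return world.profiles["wbc_secretory"] * d_eff * cfg.secretion_yield
    raise ContractError(f"unknown compartment {comp!r}")


def simulate_arrays(
    world: SyntheticWorld, sheet: SampleSheet, seed: int, with_flags: bool = False
) -> ProbeIntensityMatrix | tuple[ProbeIntensityMatrix, pd.DataFrame]:
    """Simulate one intensity column per sheet row under the signal model.

    With ``noise_sd = 0`` the output is exactly the deterministic signal
    model; identical (world, sheet, seed) triples give bit-identical output.
    ``with_flags=True`` additionally returns scanner-style present/absent
    flags: True where the deterministic biological signal (before intercept,
    background and noise) exceeds the world's detection floor.
    """
    cfg = world.config
    rng = np.random.default_rng(seed)
    cols = {}
    flag_cols = {}
    floor = world.detect_floor
    nl = ~world.linear
    for _, row in sheet.table.iterrows():
        a = _abundance(world, row)
        ng = row["input_ng"] if pd.notna(row["input_ng"]) else cfg.standard_input_ng
        u = world.slopes * float(ng) * a
        sig = u.copy()
        if nl.any():
            sig[nl] = world.sat_vmax[nl] * u[nl] / (u[nl] + world.sat_k[nl])
        flag_cols[row["sample_id"]] = sig > floor
        sig = sig + world.intercepts
        if row["compartment"] in _BACKGROUND_COMPARTMENTS:
            sig = sig + world.background_level
        if cfg.noise_sd > 0:
            sig = sig + rng.normal(0.0, cfg.noise_sd, cfg.n_mirnas)
        cols[row["sample_id"]] = np.maximum(sig, 0.0)
    values = pd.DataFrame(cols, index=world.mirna_ids)
    matrix = ProbeIntensityMatrix(values)
    if with_flags:
        return matrix, pd.DataFrame(flag_cols, index=world.mirna_ids)
    return matrix


# ---------------------------------------------------------------------------
# study-design presets

PRESETS = ("huvec_grid", "dilution_series", "timecourse", "blood_panel")


def preset_designs(name: str, config: GeneratorConfig | None = None) -> SampleSheet:
    """Sample sheets for the study's designs.

    huvec_grid
        4 donors x 4 media x {cell pellet, conditioned medium} plus one
        blank per medium (36 rows by default).
    dilution_series
        One pooled-extract sample per dilution input (6 by default,
        spanning 12.5-150 ng around the 100 ng protocol standard).
    timecourse
        time grid x triplicates x {cell, conditioned medium} from a single
        donor in MCDB, plus one blank.
    blood_panel
        Paired serum/plasma per blood donor plus WBC pellets and WBC
        conditioned media.
    """
    cfg = config or GeneratorConfig()
    rows: list[dict] = []
    if name == "huvec_grid":
        for d in cfg.huvec_donors:
            for m in cfg.media:
                rows.append(dict(sample_id=f"cell-{d}-{m}", compartment="cell", donor=d, culture_medium=m))
                rows.append(dict(sample_id=f"cm-{d}-{m}", compartment="conditioned_medium", donor=d, culture_medium=m))
        for m in cfg.media:
            rows.append(dict(sample_id=f"blank-{m}", compartment="blank_medium", culture_medium=m))
    elif name == "dilution_series":
        for ng in cfg.dilution_grid:
            rows.append(
                dict(
                    sample_id=f"dil-{ng:g}ng",
                    compartment="cell",
                    donor="pooled",
                    input_ng=ng,
                    dilution_member=True,
                )
            )
    elif name == "timecourse":
        d = cfg.timecourse_donor
        for t in cfg.time_grid:
            for r in range(1, cfg.replicates + 1):
                rows.append(
                    dict(sample_id=f"tc-cell-t{t:g}-r{r}", compartment="cell", donor=d,
                         culture_medium="MCDB", time_min=t, replicate=r)
                )
                rows.append(
                    dict(sample_id=f"tc-cm-t{t:g}-r{r}", compartment="conditioned_medium", donor=d,
                         culture_medium="MCDB", time_min=t, replicate=r)
                )
        rows.append(dict(sample_id="tc-blank-MCDB", compartment="blank_medium", culture_medium="MCDB"))
    elif name == "blood_panel":
        for d in cfg.blood_donors:
            rows.append(dict(sample_id=f"serum-{d}", compartment="serum", donor=d))
            rows.append(dict(sample_id=f"plasma-{d}", compartment="plasma", donor=d))
        for d in cfg.wbc_donors:
            rows.append(dict(sample_id=f"wbc-{d}", compartment="wbc", donor=d))
            rows.append(dict(sample_id=f"wbcm-{d}", compartment="wbc_medium", donor=d))
    else:
        raise ContractError(f"unknown preset {name!r}; available: {list(PRESETS)}")
    return SampleSheet(pd.DataFrame(rows))


def concat_sheets(*sheets: SampleSheet) -> SampleSheet:
    """Combine designs into one sheet; duplicate sample ids are rejected."""
    return SampleSheet(pd.concat([s.table for s in sheets], ignore_index=True))
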