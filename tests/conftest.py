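"""Shared fixtures: small synthetic worlds and hand-built tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import endomir as em


@pytest.fixture(scope="session")
def small_config() -> em.GeneratorConfig:
    """A compact world: 150 miRNAs, endothelial overlap 30/35/40."""
    return em.GeneratorConfig(
        n_mirnas=150, n_int_only=30, n_sec_only=35, n_shared=40, seed=11
    )


@pytest.fixture(scope="session")
def small_world(small_config) -> em.SyntheticWorld:
    return em.generate_world(small_config)


@pytest.fixture(scope="session")
def noiseless_config() -> em.GeneratorConfig:
    return em.GeneratorConfig(
        n_mirnas=150, n_int_only=30, n_sec_only=35, n_shared=40, noise_sd=0.0, seed=11
    )


@pytest.fixture(scope="session")
def noiseless_world(noiseless_config) -> em.SyntheticWorld:
    return em.generate_world(noiseless_config)


@pytest.fixture()
def tiny_matrix() -> em.ProbeIntensityMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["miR-a", "miR-b", "miR-c"],
        columns=["s1", "s2"],
    )
    return em.ProbeIntensityMatrix(values)


@pytest.fixture()
def tiny_sheet() -> em.SampleSheet:
    return em.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "compartment": ["cell", "serum"],
            }
        )
    )


def dilution_sheet(inputs=(12.5, 25.0, 50.0, 100.0)) -> em.SampleSheet:
    return em.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"d{i}" for i in range(len(inputs))],
                "compartment": ["cell"] * len(inputs),
                "input_ng": list(inputs),
                "dilution_member": [True] * len(inputs),
            }
        )
    )


# ---------------------------------------------------------------------------
# independent oracles used across test modules (plain-Python, no numpy
# vectorization, so they cannot share a code path with the implementation)


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / (sxx * syy) ** 0.5


def rank_oracle(v) -> list[float]:
    """Average ranks, 1-based, via explicit tie groups."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    return pearson_oracle(rank_oracle(list(x)), rank_oracle(list(y)))
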