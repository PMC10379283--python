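"""Shared fixtures: small synthetic stacks, tables and a direct table builder."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ratdiv import (
    PREDICTORS,
    AnalysisTable,
    SyntheticScenario,
    extract_at_points,
    generate_localities,
    generate_stack,
)


def make_table(
    ho,
    X=None,
    insularity=None,
    species: str = "rattus",
    rng: np.random.Generator | None = None,
) -> AnalysisTable:
    """Build an AnalysisTable directly from arrays (no geography involved)."""
    ho = np.asarray(ho, dtype=float)
    n = ho.size
    if X is None:
        rng = rng or np.random.default_rng(0)
        X = rng.normal(size=(n, len(PREDICTORS)))
    X = np.asarray(X, dtype=float)
    if insularity is None:
        insularity = ["mainland"] * n
    data = pd.DataFrame(X, columns=list(PREDICTORS))
    data.insert(0, "ho", ho)
    meta = pd.DataFrame(
        {
            "study_id": [f"s{i}" for i in range(n)],
            "site": [f"site{i}" for i in range(n)],
            "lon": np.linspace(-170, 170, n),
            "lat": np.linspace(-80, 80, n),
            "insularity": list(insularity),
            "marker": ["microsatellite"] * n,
        }
    )
    return AnalysisTable(data=data, species=species, meta=meta)


def linear_table(
    n: int,
    beta,
    noise_sd: float,
    seed: int,
    intercept: float = 0.5,
    insular_fraction: float = 0.0,
) -> AnalysisTable:
    """Table whose Ho follows a known linear function of the predictors."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(PREDICTORS)))
    ho = np.clip(
        intercept + X @ np.asarray(beta, dtype=float)
        + rng.normal(0, noise_sd, size=n),
        0.0, 1.0,
    )
    ins = np.where(rng.random(n) < insular_fraction, "island", "mainland")
    return make_table(ho, X, insularity=ins)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    return SyntheticScenario(
        seed=42, nrows=24, ncols=48, cellsize=7.5,
        n_localities=60, nodata_fraction=0.1,
    )


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    return generate_stack(small_scenario)


@pytest.fixture(scope="session")
def small_records(small_scenario, small_stack):
    return generate_localities(small_scenario, small_stack)


@pytest.fixture(scope="session")
def small_table(small_stack, small_records):
    table, _ = extract_at_points(small_stack, small_records)
    return table
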