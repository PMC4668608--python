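import numpy as np
import pandas as pd
import pytest

from sharedcar.inference import McmcSettings, PosteriorSamples
from sharedcar.model import ModelSpec
from sharedcar.spatial_graph import AreaGraph, grid_graph
from sharedcar.synthetic import CohortTable, Covariate, CovariateSchema


@pytest.fixture
def path3() -> AreaGraph:
    """Three areas in a path: 1-2, 2-3."""
    return AreaGraph(area_ids=["a", "b", "c"], neighbours=[[1], [0, 2], [1]])


@pytest.fixture
def two_components() -> AreaGraph:
    """A 3-clique and a 2-clique, disconnected."""
    return AreaGraph(
        area_ids=list("abcde"),
        neighbours=[[1, 2], [0, 2], [0, 1], [4], [3]],
    )


@pytest.fixture
def grid25() -> AreaGraph:
    return grid_graph(5, 5)


def random_graph(rng: np.random.Generator, n_max: int = 8, p_edge: float = 0.4) -> AreaGraph:
    """Erdos-Renyi-style symmetric areal graph (possibly disconnected)."""
    n = int(rng.integers(2, n_max + 1))
    nb = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                nb[i].append(j)
                nb[j].append(i)
    return AreaGraph(area_ids=[f"g{i}" for i in range(n)], neighbours=nb)


@pytest.fixture
def binary_schema() -> CovariateSchema:
    """Minimal one-covariate schema for conjugate-limit checks."""
    return CovariateSchema((Covariate("xbin", ("a", "b"), "a", (1, 1)),))


def make_cohort(y: np.ndarray, area_ids, covariates: dict | None = None) -> CohortTable:
    """Cohort from an (n, 3) outcome array and per-row area ids."""
    y = np.asarray(y)
    df = pd.DataFrame(
        {
            "individual_id": np.arange(1, len(y) + 1),
            "area_id": list(area_ids),
            "y_radio": y[:, 0],
            "y_chemo": y[:, 1],
            "y_hormone": y[:, 2],
        }
    )
    for name, vals in (covariates or {}).items():
        df[name] = vals
    return CohortTable(df)


def manual_samples(
    draws: dict[str, np.ndarray],
    spec: ModelSpec | None = None,
    design_columns: list[str] | None = None,
    area_ids: list[str] | None = None,
) -> PosteriorSamples:
    """Hand-built PosteriorSamples for diagnostics/summary unit tests."""
    any_arr = next(iter(draws.values()))
    n_iter = max(2 * any_arr.shape[1], 4)
    settings = McmcSettings(
        n_chains=any_arr.shape[0],
        n_iterations=n_iter,
        burn_in=n_iter - any_arr.shape[1],
        thin=1,
        seed=0,
    )
    return PosteriorSamples(
        draws={k: np.asarray(v, dtype=float) for k, v in draws.items()},
        spec=spec or ModelSpec.from_variant("A0"),
        settings=settings,
        seed=0,
        design_columns=design_columns or [],
        area_ids=area_ids or [],
    )
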