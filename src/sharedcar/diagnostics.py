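"""Convergence diagnostics, model-fit criteria and posterior summary rules.

DIC follows the Spiegelhalter construction: Dbar (posterior mean deviance)
plus pD, where pD = Dbar - D(plug-in) and the plug-in deviance is evaluated
at the posterior mean of the linear predictor (the likelihood depends on the
parameters only through it).  The posterior predictive check (PPC) is the
fraction of observed binary outcomes lying within the central 95 % range of
their posterior predictive replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .inference import PosteriorSamples
from .model import ModelSpec, ParameterState, design_matrix, linear_predictor_matrix
from .spatial_graph import AreaGraph
from .synthetic import TREATMENTS, CohortTable, CovariateSchema, default_schema

__all__ = [
    "FitReport",
    "gelman_rubin",
    "gelman_rubin_table",
    "dic",
    "ppc_coverage",
    "summarize_effects",
    "relative_weights",
]


@dataclass
class FitReport:
    """Fit criteria for one model run; dic = dbar + pd by construction."""

    dic: float
    dbar: float
    pd: float
    ppc: float
    rhat_max: float
    variant: str
    cohort_hash: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def gelman_rubin(samples: PosteriorSamples | dict) -> dict[str, np.ndarray]:
    """Potential scale reduction per scalar parameter component.

    Classic between/within construction on whole chains:
    ``R = sqrt(((m-1)/m * W + B/m) / W)`` with m draws per chain, floored at
    1.0 (values below 1 are estimation noise; constant identical chains give
    exactly 1.0).  Requires >= 2 chains with >= 10 retained draws.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else samples
    out = {}
    for name, arr in draws.items():
        c, m = arr.shape[:2]
        if c < 2:
            raise ValueError("Gelman-Rubin requires at least 2 chains")
        if m < 10:
            raise ValueError("Gelman-Rubin requires at least 10 retained draws per chain")
        flat = arr.reshape(c, m, -1)
        W = flat.var(axis=1, ddof=1).mean(axis=0)
        B = m * flat.mean(axis=1).var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            V = (m - 1) / m * W + B / m
            r = np.sqrt(V / W)
        r = np.where(W <= 0, 1.0, np.maximum(r, 1.0))
        out[name] = r.reshape(arr.shape[2:])
    return out


def gelman_rubin_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Flat per-component table of the statistic."""
    stats = gelman_rubin(samples)
    rows = []
    for name, r in stats.items():
        for idx, val in np.ndenumerate(np.atleast_1d(r)):
            label = name if r.ndim == 0 else name + "[" + ",".join(map(str, idx)) + "]"
            rows.append({"parameter": label, "rhat": float(val)})
    return pd.DataFrame(rows)


def _state_from_draw(samples: PosteriorSamples, c: int, r: int, na: int, p: int) -> ParameterState:
    st = ParameterState.zeros(na, p, samples.spec)
    for name in samples.draws:
        if hasattr(st, name):
            setattr(st, name, np.asarray(samples.draws[name][c, r]))
    if "phi2" in samples.draws and st.phi2 is None:
        st.phi2 = np.asarray(samples.draws["phi2"][c, r])
        st.log_delta2 = np.asarray(samples.draws["log_delta2"][c, r])
    return st


def _design_for(samples, cohort, graph, schema, drop):
    schema = schema or default_schema()
    x, cols = design_matrix(cohort, schema, drop=drop)
    if cols != samples.design_columns:
        raise ValueError("cohort design does not match the design the samples were fit on")
    return x, cohort.area_index(graph)


def _bernoulli_deviance(y: np.ndarray, psi: np.ndarray) -> float:
    return -2.0 * float(np.sum(y * psi + log_expit(-psi)))


def dic(
    samples: PosteriorSamples,
    spec: ModelSpec,
    cohort: CohortTable,
    graph: AreaGraph,
    schema: CovariateSchema | None = None,
    drop: tuple[str, ...] = (),
) -> tuple[float, float, float]:
    """(dic, dbar, pd): posterior mean deviance plus effective parameters.

    Uses the per-draw deviances stored with the samples when available,
    otherwise reconstructs them from the parameter draws.
    """
    if samples.n_retained == 0:
        raise ValueError("empty samples")
    y = cohort.outcomes.astype(float)
    if samples.deviance is not None and samples.psi_mean is not None:
        dbar = float(samples.deviance.mean())
        dhat = _bernoulli_deviance(y, samples.psi_mean)
    else:
        x, area_idx = _design_for(samples, cohort, graph, schema, drop)
        na, p = graph.n_areas, x.shape[1]
        devs = []
        psi_sum = np.zeros((len(cohort), 3))
        for c in range(samples.n_chains):
            for r in range(samples.n_retained):
                st = _state_from_draw(samples, c, r, na, p)
                psi = linear_predictor_matrix(st, spec, x, area_idx)
                devs.append(_bernoulli_deviance(y, psi))
                psi_sum += psi
        dbar = float(np.mean(devs))
        dhat = _bernoulli_deviance(y, psi_sum / len(devs))
    pd_ = dbar - dhat
    return dbar + pd_, dbar, pd_


def ppc_coverage(
    samples: PosteriorSamples,
    spec: ModelSpec,
    cohort: CohortTable,
    graph: AreaGraph,
    schema: CovariateSchema | None = None,
    drop: tuple[str, ...] = (),
    n_replicates: int = 200,
    seed: int = 0,
) -> float:
    """Fraction of observed outcomes inside the central 95 % of their
    posterior predictive replicates.

    For each individual-by-treatment cell, outcomes are simulated from the
    likelihood under a random subsample of posterior draws; the observation
    is covered when it lies within the 2.5th-97.5th percentile range of its
    replicate set.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    total = samples.n_chains * samples.n_retained
    if total < 100:
        raise ValueError("need at least 100 retained draws for the predictive check")
    rng = np.random.default_rng(seed)
    pick = rng.choice(total, size=min(n_replicates, total), replace=False)
    x, area_idx = _design_for(samples, cohort, graph, schema, drop)
    na, p = graph.n_areas, x.shape[1]
    y = cohort.outcomes
    reps = np.empty((len(pick), len(cohort), 3), dtype=np.int8)
    for i, flat in enumerate(pick):
        c, r = divmod(int(flat), samples.n_retained)
        st = _state_from_draw(samples, c, r, na, p)
        pmat = expit(linear_predictor_matrix(st, spec, x, area_idx))
        reps[i] = rng.random(pmat.shape) < pmat
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    covered = (y >= lo) & (y <= hi)
    return float(covered.mean())


def _interval_summary(draws: np.ndarray) -> tuple[float, float, float, bool]:
    """Median, central 95 % interval and the exclusion-of-unity flag for
    odds-ratio draws.  An interval touching 1 exactly counts as including
    unity (flag False)."""
    med = float(np.median(draws))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return med, float(lo), float(hi), bool(lo > 1.0 or hi < 1.0)


def summarize_effects(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior odds-ratio table for every regression coefficient.

    Odds ratios are exp(coefficient) draw-wise; ``substantive`` is True iff
    the 95 % credible interval excludes unity.
    """
    beta = samples.stacked("beta")  # (m, p, 3)
    rows = []
    for j, name in enumerate(samples.design_columns):
        for k, treat in enumerate(TREATMENTS):
            med, lo, hi, flag = _interval_summary(np.exp(beta[:, j, k]))
            rows.append(
                {
                    "coefficient": name,
                    "treatment": treat,
                    "or_median": med,
                    "cri_low": lo,
                    "cri_high": hi,
                    "substantive": flag,
                }
            )
    return pd.DataFrame(rows)


_RATIO_PAIRS = ((1, 0), (2, 0), (2, 1))


def relative_weights(samples: PosteriorSamples) -> pd.DataFrame:
    """Pairwise ratios of the shared-component weights (draw-wise), e.g.
    delta_chemotherapy / delta_radiotherapy, with median, 95 % CrI and the
    exclusion-of-unity flag."""
    if "log_delta" not in samples.draws:
        raise ValueError("model variant has no shared component")
    ld = samples.stacked("log_delta")  # (m, 3)
    rows = []
    for num, den in _RATIO_PAIRS:
        ratio = np.exp(ld[:, num] - ld[:, den])
        med, lo, hi, flag = _interval_summary(ratio)
        rows.append(
            {
                "ratio": f"delta_{TREATMENTS[num]}/delta_{TREATMENTS[den]}",
                "median": med,
                "cri_low": lo,
                "cri_high": hi,
                "substantive": flag,
            }
        )
    return pd.DataFrame(rows)
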