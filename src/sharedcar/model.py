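"""Likelihood, priors and constraints of the shared spatial-component model.

Three binary outcomes per individual are modelled jointly:

    y_jk ~ Bernoulli(p_jk),
    logit(p_jk) = alpha_k + beta_k' x_j + u_{i(j),k} + eta_{i(j),k},
    eta_{ik}    = delta_k * phi_i + s_{ik},

with phi an intrinsic-CAR shared field over areas, s_k per-outcome CAR
fields, u_i trivariate unstructured effects with a Wishart-prior precision,
and positive weights delta constrained to product 1.  Variant flags (A0-A7)
switch individual blocks on/off or swap their priors; see ``ModelSpec``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import log_expit
from scipy.stats import gamma as gamma_dist
from scipy.stats import wishart as wishart_dist

from .spatial_graph import AreaGraph, car_log_density, center_sum_to_zero

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import CohortTable, CovariateSchema

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparameters",
    "ModelSpec",
    "ParameterState",
    "VARIANTS",
    "design_matrix",
    "linear_predictor",
    "linear_predictor_matrix",
    "log_likelihood",
    "log_prior",
    "apply_constraints",
]

VARIANTS = ("A0", "A1", "A2", "A3", "A4", "A5", "A6", "A7")

_PAIRS = {
    "A2": ("radiotherapy", "chemotherapy"),
    "A3": ("radiotherapy", "hormonal"),
    "A4": ("chemotherapy", "hormonal"),
}
_TREATMENT_INDEX = {"radiotherapy": 0, "chemotherapy": 1, "hormonal": 2}


@dataclass(frozen=True)
class Hyperparameters:
    """Shape/rate pairs and scale matrices of every prior in the model.

    Gamma distributions are parameterised by shape and rate (inverse scale)
    throughout: fixed-effect precisions get Gamma(0.005, 0.5), CAR precisions
    Gamma(0.5, 0.005).  The Wishart on the u-precision has identity scale and
    5 degrees of freedom; free log-weights are Gaussian with precision 5.9.
    The flat fixed-effect alternative uses a constant precision of 1e-4.
    """

    fe_shape: float = 0.005
    fe_rate: float = 0.5
    car_shape: float = 0.5
    car_rate: float = 0.005
    u_indep_shape: float = 0.5
    u_indep_rate: float = 0.005
    wishart_df: float = 5.0
    wishart_scale: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    logdelta_prec: float = 5.9
    flat_prec: float = 1e-4

    def wishart_scale_matrix(self) -> np.ndarray:
        return np.asarray(self.wishart_scale, dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """Variant flag plus hyperparameters; fully determines likelihood and priors."""

    variant: str = "A0"
    include_u: bool = True
    u_prior: str = "multivariate"  # or "independent"
    include_s: bool = True
    include_shared: bool = True
    second_shared_pair: tuple[str, str] | None = None
    fixed_effect_prior: str = "hierarchical"  # or "flat"
    hyper: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self):
        if self.u_prior not in ("multivariate", "independent"):
            raise ValueError(f"unknown u_prior {self.u_prior!r}")
        if self.fixed_effect_prior not in ("hierarchical", "flat"):
            raise ValueError(f"unknown fixed_effect_prior {self.fixed_effect_prior!r}")
        if self.second_shared_pair is not None:
            pair = tuple(self.second_shared_pair)
            if len(pair) != 2 or any(t not in _TREATMENT_INDEX for t in pair):
                raise ValueError(f"invalid second_shared_pair {pair}")
            object.__setattr__(self, "second_shared_pair", pair)

    @classmethod
    def from_variant(cls, variant: str, hyper: Hyperparameters | None = None) -> "ModelSpec":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        hyper = hyper or Hyperparameters()
        return cls(
            variant=variant,
            include_u=variant != "A5",
            u_prior="independent" if variant == "A1" else "multivariate",
            include_s=variant != "A6",
            include_shared=True,
            second_shared_pair=_PAIRS.get(variant),
            fixed_effect_prior="flat" if variant == "A7" else "hierarchical",
            hyper=hyper,
        )

    @property
    def pair_indices(self) -> tuple[int, int] | None:
        if self.second_shared_pair is None:
            return None
        a, b = self.second_shared_pair
        return _TREATMENT_INDEX[a], _TREATMENT_INDEX[b]

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "include_u": self.include_u,
            "u_prior": self.u_prior,
            "include_s": self.include_s,
            "include_shared": self.include_shared,
            "second_shared_pair": list(self.second_shared_pair)
            if self.second_shared_pair
            else None,
            "fixed_effect_prior": self.fixed_effect_prior,
            "hyper": {
                k: (list(map(list, v)) if k == "wishart_scale" else v)
                for k, v in self.hyper.__dict__.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        hyper = d.pop("hyper", None)
        if hyper is not None:
            hyper = dict(hyper)
            if "wishart_scale" in hyper:
                hyper["wishart_scale"] = tuple(map(tuple, hyper["wishart_scale"]))
            hyper = Hyperparameters(**hyper)
        else:
            hyper = Hyperparameters()
        pair = d.pop("second_shared_pair", None)
        return cls(**d, second_shared_pair=tuple(pair) if pair else None, hyper=hyper)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def design_matrix(
    cohort,
    schema: "CovariateSchema",
    drop: tuple[str, ...] = (),
    drop_empty: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix (reference levels omitted).

    ``cohort`` may be a CohortTable or a bare DataFrame with the covariate
    columns.  By default, categories absent from the (sub-)cohort are dropped
    from the design with a warning rather than carried as inestimable
    columns; ``drop_empty=False`` keeps the full schema coding (used by the
    generator, where the coefficient matrix is fixed a priori).
    """
    df = getattr(cohort, "df", cohort)
    cols: list[str] = []
    mats: list[np.ndarray] = []
    for cov in schema:
        if cov.name in drop:
            continue
        values = df[cov.name].to_numpy()
        unknown = set(np.unique(values)) - set(cov.labels)
        if unknown:
            raise ValueError(f"{cov.name}: unknown categories {sorted(unknown)}")
        for lab in cov.labels:
            if lab == cov.reference:
                continue
            col = (values == lab).astype(float)
            if drop_empty and col.sum() == 0:
                logger.warning(
                    "dropping empty design column %s=%s (category absent from cohort)",
                    cov.name,
                    lab,
                )
                continue
            cols.append(f"{cov.name}={lab}")
            mats.append(col)
    x = np.column_stack(mats) if mats else np.empty((len(df), 0))
    return x, cols


@dataclass
class ParameterState:
    """One full set of model parameters.

    Blocks absent under a variant are kept as zero arrays so the linear
    predictor is always well defined.  ``log_delta`` has three entries
    summing to zero (product-1 constraint on the weights); ``log_delta2``
    has two, for the designated pair.
    """

    alpha: np.ndarray
    beta: np.ndarray  # (p, 3)
    u: np.ndarray  # (n_areas, 3)
    s: np.ndarray  # (n_areas, 3)
    phi: np.ndarray  # (n_areas,)
    log_delta: np.ndarray  # (3,)
    tau_phi: float = 1.0
    tau_s: np.ndarray = field(default_factory=lambda: np.ones(3))
    tau_alpha: float = 1.0
    tau_beta: np.ndarray = field(default_factory=lambda: np.ones(3))
    sigma_u_prec: np.ndarray = field(default_factory=lambda: np.eye(3))
    tau_u: np.ndarray = field(default_factory=lambda: np.ones(3))  # A1 only
    phi2: np.ndarray | None = None
    log_delta2: np.ndarray | None = None
    tau_phi2: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "u", "s", "phi", "log_delta", "tau_s", "tau_beta",
                     "sigma_u_prec", "tau_u"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.phi2 is not None:
            self.phi2 = np.asarray(self.phi2, dtype=float)
        if self.log_delta2 is not None:
            self.log_delta2 = np.asarray(self.log_delta2, dtype=float)

    @property
    def delta(self) -> np.ndarray:
        return np.exp(self.log_delta)

    @classmethod
    def zeros(cls, n_areas: int, p: int, spec: ModelSpec | None = None) -> "ParameterState":
        st = cls(
            alpha=np.zeros(3),
            beta=np.zeros((p, 3)),
            u=np.zeros((n_areas, 3)),
            s=np.zeros((n_areas, 3)),
            phi=np.zeros(n_areas),
            log_delta=np.zeros(3),
        )
        if spec is not None and spec.second_shared_pair is not None:
            st.phi2 = np.zeros(n_areas)
            st.log_delta2 = np.zeros(2)
        return st

    def copy(self) -> "ParameterState":
        return replace(
            self,
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            u=self.u.copy(),
            s=self.s.copy(),
            phi=self.phi.copy(),
            log_delta=self.log_delta.copy(),
            tau_s=self.tau_s.copy(),
            tau_beta=self.tau_beta.copy(),
            sigma_u_prec=self.sigma_u_prec.copy(),
            tau_u=self.tau_u.copy(),
            phi2=None if self.phi2 is None else self.phi2.copy(),
            log_delta2=None if self.log_delta2 is None else self.log_delta2.copy(),
        )


def _second_shared_term(state: ParameterState, spec: ModelSpec, area_idx) -> np.ndarray:
    """(n, 3) contribution of the second shared component (zero elsewhere)."""
    pair = spec.pair_indices
    out = np.zeros((np.size(area_idx), 3))
    if pair is None or state.phi2 is None:
        return out
    d2 = np.exp(state.log_delta2)
    out[:, pair[0]] = d2[0] * state.phi2[area_idx]
    out[:, pair[1]] = d2[1] * state.phi2[area_idx]
    return out


def linear_predictor_matrix(
    state: ParameterState, spec: ModelSpec, x: np.ndarray, area_idx: np.ndarray
) -> np.ndarray:
    """Logits for every individual and treatment, shape (n, 3)."""
    if x.shape[1] != state.beta.shape[0]:
        raise ValueError(
            f"design has {x.shape[1]} columns but beta has {state.beta.shape[0]} rows"
        )
    psi = state.alpha + x @ state.beta
    if spec.include_u:
        psi = psi + state.u[area_idx]
    if spec.include_shared:
        psi = psi + np.outer(state.phi[area_idx], state.delta)
    if spec.include_s:
        psi = psi + state.s[area_idx]
    if spec.second_shared_pair is not None:
        psi = psi + _second_shared_term(state, spec, area_idx)
    return psi


def linear_predictor(
    state: ParameterState, spec: ModelSpec, x: np.ndarray, area: int, k: int
) -> float:
    """Logit for one individual (covariate row ``x``, area index, treatment k in 0..2)."""
    if not 0 <= k <= 2:
        raise ValueError("treatment index must be in 0..2")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    psi = linear_predictor_matrix(state, spec, x, np.asarray([area]))
    return float(psi[0, k])


def log_likelihood(
    state: ParameterState,
    spec: ModelSpec,
    cohort: "CohortTable",
    graph: AreaGraph,
    schema: "CovariateSchema | None" = None,
    drop: tuple[str, ...] = (),
    design: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Bernoulli log-likelihood summed over individuals and treatments.

    ``design`` may carry a precomputed ``(x, area_idx)`` pair to avoid
    rebuilding the dummy coding in tight loops.
    """
    if len(cohort) == 0:
        return 0.0
    if design is not None:
        x, area_idx = design
    else:
        from .synthetic import default_schema

        x, _ = design_matrix(cohort, schema or default_schema(), drop=drop)
        area_idx = cohort.area_index(graph)
    y = cohort.outcomes
    psi = linear_predictor_matrix(state, spec, x, area_idx)
    return float(np.sum(y * psi + log_expit(-psi)))


def _gamma_lpdf(x, shape, rate) -> float:
    return float(gamma_dist.logpdf(x, a=shape, scale=1.0 / rate))


def _normal_lpdf_sum(x, prec) -> float:
    x = np.asarray(x, dtype=float)
    return float(0.5 * x.size * (np.log(prec) - np.log(2 * np.pi)) - 0.5 * prec * np.sum(x * x))


def log_prior(state: ParameterState, spec: ModelSpec, graph: AreaGraph) -> float:
    """Sum of all prior log-densities active under the variant."""
    h = spec.hyper
    lp = 0.0

    # fixed effects
    if spec.fixed_effect_prior == "hierarchical":
        lp += _gamma_lpdf(state.tau_alpha, h.fe_shape, h.fe_rate)
        lp += _normal_lpdf_sum(state.alpha, state.tau_alpha)
        for k in range(3):
            lp += _gamma_lpdf(state.tau_beta[k], h.fe_shape, h.fe_rate)
            lp += _normal_lpdf_sum(state.beta[:, k], state.tau_beta[k])
    else:
        lp += _normal_lpdf_sum(state.alpha, h.flat_prec)
        lp += _normal_lpdf_sum(state.beta, h.flat_prec)

    # unstructured effects
    if spec.include_u:
        if spec.u_prior == "multivariate":
            prec = state.sigma_u_prec
            sign, logdet = np.linalg.slogdet(prec)
            if sign <= 0:
                raise ValueError("sigma_u_prec must be positive definite")
            lp += float(
                wishart_dist.logpdf(prec, df=h.wishart_df, scale=h.wishart_scale_matrix())
            )
            na = state.u.shape[0]
            quad = float(np.einsum("ij,jk,ik->", state.u, prec, state.u))
            lp += 0.5 * na * (logdet - 3 * np.log(2 * np.pi)) - 0.5 * quad
        else:
            for k in range(3):
                lp += _gamma_lpdf(state.tau_u[k], h.u_indep_shape, h.u_indep_rate)
                lp += _normal_lpdf_sum(state.u[:, k], state.tau_u[k])

    # shared component(s) and weights
    if spec.include_shared:
        lp += _gamma_lpdf(state.tau_phi, h.car_shape, h.car_rate)
        lp += car_log_density(state.phi, state.tau_phi, graph)
        lp += _normal_lpdf_sum(state.log_delta[:2], h.logdelta_prec)
    if spec.second_shared_pair is not None:
        if state.phi2 is None or state.log_delta2 is None:
            raise ValueError("variant has a second shared component but state lacks phi2")
        lp += _gamma_lpdf(state.tau_phi2, h.car_shape, h.car_rate)
        lp += car_log_density(state.phi2, state.tau_phi2, graph)
        lp += _normal_lpdf_sum(state.log_delta2[:1], h.logdelta_prec)

    # treatment-specific structured effects
    if spec.include_s:
        for k in range(3):
            lp += _gamma_lpdf(state.tau_s[k], h.car_shape, h.car_rate)
            lp += car_log_density(state.s[:, k], state.tau_s[k], graph)
    return lp


def apply_constraints(state: ParameterState, graph: AreaGraph) -> ParameterState:
    """Centre phi/s per connected component and zero-sum the log-weights.

    Idempotent; returns a new state.
    """
    out = state.copy()
    out.phi = center_sum_to_zero(out.phi, graph)
    for k in range(3):
        out.s[:, k] = center_sum_to_zero(out.s[:, k], graph)
    out.log_delta = out.log_delta - out.log_delta.mean()
    if out.phi2 is not None:
        out.phi2 = center_sum_to_zero(out.phi2, graph)
    if out.log_delta2 is not None:
        out.log_delta2 = out.log_delta2 - out.log_delta2.mean()
    return out
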