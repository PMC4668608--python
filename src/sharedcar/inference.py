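"""Posterior sampling for the shared spatial-component model.

The sampler is a Pólya–Gamma-augmented Gibbs scheme: conditional on the
augmentation variables the Bernoulli logistic likelihood is Gaussian in every
location block, so fixed effects, unstructured effects, the CAR fields and
all precisions have closed-form full conditionals.  The free log-weights of
the shared component(s) get a small adaptive random-walk Metropolis step
against their (PG-conditionally Gaussian-in-delta) target.  CAR fields are
drawn exactly under the per-component sum-to-zero constraints by
conditioning-by-kriging, so every retained state satisfies the constraints to
machine precision.

All randomness flows from a single master seed: ``SeedSequence(seed)`` is
spawned once per chain, and each chain owns one ``numpy.random.Generator``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import log_expit
from scipy.stats import wishart as wishart_dist

from .model import ModelSpec, ParameterState, apply_constraints, design_matrix
from .polyagamma import sample_pg
from .spatial_graph import AreaGraph
from .synthetic import CohortTable, CovariateSchema, default_schema

__all__ = ["McmcSettings", "default_settings", "PosteriorSamples", "run_mcmc"]


@dataclass(frozen=True)
class McmcSettings:
    """Chain schedule.  Retained draws per chain = floor((n_iterations -
    burn_in) / thin); totals are pooled over chains (e.g. 2 chains of 17,500
    iterations with 10,000 burn-in and thinning 3 retain 2,500 per chain,
    5,000 pooled)."""

    n_chains: int = 2
    n_iterations: int = 17_500
    burn_in: int = 10_000
    thin: int = 3
    seed: int = 0
    mh_step: float = 0.25
    mh_target_accept: float = 0.4

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain


def default_settings(sub_cohort: bool = False, seed: int = 0) -> McmcSettings:
    """Published chain schedules: full-cohort (2 chains, 17,500 iterations,
    10,000 burn-in, thin 3) or sub-cohort (2, 37,500, 30,000, 3)."""
    if sub_cohort:
        return McmcSettings(n_chains=2, n_iterations=37_500, burn_in=30_000, thin=3, seed=seed)
    return McmcSettings(n_chains=2, n_iterations=17_500, burn_in=10_000, thin=3, seed=seed)


@dataclass
class PosteriorSamples:
    """Retained draws per chain: ``draws[name]`` has shape
    ``(n_chains, n_retained, *param_shape)``."""

    draws: dict[str, np.ndarray]
    spec: ModelSpec
    settings: McmcSettings
    seed: int
    design_columns: list[str]
    area_ids: list[str]
    deviance: np.ndarray | None = None  # (n_chains, n_retained)
    psi_mean: np.ndarray | None = None  # (n, 3) posterior-mean linear predictor

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains: (n_chains * n_retained, *shape)."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_retained(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def to_dir(self, path) -> None:
        """Persist as per-parameter CSV (chain, draw, components) + manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in self.draws.items():
            c, m = arr.shape[:2]
            flat = arr.reshape(c * m, -1)
            df = pd.DataFrame(flat, columns=[f"v{i}" for i in range(flat.shape[1])])
            df.insert(0, "draw", np.tile(np.arange(m), c))
            df.insert(0, "chain", np.repeat(np.arange(c), m))
            df.to_csv(path / f"{name}.csv", index=False, lineterminator="\n")
        manifest = {
            "spec": self.spec.to_dict(),
            "settings": self.settings.__dict__,
            "seed": self.seed,
            "design_columns": self.design_columns,
            "area_ids": self.area_ids,
            "shapes": {k: list(v.shape[2:]) for k, v in self.draws.items()},
        }
        if self.deviance is not None:
            np.savetxt(path / "deviance.txt", self.deviance.reshape(-1))
        if self.psi_mean is not None:
            np.savetxt(path / "psi_mean.txt", self.psi_mean)
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def from_dir(cls, path) -> "PosteriorSamples":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        settings = McmcSettings(**manifest["settings"])
        spec = ModelSpec.from_dict(manifest["spec"])
        draws = {}
        for name, shape in manifest["shapes"].items():
            df = pd.read_csv(path / f"{name}.csv")
            c = int(df["chain"].max()) + 1
            m = int(df["draw"].max()) + 1
            vals = df.drop(columns=["chain", "draw"]).to_numpy()
            draws[name] = vals.reshape(c, m, *shape)
        dev = None
        if (path / "deviance.txt").exists():
            dev = np.loadtxt(path / "deviance.txt").reshape(
                next(iter(draws.values())).shape[:2]
            )
        psi_mean = None
        if (path / "psi_mean.txt").exists():
            psi_mean = np.loadtxt(path / "psi_mean.txt")
            if psi_mean.ndim == 1:
                psi_mean = psi_mean.reshape(-1, 3)
        return cls(
            draws=draws,
            spec=spec,
            settings=settings,
            seed=manifest["seed"],
            design_columns=manifest["design_columns"],
            area_ids=manifest["area_ids"],
            deviance=dev,
            psi_mean=psi_mean,
        )


# --------------------------------------------------------------------------
# constrained Gaussian sampling


def _constrained_gaussian(Q: np.ndarray, r: np.ndarray, C: np.ndarray, rng) -> np.ndarray:
    """Exact draw from N(mean, Q^-1) with canonical parameters (Q, r),
    conditioned on the hard constraints C x = 0 (conditioning by kriging).

    Q need only be positive definite on the null space of C (the intrinsic
    CAR case); a rank-correction along the constraint directions makes the
    factorisation well posed without affecting the constrained law.
    """
    n = Q.shape[0]
    scale = max(np.mean(np.diag(Q)), 1e-8)
    sizes = C.sum(axis=1)
    A = Q + scale * (C.T * (1.0 / sizes)) @ C
    chol = cho_factor(A, lower=True)
    mean = cho_solve(chol, r)
    z = rng.standard_normal(n)
    noise = solve_triangular(chol[0], z, lower=True, trans="T")
    x = mean + noise
    AinvCt = cho_solve(chol, C.T)
    w = np.linalg.solve(C @ AinvCt, C @ x)
    return x - AinvCt @ w


# --------------------------------------------------------------------------
# the sampler


def _init_state(
    spec: ModelSpec, graph: AreaGraph, p: int, rng: np.random.Generator, spread: float
) -> ParameterState:
    """Over-dispersed initial state: location parameters from inflated
    Gaussians (chain-specific spread), precisions at moderate values."""
    na = graph.n_areas
    st = ParameterState.zeros(na, p, spec)
    st.alpha = rng.normal(0.0, 0.5 * spread, size=3)
    st.beta = rng.normal(0.0, 0.25 * spread, size=(p, 3))
    if spec.include_u:
        st.u = rng.normal(0.0, 0.1 * spread, size=(na, 3))
    if spec.include_shared:
        st.phi = rng.normal(0.0, 0.2 * spread, size=na)
        st.log_delta = rng.normal(0.0, 0.2 * spread, size=3)
    if spec.include_s:
        st.s = rng.normal(0.0, 0.1 * spread, size=(na, 3))
    if spec.second_shared_pair is not None:
        st.phi2 = rng.normal(0.0, 0.1 * spread, size=na)
        st.log_delta2 = rng.normal(0.0, 0.2 * spread, size=2)
    st.tau_phi = st.tau_phi2 = 10.0
    st.tau_s = np.full(3, 10.0)
    st.tau_u = np.full(3, 10.0)
    st.sigma_u_prec = np.eye(3) * 10.0
    st.tau_alpha = 1.0
    st.tau_beta = np.ones(3)
    return apply_constraints(st, graph)


def _aggregate(area_idx: np.ndarray, vals: np.ndarray, na: int) -> np.ndarray:
    """Column-wise per-area sums of an (n, 3) array."""
    return np.column_stack(
        [np.bincount(area_idx, weights=vals[:, k], minlength=na) for k in range(3)]
    )


def run_mcmc(
    spec: ModelSpec,
    cohort: CohortTable,
    graph: AreaGraph,
    settings: McmcSettings,
    schema: CovariateSchema | None = None,
    drop: tuple[str, ...] = (),
) -> PosteriorSamples:
    """Sample the posterior of ``spec`` given the cohort and areal graph.

    Identical seed gives identical output.  Constraints (product-1 weights,
    per-component sum-to-zero CAR fields) hold for every retained draw.
    """
    schema = schema or default_schema()
    x, colnames = design_matrix(cohort, schema, drop=drop)
    area_idx = cohort.area_index(graph)
    y = cohort.outcomes.astype(float)
    n, p = x.shape
    na = graph.n_areas
    kappa = y - 0.5
    D = np.column_stack([np.ones(n), x])  # intercept + covariates

    L = graph.laplacian().toarray()
    C = graph.component_indicator()
    pair = spec.pair_indices
    h = spec.hyper

    master = np.random.SeedSequence(settings.seed)
    chain_seeds = master.spawn(settings.n_chains)

    m = settings.retained_per_chain
    names = _param_names(spec, p, na)
    draws = {nm: np.empty((settings.n_chains, m) + shape) for nm, shape in names.items()}
    deviance = np.empty((settings.n_chains, m))
    psi_sum = np.zeros((n, 3))

    for c in range(settings.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        st = _init_state(spec, graph, p, rng, spread=1.0 + 0.75 * c)
        if not np.isfinite(_deviance(st, spec, x, area_idx, y)):
            raise FloatingPointError("non-finite posterior at initialisation")
        mh_logstep = np.log(settings.mh_step)
        mh_logstep2 = np.log(settings.mh_step)
        rec = 0

        for it in range(1, settings.n_iterations + 1):
            adapting = it <= settings.burn_in

            fe = st.alpha + D[:, 1:] @ st.beta
            upart = st.u[area_idx] if spec.include_u else np.zeros((n, 3))
            shpart = (
                np.outer(st.phi[area_idx], st.delta)
                if spec.include_shared
                else np.zeros((n, 3))
            )
            spart = st.s[area_idx] if spec.include_s else np.zeros((n, 3))
            if pair is not None:
                d2 = np.exp(st.log_delta2)
                sh2 = np.zeros((n, 3))
                sh2[:, pair[0]] = d2[0] * st.phi2[area_idx]
                sh2[:, pair[1]] = d2[1] * st.phi2[area_idx]
            else:
                sh2 = np.zeros((n, 3))
            psi = fe + upart + shpart + spart + sh2

            omega = sample_pg(psi, rng) if n else np.zeros((n, 3))

            # --- fixed effects (intercept + coefficients), per treatment
            for k in range(3):
                offset = psi[:, k] - fe[:, k]
                if spec.fixed_effect_prior == "hierarchical":
                    prior = np.concatenate([[st.tau_alpha], np.full(p, st.tau_beta[k])])
                else:
                    prior = np.full(p + 1, h.flat_prec)
                A = (D * omega[:, k : k + 1]).T @ D if n else np.zeros((p + 1, p + 1))
                A[np.diag_indices_from(A)] += prior
                b = D.T @ (kappa[:, k] - omega[:, k] * offset) if n else np.zeros(p + 1)
                chol = cho_factor(A, lower=True)
                coef = cho_solve(chol, b) + solve_triangular(
                    chol[0], rng.standard_normal(p + 1), lower=True, trans="T"
                )
                st.alpha[k] = coef[0]
                st.beta[:, k] = coef[1:]
            fe = st.alpha + D[:, 1:] @ st.beta
            psi = fe + upart + shpart + spart + sh2

            # --- unstructured effects u
            if spec.include_u:
                rest = psi - upart
                W = _aggregate(area_idx, omega, na)
                R = _aggregate(area_idx, kappa - omega * rest, na)
                if spec.u_prior == "multivariate":
                    P = np.broadcast_to(st.sigma_u_prec, (na, 3, 3)).copy()
                    P[:, np.arange(3), np.arange(3)] += W
                    Lc = np.linalg.cholesky(P)
                    meanv = np.linalg.solve(P, R[..., None])[..., 0]
                    z = rng.standard_normal((na, 3))
                    noise = np.linalg.solve(np.swapaxes(Lc, 1, 2), z[..., None])[..., 0]
                    st.u = meanv + noise
                else:
                    prec = W + st.tau_u
                    st.u = R / prec + rng.standard_normal((na, 3)) / np.sqrt(prec)
                upart = st.u[area_idx]
                psi = rest + upart

            # --- shared field phi
            if spec.include_shared:
                rest = psi - shpart
                W = _aggregate(area_idx, omega, na)
                R = _aggregate(area_idx, kappa - omega * rest, na)
                d = st.delta
                Q = st.tau_phi * L + np.diag(W @ (d * d))
                st.phi = _constrained_gaussian(Q, R @ d, C, rng)
                shpart = np.outer(st.phi[area_idx], d)
                psi = rest + shpart

                # --- weights delta via random-walk MH on the two free logs
                phi_a = st.phi[area_idx]
                Aq = (omega * phi_a[:, None] ** 2).sum(axis=0)
                Bq = ((kappa - omega * rest) * phi_a[:, None]).sum(axis=0)

                def _target(l2free):
                    ld = np.array([l2free[0], l2free[1], -l2free[0] - l2free[1]])
                    dd = np.exp(ld)
                    return float(
                        (Bq * dd).sum()
                        - 0.5 * (Aq * dd * dd).sum()
                        - 0.5 * h.logdelta_prec * (l2free**2).sum()
                    )

                cur = st.log_delta[:2].copy()
                prop = cur + np.exp(mh_logstep) * rng.standard_normal(2)
                log_acc = _target(prop) - _target(cur)
                accepted = np.log(rng.random()) < log_acc
                if accepted:
                    cur = prop
                if adapting:
                    mh_logstep += (
                        (1.0 if accepted else 0.0) - settings.mh_target_accept
                    ) / max(it, 10) ** 0.6
                st.log_delta = np.array([cur[0], cur[1], -cur[0] - cur[1]])
                shpart = np.outer(st.phi[area_idx], st.delta)
                psi = rest + shpart

            # --- second shared component
            if pair is not None:
                rest = psi - sh2
                W = _aggregate(area_idx, omega, na)
                R = _aggregate(area_idx, kappa - omega * rest, na)
                d2 = np.exp(st.log_delta2)
                bdiag = d2[0] ** 2 * W[:, pair[0]] + d2[1] ** 2 * W[:, pair[1]]
                rhs = d2[0] * R[:, pair[0]] + d2[1] * R[:, pair[1]]
                Q = st.tau_phi2 * L + np.diag(bdiag)
                st.phi2 = _constrained_gaussian(Q, rhs, C, rng)

                phi2_a = st.phi2[area_idx]
                Aq2 = (omega[:, list(pair)] * phi2_a[:, None] ** 2).sum(axis=0)
                Bq2 = (
                    (kappa[:, list(pair)] - omega[:, list(pair)] * rest[:, list(pair)])
                    * phi2_a[:, None]
                ).sum(axis=0)

                def _target2(lfree):
                    dd = np.exp(np.array([lfree, -lfree]))
                    return float(
                        (Bq2 * dd).sum()
                        - 0.5 * (Aq2 * dd * dd).sum()
                        - 0.5 * h.logdelta_prec * lfree**2
                    )

                cur2 = float(st.log_delta2[0])
                prop2 = cur2 + np.exp(mh_logstep2) * rng.standard_normal()
                accepted2 = np.log(rng.random()) < _target2(prop2) - _target2(cur2)
                if accepted2:
                    cur2 = prop2
                if adapting:
                    mh_logstep2 += (
                        (1.0 if accepted2 else 0.0) - settings.mh_target_accept
                    ) / max(it, 10) ** 0.6
                st.log_delta2 = np.array([cur2, -cur2])
                d2 = np.exp(st.log_delta2)
                sh2 = np.zeros((n, 3))
                sh2[:, pair[0]] = d2[0] * st.phi2[area_idx]
                sh2[:, pair[1]] = d2[1] * st.phi2[area_idx]
                psi = rest + sh2

            # --- treatment-specific fields s
            if spec.include_s:
                rest = psi - spart
                W = _aggregate(area_idx, omega, na)
                R = _aggregate(area_idx, kappa - omega * rest, na)
                for k in range(3):
                    Q = st.tau_s[k] * L + np.diag(W[:, k])
                    st.s[:, k] = _constrained_gaussian(Q, R[:, k], C, rng)
                spart = st.s[area_idx]
                psi = rest + spart

            # --- precisions (conjugate)
            rank = graph.rank
            if spec.include_shared:
                st.tau_phi = rng.gamma(
                    h.car_shape + 0.5 * rank,
                    1.0 / (h.car_rate + 0.5 * st.phi @ L @ st.phi),
                )
            if pair is not None:
                st.tau_phi2 = rng.gamma(
                    h.car_shape + 0.5 * rank,
                    1.0 / (h.car_rate + 0.5 * st.phi2 @ L @ st.phi2),
                )
            if spec.include_s:
                for k in range(3):
                    st.tau_s[k] = rng.gamma(
                        h.car_shape + 0.5 * rank,
                        1.0 / (h.car_rate + 0.5 * st.s[:, k] @ L @ st.s[:, k]),
                    )
            if spec.include_u:
                if spec.u_prior == "multivariate":
                    scale_inv = np.linalg.inv(h.wishart_scale_matrix()) + st.u.T @ st.u
                    st.sigma_u_prec = wishart_dist.rvs(
                        df=h.wishart_df + na, scale=np.linalg.inv(scale_inv), random_state=rng
                    )
                else:
                    for k in range(3):
                        st.tau_u[k] = rng.gamma(
                            h.u_indep_shape + 0.5 * na,
                            1.0 / (h.u_indep_rate + 0.5 * st.u[:, k] @ st.u[:, k]),
                        )
            if spec.fixed_effect_prior == "hierarchical":
                st.tau_alpha = rng.gamma(
                    h.fe_shape + 1.5, 1.0 / (h.fe_rate + 0.5 * st.alpha @ st.alpha)
                )
                for k in range(3):
                    st.tau_beta[k] = rng.gamma(
                        h.fe_shape + 0.5 * p,
                        1.0 / (h.fe_rate + 0.5 * st.beta[:, k] @ st.beta[:, k]),
                    )

            # numerical safety net; draws already satisfy the constraints
            st = apply_constraints(st, graph)

            if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                _record(draws, st, spec, c, rec)
                psi_now = _assemble_psi(st, spec, x, area_idx)
                deviance[c, rec] = -2.0 * float(np.sum(y * psi_now + log_expit(-psi_now)))
                psi_sum += psi_now
                rec += 1

    total = settings.retained_total
    return PosteriorSamples(
        draws=draws,
        spec=spec,
        settings=settings,
        seed=settings.seed,
        design_columns=colnames,
        area_ids=list(graph.area_ids),
        deviance=deviance,
        psi_mean=psi_sum / total if total else None,
    )


def _param_names(spec: ModelSpec, p: int, na: int) -> dict[str, tuple]:
    names = {
        "alpha": (3,),
        "beta": (p, 3),
        "tau_alpha": (),
        "tau_beta": (3,),
    }
    if spec.include_u:
        names["u"] = (na, 3)
        if spec.u_prior == "multivariate":
            names["sigma_u_prec"] = (3, 3)
        else:
            names["tau_u"] = (3,)
    if spec.include_shared:
        names.update({"phi": (na,), "log_delta": (3,), "tau_phi": ()})
    if spec.include_s:
        names.update({"s": (na, 3), "tau_s": (3,)})
    if spec.second_shared_pair is not None:
        names.update({"phi2": (na,), "log_delta2": (2,), "tau_phi2": ()})
    return names


def _record(draws, st: ParameterState, spec: ModelSpec, c: int, r: int) -> None:
    for nm in draws:
        draws[nm][c, r] = getattr(st, nm)


def _assemble_psi(st: ParameterState, spec: ModelSpec, x, area_idx) -> np.ndarray:
    from .model import linear_predictor_matrix

    return linear_predictor_matrix(st, spec, x, area_idx)


def _deviance(st: ParameterState, spec: ModelSpec, x, area_idx, y) -> float:
    psi = _assemble_psi(st, spec, x, area_idx)
    return -2.0 * float(np.sum(y * psi + log_expit(-psi)))
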