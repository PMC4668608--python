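"""Likelihood, priors, variants and constraint projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import bernoulli

from sharedcar.model import (
    Hyperparameters,
    ModelSpec,
    ParameterState,
    apply_constraints,
    design_matrix,
    linear_predictor,
    linear_predictor_matrix,
    log_likelihood,
    log_prior,
)
from sharedcar.spatial_graph import car_log_density, grid_graph
from sharedcar.synthetic import TruthConfig, default_schema, generate_cohort

from conftest import make_cohort


@pytest.fixture(scope="module")
def schema():
    return default_schema()


@pytest.fixture(scope="module")
def small_fit_inputs(schema):
    g = grid_graph(4, 4)
    truth = TruthConfig.default(g, schema, n_individuals=60, seed=1)
    cohort, _ = generate_cohort(truth, schema, g)
    return g, cohort


def _random_state(rng, n_areas, p, spec=None):
    st_ = ParameterState.zeros(n_areas, p, spec)
    st_.alpha = rng.standard_normal(3)
    st_.beta = rng.standard_normal((p, 3))
    st_.u = rng.standard_normal((n_areas, 3)) * 0.5
    st_.s = rng.standard_normal((n_areas, 3)) * 0.5
    st_.phi = rng.standard_normal(n_areas) * 0.5
    st_.log_delta = rng.standard_normal(3) * 0.3
    if st_.phi2 is not None:
        st_.phi2 = rng.standard_normal(n_areas) * 0.3
        st_.log_delta2 = rng.standard_normal(2) * 0.3
    return st_


class TestModelSpecVariants:
    def test_baseline_flags(self):
        s = ModelSpec.from_variant("A0")
        assert s.include_u and s.include_s and s.include_shared
        assert s.u_prior == "multivariate"
        assert s.second_shared_pair is None
        assert s.fixed_effect_prior == "hierarchical"

    @pytest.mark.parametrize(
        "variant,attr,value",
        [
            ("A1", "u_prior", "independent"),
            ("A2", "second_shared_pair", ("radiotherapy", "chemotherapy")),
            ("A3", "second_shared_pair", ("radiotherapy", "hormonal")),
            ("A4", "second_shared_pair", ("chemotherapy", "hormonal")),
            ("A5", "include_u", False),
            ("A6", "include_s", False),
            ("A7", "fixed_effect_prior", "flat"),
        ],
    )
    def test_variant_flags(self, variant, attr, value):
        assert getattr(ModelSpec.from_variant(variant), attr) == value

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            ModelSpec.from_variant("A9")

    def test_json_roundtrip(self, tmp_path):
        spec = ModelSpec.from_variant(
            "A3", hyper=Hyperparameters(car_rate=0.05, logdelta_prec=2.9)
        )
        spec.to_json(tmp_path / "spec.json")
        back = ModelSpec.from_json(tmp_path / "spec.json")
        assert back == spec

    def test_default_hyperparameters_are_published_values(self):
        h = Hyperparameters()
        assert (h.fe_shape, h.fe_rate) == (0.005, 0.5)
        assert (h.car_shape, h.car_rate) == (0.5, 0.005)
        assert h.wishart_df == 5.0
        assert h.logdelta_prec == 5.9
        assert h.flat_prec == 1e-4


class TestLinearPredictor:
    def test_all_zero(self, grid25):
        st_ = ParameterState.zeros(25, 4)
        spec = ModelSpec.from_variant("A0")
        val = linear_predictor(st_, spec, np.zeros(4), area=3, k=1)
        assert val == 0.0
        assert expit(val) == 0.5

    def test_hand_arithmetic(self, grid25):
        # alpha=1, delta=2, phi=0.5 -> logit 1 + 2*0.5 = 2
        st_ = ParameterState.zeros(25, 2)
        st_.alpha[:] = 1.0
        st_.log_delta[:] = np.log(2.0)
        st_.phi[:] = 0.5
        spec = ModelSpec.from_variant("A0")
        assert linear_predictor(st_, spec, np.zeros(2), area=0, k=2) == pytest.approx(2.0)

    def test_matches_naive_oracle(self, grid25):
        rng = np.random.default_rng(8)
        spec = ModelSpec.from_variant("A2")
        st_ = _random_state(rng, 25, 6, spec)
        x = rng.standard_normal(6)
        area, k = 17, 1
        pair = spec.pair_indices
        naive = (
            st_.alpha[k]
            + sum(st_.beta[j, k] * x[j] for j in range(6))
            + st_.u[area, k]
            + np.exp(st_.log_delta[k]) * st_.phi[area]
            + st_.s[area, k]
        )
        if k in pair:
            naive += np.exp(st_.log_delta2[pair.index(k)]) * st_.phi2[area]
        assert linear_predictor(st_, spec, x, area, k) == pytest.approx(naive, abs=1e-12)

    def test_treatment_index_out_of_range(self, grid25):
        st_ = ParameterState.zeros(25, 1)
        with pytest.raises(ValueError):
            linear_predictor(st_, ModelSpec.from_variant("A0"), np.zeros(1), 0, 3)

    def test_variant_reduction(self, grid25):
        """A6 predictor is A0's with s zeroed; A5's is A0's with u zeroed."""
        rng = np.random.default_rng(9)
        st_ = _random_state(rng, 25, 3)
        x = rng.standard_normal((10, 3))
        area_idx = rng.integers(0, 25, size=10)
        a0 = ModelSpec.from_variant("A0")
        for variant, zeroed in (("A6", "s"), ("A5", "u")):
            st2 = st_.copy()
            setattr(st2, zeroed, np.zeros_like(getattr(st2, zeroed)))
            reduced = linear_predictor_matrix(st_, ModelSpec.from_variant(variant), x, area_idx)
            full = linear_predictor_matrix(st2, a0, x, area_idx)
            assert reduced == pytest.approx(full, abs=1e-12)


class TestLogLikelihood:
    def test_single_individual_half(self, grid25):
        cohort = make_cohort(np.array([[1, 0, 1]]), ["a01"])
        st_ = ParameterState.zeros(25, 0)
        ll = log_likelihood(
            st_, ModelSpec.from_variant("A0"), cohort, grid25,
            design=(np.zeros((1, 0)), np.zeros(1, dtype=int)),
        )
        assert ll == pytest.approx(3 * np.log(0.5))

    def test_empty_cohort(self, grid25):
        cohort = make_cohort(np.zeros((0, 3), dtype=int), [])
        st_ = ParameterState.zeros(25, 0)
        assert log_likelihood(st_, ModelSpec.from_variant("A0"), cohort, grid25,
                              design=(np.zeros((0, 0)), np.zeros(0, dtype=int))) == 0.0

    def test_matches_bernoulli_pmf_oracle(self, small_fit_inputs, schema):
        g, cohort = small_fit_inputs
        rng = np.random.default_rng(10)
        spec = ModelSpec.from_variant("A0")
        x, _ = design_matrix(cohort, schema)
        st_ = _random_state(rng, g.n_areas, x.shape[1])
        ll = log_likelihood(st_, spec, cohort, g, schema=schema)
        psi = linear_predictor_matrix(st_, spec, x, cohort.area_index(g))
        oracle = bernoulli.logpmf(cohort.outcomes, expit(psi)).sum()
        assert ll == pytest.approx(oracle, abs=1e-10)


def _wishart_logpdf_oracle(X, df, S):
    """Textbook Wishart log-density (dimension 3)."""
    from scipy.special import multigammaln

    d = 3
    sign, ldX = np.linalg.slogdet(X)
    _, ldS = np.linalg.slogdet(S)
    return (
        0.5 * (df - d - 1) * ldX
        - 0.5 * np.trace(np.linalg.solve(S, X))
        - 0.5 * df * d * np.log(2.0)
        - 0.5 * df * ldS
        - multigammaln(0.5 * df, d)
    )


class TestLogPrior:
    def test_all_zero_state_gaussian_constants(self, grid25):
        """Flat-prior variant, zero state: only normalising terms remain."""
        spec = ModelSpec(
            variant="A7", include_u=False, include_s=False, include_shared=False,
            fixed_effect_prior="flat",
        )
        p = 4
        st_ = ParameterState.zeros(25, p)
        expected = (3 + 3 * p) * 0.5 * (np.log(1e-4) - np.log(2 * np.pi))
        assert log_prior(st_, spec, grid25) == pytest.approx(expected)

    def test_wishart_term_matches_oracle(self, grid25):
        rng = np.random.default_rng(11)
        spec = ModelSpec.from_variant("A0")
        st_ = _random_state(rng, 25, 2)
        A = rng.standard_normal((3, 3))
        st_.sigma_u_prec = A @ A.T + 3 * np.eye(3)
        base = st_.copy()
        base.sigma_u_prec = np.eye(3)
        diff = log_prior(st_, spec, grid25) - log_prior(base, spec, grid25)
        # isolate the Wishart + u-quadratic difference
        quad = lambda P: (
            0.5 * 25 * np.linalg.slogdet(P)[1]
            - 0.5 * np.einsum("ij,jk,ik->", st_.u, P, st_.u)
        )
        oracle = (
            _wishart_logpdf_oracle(st_.sigma_u_prec, 5.0, np.eye(3))
            - _wishart_logpdf_oracle(np.eye(3), 5.0, np.eye(3))
            + quad(st_.sigma_u_prec)
            - quad(np.eye(3))
        )
        assert diff == pytest.approx(oracle, abs=1e-9)

    def test_car_precision_change_delegates_to_car_density(self, grid25):
        rng = np.random.default_rng(12)
        spec = ModelSpec.from_variant("A0")
        st_ = _random_state(rng, 25, 2)
        st_ = apply_constraints(st_, grid25)
        hi = st_.copy()
        hi.tau_phi = 2 * st_.tau_phi
        diff = log_prior(hi, spec, grid25) - log_prior(st_, spec, grid25)
        from scipy.stats import gamma as gd

        oracle = (
            car_log_density(st_.phi, hi.tau_phi, grid25)
            - car_log_density(st_.phi, st_.tau_phi, grid25)
            + gd.logpdf(hi.tau_phi, a=0.5, scale=1 / 0.005)
            - gd.logpdf(st_.tau_phi, a=0.5, scale=1 / 0.005)
        )
        assert diff == pytest.approx(oracle, abs=1e-9)

    def test_a7_differs_from_a0_only_in_fixed_effect_terms(self, grid25):
        rng = np.random.default_rng(13)
        p = 3
        st_ = apply_constraints(_random_state(rng, 25, p), grid25)
        a0, a7 = ModelSpec.from_variant("A0"), ModelSpec.from_variant("A7")
        diff = log_prior(st_, a7, grid25) - log_prior(st_, a0, grid25)
        from scipy.stats import gamma as gd, norm

        def fe_terms_h():
            t = gd.logpdf(st_.tau_alpha, a=0.005, scale=2.0)
            t += norm.logpdf(st_.alpha, scale=st_.tau_alpha**-0.5).sum()
            for k in range(3):
                t += gd.logpdf(st_.tau_beta[k], a=0.005, scale=2.0)
                t += norm.logpdf(st_.beta[:, k], scale=st_.tau_beta[k] ** -0.5).sum()
            return t

        flat = norm.logpdf(st_.alpha, scale=100.0).sum() + norm.logpdf(
            st_.beta, scale=100.0
        ).sum()
        assert diff == pytest.approx(flat - fe_terms_h(), abs=1e-9)

    def test_finite_for_constrained_states(self, grid25):
        rng = np.random.default_rng(14)
        for variant in ("A0", "A1", "A2", "A5", "A6", "A7"):
            spec = ModelSpec.from_variant(variant)
            st_ = apply_constraints(_random_state(rng, 25, 4, spec), grid25)
            assert np.isfinite(log_prior(st_, spec, grid25))


class TestApplyConstraints:
    def test_log_delta_examples(self, grid25):
        st_ = ParameterState.zeros(25, 1)
        st_.log_delta = np.array([0.3, -0.1, -0.2])
        out = apply_constraints(st_, grid25)
        assert out.log_delta == pytest.approx([0.3, -0.1, -0.2])
        st_.log_delta = np.array([1.0, 1.0, 1.0])
        out = apply_constraints(st_, grid25)
        assert out.log_delta == pytest.approx(np.zeros(3))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_idempotent(self, seed):
        g = grid_graph(5, 5)
        rng = np.random.default_rng(seed)
        spec = ModelSpec.from_variant("A4")
        st_ = _random_state(rng, 25, 3, spec)
        once = apply_constraints(st_, g)
        twice = apply_constraints(once, g)
        for name in ("phi", "s", "log_delta", "phi2", "log_delta2"):
            assert getattr(twice, name) == pytest.approx(getattr(once, name), abs=1e-12)


class TestDesignMatrix:
    def test_empty_category_dropped_with_warning(self, schema, caplog):
        import logging

        g = grid_graph(3, 3)
        truth = TruthConfig.default(g, schema, n_individuals=40, seed=2)
        cohort, _ = generate_cohort(truth, schema, g)
        # "no_surgery" (frequency 15/6296) is almost surely absent at n=40
        assert "no_surgery" not in set(cohort.df["surgery"])
        with caplog.at_level(logging.WARNING):
            x, cols = design_matrix(cohort, schema)
        assert "surgery=no_surgery" not in cols
        assert any("no_surgery" in r.message for r in caplog.records)
        assert x.shape == (40, len(cols))

    def test_unknown_category_rejected(self, schema):
        cohort = make_cohort(np.zeros((1, 3), dtype=int), ["a1"])
        df = cohort.df
        for cov in schema:
            df[cov.name] = cov.reference
        df["stage"] = "bogus"
        with pytest.raises(ValueError, match="unknown categories"):
            design_matrix(df, schema)

    def test_drop_covariate(self, schema, small_fit_inputs):
        _, cohort = small_fit_inputs
        _, cols = design_matrix(cohort, schema, drop=("age_group",), drop_empty=False)
        assert not any(c.startswith("age_group=") for c in cols)
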